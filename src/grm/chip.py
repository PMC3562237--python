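"""ChIP-signal prediction and the synthetic measurement model.

A ChIP time course reports, per protein, the fraction of cells in the sample
in which that protein is promoter-bound: c_p(t) = sum_i P_pi * p_i(t), the
contraction of the constant binding matrix with the population state
distribution.  ``measure`` turns a noiseless predicted course into a
realistic sampled one: finite-cell binomial counting noise plus Gaussian
technical noise on a coarser sampling grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import StateDistribution
from .network import BindingMatrix

logger = logging.getLogger(__name__)

__all__ = ["ChIPSeries", "chip_signal", "measure", "write_chip_csv", "read_chip_csv"]


@dataclass(frozen=True)
class ChIPSeries:
    """Per-protein ChIP concentration trajectories on a time grid.

    ``values[p, k]`` is protein p's concentration (fraction of input, 0-1
    for noiseless series) at ``time_grid[k]``.
    """

    time_grid: np.ndarray
    values: np.ndarray
    protein_names: tuple[str, ...]
    noise_sd: float | None = None
    n_cells: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be 1-D and strictly increasing")
        if v.shape != (len(self.protein_names), t.size):
            raise ValueError(
                f"values must be (n_proteins, n_times) = "
                f"({len(self.protein_names)}, {t.size}), got {v.shape}"
            )
        if self.noise_sd is None and self.n_cells is None:
            if v.min() < -1e-9 or v.max() > 1 + 1e-9:
                raise ValueError("noiseless concentrations must lie in [0, 1]")
        t.setflags(write=False)
        v.setflags(write=False)
        object.__setattr__(self, "time_grid", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "protein_names", tuple(self.protein_names))

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    def protein(self, name: str) -> np.ndarray:
        return self.values[self.protein_names.index(name)]

    def truncated(self, t_max: float) -> "ChIPSeries":
        """The sub-series with ``time <= t_max`` (e.g. the transient window)."""
        keep = self.time_grid <= t_max
        return ChIPSeries(
            time_grid=self.time_grid[keep],
            values=self.values[:, keep],
            protein_names=self.protein_names,
            noise_sd=self.noise_sd,
            n_cells=self.n_cells,
            seed=self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.T, columns=list(self.protein_names))
        df.insert(0, "time", self.time_grid)
        return df


def chip_signal(
    binding: BindingMatrix, dists: list[StateDistribution]
) -> ChIPSeries:
    """Predict the noiseless ChIP signal from a distribution time course."""
    if not dists:
        raise ValueError("need at least one state distribution")
    if binding.n_states != dists[0].n_states:
        raise ValueError(
            f"binding matrix covers {binding.n_states} states, "
            f"distributions have {dists[0].n_states}"
        )
    probs = np.column_stack([d.probs for d in dists])
    times = np.array([d.time for d in dists])
    return ChIPSeries(
        time_grid=times,
        values=binding.values @ probs,
        protein_names=binding.protein_names,
    )


def measure(
    series: ChIPSeries,
    n_cells: int = 10**6,
    noise_sd: float = 0.0,
    sampling_interval: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> ChIPSeries:
    """Emulate a sampled, noisy ChIP measurement of a noiseless course.

    Subsamples the time grid at ``sampling_interval`` (nearest grid points),
    replaces each concentration by a binomial draw over ``n_cells`` cells,
    adds Gaussian technical noise of standard deviation ``noise_sd`` and
    clips to [0, 1].  Reproducible under ``seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    t = series.time_grid
    if sampling_interval is None:
        keep = np.arange(t.size)
    else:
        if sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        span = t[-1] - t[0]
        if sampling_interval > span:
            raise ValueError(
                f"sampling_interval {sampling_interval} exceeds series span {span}"
            )
        targets = np.arange(t[0], t[-1] + 1e-12, sampling_interval)
        keep = np.unique(np.searchsorted(t, targets, side="left").clip(0, t.size - 1))
    rng = np.random.default_rng(seed)
    clean = np.clip(series.values[:, keep], 0.0, 1.0)
    noisy = rng.binomial(n_cells, clean) / n_cells
    if noise_sd > 0:
        noisy = noisy + rng.normal(0.0, noise_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, 1.0)
    return ChIPSeries(
        time_grid=t[keep],
        values=noisy,
        protein_names=series.protein_names,
        noise_sd=noise_sd,
        n_cells=n_cells,
        seed=seed if isinstance(seed, int) else None,
    )


def write_chip_csv(series: ChIPSeries, path_or_buf) -> None:
    """Write the wide-format ChIP CSV: ``time,<protein1>,<protein2>,...``."""
    series.to_frame().to_csv(path_or_buf, index=False)


def read_chip_csv(path_or_buf) -> ChIPSeries:
    """Read a wide-format ChIP CSV; rows with missing values are dropped."""
    df = pd.read_csv(path_or_buf)
    if "time" not in df.columns or df.shape[1] < 2:
        raise ValueError("ChIP CSV needs a 'time' column plus protein columns")
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("dropping %d rows with missing values", n_bad)
        df = df.dropna()
    proteins = [c for c in df.columns if c != "time"]
    return ChIPSeries(
        time_grid=df["time"].to_numpy(),
        values=df[proteins].to_numpy().T,
        protein_names=tuple(proteins),
        noise_sd=np.nan,  # unknown provenance: skip the [0,1] noiseless check
    )
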