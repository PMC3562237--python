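"""Recruitment-state networks and protein binding patterns.

A recruitment process is modelled as a continuous-time Markov chain on N
"landmark" states arranged on a circle (state ``N-1`` wraps to ``0``).
Strictly sequential recruitment (SR) links each state only to its successor;
probabilistic recruitment (PR) adds reversible steps, weak random links or
long-range shortcuts on top of the cycle.  Which proteins are ChIP-visible in
which state is a constant binary binding matrix.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RecruitmentNetwork",
    "BindingMatrix",
    "Shortcut",
    "build_sr",
    "add_reversible",
    "add_random_transitions",
    "add_shortcuts",
    "binding_from_windows",
    "build_ps2_scenario",
    "classify_transition_range",
    "write_network",
    "read_network",
]


@dataclass(frozen=True)
class RecruitmentNetwork:
    """A recruitment-state network.

    Parameters
    ----------
    n_states:
        Number of landmark states N (the ChIP-detectable complexes).
    rates:
        ``(N, N)`` matrix of non-negative transition rates; ``rates[i, j]``
        is the rate of the transition ``i -> j`` per unit time.  The diagonal
        is zero (no self-transitions).
    substeps:
        Number m of exponential intermediate substeps interpolating each
        landmark transition.  ``m=1`` is the plain exponential chain; large m
        is the "clockwork" regime where landmark waiting times concentrate.
    labels:
        Optional per-state names.
    """

    n_states: int
    rates: np.ndarray
    substeps: int = 1
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("a recruitment network needs at least 2 states")
        if self.substeps < 1:
            raise ValueError("substeps must be a positive integer")
        rates = np.asarray(self.rates, dtype=float)
        if rates.shape != (self.n_states, self.n_states):
            raise ValueError(
                f"rates must be ({self.n_states}, {self.n_states}), got {rates.shape}"
            )
        if np.any(rates < 0):
            raise ValueError("transition rates must be non-negative")
        if np.any(np.diag(rates) != 0):
            raise ValueError("self-transitions are not allowed (diagonal must be 0)")
        if np.any(rates.sum(axis=1) <= 0):
            stalled = np.flatnonzero(rates.sum(axis=1) <= 0)
            raise ValueError(f"absorbing states (no outgoing rate): {stalled.tolist()}")
        if self.labels is not None and len(self.labels) != self.n_states:
            raise ValueError("labels must have one entry per state")
        rates.setflags(write=False)
        object.__setattr__(self, "rates", rates)

    @property
    def total_exit_rates(self) -> np.ndarray:
        """Per-state total outgoing rate (the exponential holding rate)."""
        return self.rates.sum(axis=1)

    def with_rates(self, rates: np.ndarray) -> "RecruitmentNetwork":
        return replace(self, rates=np.array(rates, dtype=float))

    def cycle_rate(self) -> float:
        """The forward on-cycle rate, if it is uniform.

        Raises if the cycle edges ``i -> i+1 (mod N)`` do not all carry the
        same positive rate.
        """
        nxt = (np.arange(self.n_states) + 1) % self.n_states
        fwd = self.rates[np.arange(self.n_states), nxt]
        if np.any(fwd <= 0) or not np.allclose(fwd, fwd[0]):
            raise ValueError("network has no uniform forward cycle rate")
        return float(fwd[0])


@dataclass(frozen=True)
class BindingMatrix:
    """Constant binary map from recruitment states to bound proteins.

    ``values[p, i] == 1`` means protein p is bound at the promoter in state
    i.  Contracting this matrix with a state distribution yields the
    predicted ChIP concentration of each protein.
    """

    values: np.ndarray
    protein_names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("binding matrix must be 2-D (proteins x states)")
        if not np.isin(values, (0, 1)).all():
            raise ValueError("binding matrix entries must be 0 or 1")
        if len(self.protein_names) != values.shape[0]:
            raise ValueError("need one protein name per row")
        values = values.astype(float)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "protein_names", tuple(self.protein_names))

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_states(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            self.values.astype(int),
            index=list(self.protein_names),
            columns=[str(i) for i in range(self.n_states)],
        )
        df.index.name = "protein"
        df.to_csv(path_or_buf)

    @classmethod
    def from_csv(cls, path_or_buf) -> "BindingMatrix":
        df = pd.read_csv(path_or_buf, index_col=0)
        return cls(values=df.to_numpy(), protein_names=tuple(df.index.astype(str)))


@dataclass(frozen=True)
class Shortcut:
    """An off-cycle transition ``source -> target`` with a positive rate."""

    source: int
    target: int
    rate: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("a shortcut cannot start and end at the same state")
        if self.rate <= 0:
            raise ValueError("shortcut rate must be positive")

    def span(self, n_states: int) -> int:
        """Circular span (target - source) mod N, in landmark units."""
        return (self.target - self.source) % n_states

    def direction(self, n_states: int) -> str:
        """``forward`` if the ascending circular span is the shorter way round."""
        s = self.span(n_states)
        return "forward" if s <= n_states - s else "backward"


def build_sr(n_states: int, rate: float) -> RecruitmentNetwork:
    """Build a pure sequential-recruitment cycle.

    Every state is linked only to its unique successor (circularly), all
    with the same rate, so the rate matrix is the circular sub-diagonal.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if rate <= 0:
        raise ValueError("rate must be positive")
    rates = np.zeros((n_states, n_states))
    idx = np.arange(n_states)
    rates[idx, (idx + 1) % n_states] = rate
    return RecruitmentNetwork(n_states=n_states, rates=rates)


def add_reversible(net: RecruitmentNetwork, backward_rate: float) -> RecruitmentNetwork:
    """Make every on-cycle step reversible with a common backward rate.

    Adds ``i -> (i-1) mod N`` at ``backward_rate`` for every state.  The
    model regime of interest has the backward rate smaller than the forward
    rate; violating that is allowed but flagged.
    """
    if backward_rate < 0:
        raise ValueError("backward_rate must be non-negative")
    if backward_rate == 0:
        return net
    idx = np.arange(net.n_states)
    fwd = net.rates[idx, (idx + 1) % net.n_states]
    if backward_rate >= fwd.min():
        warnings.warn(
            "backward rate >= forward rate: drift vanishes or reverses and the "
            "process is diffusion-dominated",
            stacklevel=2,
        )
    rates = np.array(net.rates)
    rates[idx, (idx - 1) % net.n_states] += backward_rate
    return net.with_rates(rates)


def add_random_transitions(
    net: RecruitmentNetwork,
    count: int,
    rate_range: tuple[float, float],
    span_range: tuple[int, int],
    seed: int | np.random.Generator | None = None,
) -> RecruitmentNetwork:
    """Add ``count`` distinct random off-cycle transitions.

    Rates are drawn uniformly from ``rate_range``, sources uniformly over
    states, circular spans uniformly over the integers of ``span_range``
    (inclusive), direction forward/backward with equal probability.
    Reproducible under ``seed``.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count == 0:
        return net
    lo, hi = rate_range
    if lo <= 0 or hi < lo:
        raise ValueError("rate_range must be within (0, inf) with lo <= hi")
    smin, smax = int(span_range[0]), int(span_range[1])
    n = net.n_states
    if not (1 <= smin <= smax <= n - 1):
        raise ValueError("span_range must lie within [1, N-1]")
    idx = np.arange(n)
    on_cycle = set(zip(idx.tolist(), ((idx + 1) % n).tolist()))
    candidates = {
        (src, (src + sign * span) % n)
        for src in range(n)
        for span in range(smin, smax + 1)
        for sign in (1, -1)
    } - on_cycle
    if count > len(candidates):
        raise ValueError(
            f"cannot place {count} distinct off-cycle transitions "
            f"(only {len(candidates)} candidate pairs in span range)"
        )
    rng = np.random.default_rng(seed)
    rates = np.array(net.rates)
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < count:
        src = int(rng.integers(0, n))
        span = int(rng.integers(smin, smax + 1))
        sign = 1 if rng.random() < 0.5 else -1
        tgt = (src + sign * span) % n
        pair = (src, tgt)
        if pair in chosen or pair in on_cycle or src == tgt:
            continue
        chosen.add(pair)
        rates[src, tgt] += rng.uniform(lo, hi)
    return net.with_rates(rates)


def add_shortcuts(net: RecruitmentNetwork, shortcuts: list[Shortcut]) -> RecruitmentNetwork:
    """Add the listed shortcuts; rates accumulate additively."""
    rates = np.array(net.rates)
    for sc in shortcuts:
        if not (0 <= sc.source < net.n_states and 0 <= sc.target < net.n_states):
            raise ValueError(f"shortcut indices out of range: {sc}")
        rates[sc.source, sc.target] += sc.rate
    return net.with_rates(rates)


def binding_from_windows(
    n_states: int,
    windows: dict[str, list[tuple[int, int]]],
) -> BindingMatrix:
    """Build a binding matrix from half-open bound windows per protein.

    ``windows`` maps protein name to a list of ``[start, end)`` index
    windows (wrapping allowed: ``start > end`` wraps past state N-1).
    """
    names = list(windows)
    values = np.zeros((len(names), n_states), dtype=int)
    for p, name in enumerate(names):
        for start, end in windows[name]:
            start %= n_states
            end = end % n_states if end != n_states else n_states
            if start < end:
                values[p, start:end] = 1
            else:  # wrapped window
                values[p, start:] = 1
                values[p, :end] = 1
    return BindingMatrix(values=values, protein_names=tuple(names))


def build_ps2_scenario(
    n_per_cycle: int,
    clearance_probability: float,
    rate: float = 1.0,
) -> tuple[RecruitmentNetwork, BindingMatrix]:
    """Double transcription-cycle network with probabilistic promoter clearance.

    The network is a ``2 * n_per_cycle`` state cycle: an "odd" half (states
    ``0 .. n-1``) followed by an "even" half (states ``n .. 2n-1``).  At the
    end of the odd half a shortcut back to the cleared-promoter state 0
    carries embedded jump probability ``clearance_probability`` (the rate is
    the competing-exponentials inversion ``rate * q / (1 - q)``); otherwise
    the process continues into the even half, after which clearance is
    certain.

    Proteins
    --------
    A (persistent, TBP-like)
        Bound on one window of length ``n_per_cycle`` spanning the odd/even
        boundary (``[0.9 n, 1.9 n)``): it binds late in the odd cycle and
        remains bound through the even cycle.  Because its bound window
        covers (almost) exactly one of the two conjugate phases at every
        point of the transcription cycle, its ChIP signal carries the
        double-cycle periodicity (period ``2n / rate``) with almost no
        single-cycle component — the structural signature of a factor that
        distinguishes odd from even cycles.
    B (cycling factor)
        Bound on the same relative window within each half, hence one
        appearance per transcription cycle (period ``n / rate``).
    C (early factor)
        Bound early in each half.
    """
    if n_per_cycle < 10:
        raise ValueError("n_per_cycle must be >= 10")
    q = float(clearance_probability)
    if not (0.0 <= q <= 1.0):
        raise ValueError("clearance_probability must be within [0, 1]")
    n = int(n_per_cycle)
    N = 2 * n
    rates = np.zeros((N, N))
    idx = np.arange(N)
    rates[idx, (idx + 1) % N] = rate
    if q == 1.0:
        # degenerate limit: the even half is unreachable
        rates[n - 1, n] = 0.0
        rates[n - 1, 0] = rate
    elif q > 0.0:
        rates[n - 1, 0] = rate * q / (1.0 - q)
    net = RecruitmentNetwork(n_states=N, rates=rates)

    start_a = int(0.9 * n)
    windows = {
        "A": [(start_a, start_a + n)],  # spans both halves, length exactly n
        "B": [(int(0.6 * n), int(0.9 * n)), (n + int(0.6 * n), n + int(0.9 * n))],
        "C": [(int(0.05 * n), int(0.30 * n)), (n + int(0.05 * n), n + int(0.30 * n))],
    }
    binding = binding_from_windows(N, windows)
    return net, binding


def classify_transition_range(
    net: RecruitmentNetwork,
    transition: Shortcut,
    observation_time: float,
    broadening_fraction: float = 0.05,
) -> str:
    """Classify a transition as ``short_range`` or ``long_range``.

    A transition's contribution to the effective diffusion constant is
    ``span**2 * rate / 2`` (landmark units squared per time, with span the
    minimal circular jump length).  It is long-range iff the implied
    broadening ``sqrt(2 * D * observation_time)`` exceeds
    ``broadening_fraction`` of the cycle length N — i.e. iff it visibly
    widens the population distribution over the observation time.
    """
    if net.rates[transition.source, transition.target] <= 0:
        raise ValueError("transition does not exist in the network")
    n = net.n_states
    s = transition.span(n)
    span = min(s, n - s)
    d_contrib = span**2 * transition.rate / 2.0
    widening = np.sqrt(2.0 * d_contrib * observation_time)
    return "long_range" if widening > broadening_fraction * n else "short_range"


# ---------------------------------------------------------------------------
# serialization


def write_network(net: RecruitmentNetwork, path_or_buf) -> None:
    """Write a network as a tab-separated edge list with a one-line header."""
    buf = io.StringIO()
    buf.write(f"#GRM n_states={net.n_states} substeps={net.substeps}\n")
    src, tgt = np.nonzero(net.rates)
    for i, j in zip(src.tolist(), tgt.tolist()):
        buf.write(f"{i}\t{j}\t{float(net.rates[i, j])!r}\n")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_network(path_or_buf) -> RecruitmentNetwork:
    """Read a network written by :func:`write_network`."""
    if hasattr(path_or_buf, "read"):
        lines = path_or_buf.read().splitlines()
    else:
        with open(path_or_buf) as fh:
            lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#GRM"):
        raise ValueError("not a GRM network file (missing #GRM header)")
    header = dict(tok.split("=") for tok in lines[0].split()[1:])
    n_states = int(header["n_states"])
    substeps = int(header.get("substeps", 1))
    rates = np.zeros((n_states, n_states))
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            i_s, j_s, r_s = line.split("\t")
            rates[int(i_s), int(j_s)] = float(r_s)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"malformed edge at line {lineno}: {line!r}") from exc
    return RecruitmentNetwork(n_states=n_states, rates=rates, substeps=substeps)
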