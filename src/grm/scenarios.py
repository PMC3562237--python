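"""Scenario configuration and the end-to-end runner.

A scenario bundles a network topology, a binding matrix, initial conditions,
a propagation regime and an optional measurement model; running it produces
ChIP time courses per initial condition, oscillation diagnostics and the
SR/PR verdict, plus a provenance sidecar.  The six bundled scenarios cover
the canonical study conditions: pure sequential recruitment, 100 weak random
transitions, one shortcut, two shortcuts, 100 shortcuts, and the
double-transcription-cycle promoter with probabilistic clearance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .chip import ChIPSeries, chip_signal, measure, read_chip_csv, write_chip_csv
from .discriminate import (
    DESYNCHRONIZED_KINDS,
    DiscriminationReport,
    classify_recruitment,
    desynchronize,
    detect_oscillations,
    make_initial_condition,
)
from .dynamics import clockwork_propagate, propagate
from .network import (
    BindingMatrix,
    RecruitmentNetwork,
    Shortcut,
    add_random_transitions,
    add_reversible,
    add_shortcuts,
    binding_from_windows,
    build_ps2_scenario,
    build_sr,
    write_network,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "load_config",
    "build_from_config",
    "run_scenario",
    "classify_file",
    "SCENARIOS",
    "scenario_config",
]

_TOPOLOGIES = ("sr", "reversible", "random_weak", "shortcuts", "ps2")
_REGIMES = ("clockwork", "master")


@dataclass
class ScenarioConfig:
    """Schema-validated scenario description (YAML/JSON-friendly)."""

    topology: str = "sr"
    n_states: int = 200
    rate: float = 1.0
    backward_rate: float = 0.0
    random_count: int = 0
    random_rate_range: tuple[float, float] = (0.01, 0.05)
    random_span_range: tuple[int, int] = (1, 3)
    shortcuts: list[dict] = field(default_factory=list)
    ps2_n_per_cycle: int = 100
    ps2_clearance_probability: float = 0.5
    binding: dict[str, list[tuple[int, int]]] | None = None
    initial_conditions: tuple[str, ...] = ("random", "gaussian", "uniform")
    sigma: float | None = None
    ic_center: int = 0
    regime: str = "clockwork"
    n_periods: float = 40.0
    detect_periods: float = 8.0
    desync_detect_periods: float = 3.0
    dt: float | None = None
    n_cells: int | None = None
    noise_sd: float = 0.0
    sampling_interval: float | None = None
    seed: int = 0
    name: str = "scenario"

    def __post_init__(self) -> None:
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"topology must be one of {_TOPOLOGIES}, got {self.topology!r}")
        if self.regime not in _REGIMES:
            raise ValueError(f"regime must be one of {_REGIMES}, got {self.regime!r}")
        unknown = set(self.initial_conditions) - {"random", "gaussian", "uniform", "desynchronized"}
        if unknown:
            raise ValueError(f"unknown initial-condition kinds: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(known)}"
            )
        cfg = dict(raw)
        for key in ("random_rate_range", "random_span_range", "initial_conditions"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return cls(**cfg)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d


def load_config(path) -> ScenarioConfig:
    """Load a YAML or JSON scenario config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return ScenarioConfig.from_dict(raw)


def _default_binding(n: int) -> dict[str, list[tuple[int, int]]]:
    """Three hypothetical proteins bound in evenly spaced windows of N/5."""
    w = n // 5
    return {
        "P1": [(0, w)],
        "P2": [(n // 3, n // 3 + w)],
        "P3": [(2 * n // 3, 2 * n // 3 + w)],
    }


def _probability_to_rate(q: float, cycle_rate: float) -> float:
    """Invert the embedded jump probability of a shortcut competing with the
    forward cycle edge: rate = cycle_rate * q / (1 - q)."""
    if not (0.0 < q < 1.0):
        raise ValueError("shortcut probability must be in (0, 1)")
    return cycle_rate * q / (1.0 - q)


def build_from_config(cfg: ScenarioConfig) -> tuple[RecruitmentNetwork, BindingMatrix]:
    """Build the network and binding matrix a config describes."""
    if cfg.topology == "ps2":
        return build_ps2_scenario(cfg.ps2_n_per_cycle, cfg.ps2_clearance_probability, cfg.rate)
    net = build_sr(cfg.n_states, cfg.rate)
    if cfg.topology == "reversible":
        net = add_reversible(net, cfg.backward_rate)
    elif cfg.topology == "random_weak":
        net = add_random_transitions(
            net, cfg.random_count, cfg.random_rate_range, cfg.random_span_range,
            seed=cfg.seed,
        )
    elif cfg.topology == "shortcuts":
        scs = []
        for item in cfg.shortcuts:
            if "probability" in item:
                rate = _probability_to_rate(float(item["probability"]), cfg.rate)
            else:
                rate = float(item["rate"])
            scs.append(Shortcut(int(item["source"]), int(item["target"]), rate))
        net = add_shortcuts(net, scs)
    binding_windows = cfg.binding
    if binding_windows is None:
        binding_windows = _default_binding(net.n_states)
    binding = binding_from_windows(net.n_states, {
        name: [tuple(w) for w in wins] for name, wins in binding_windows.items()
    })
    return net, binding


def _simulate(cfg: ScenarioConfig, net: RecruitmentNetwork, binding: BindingMatrix,
              ic_probs: np.ndarray) -> ChIPSeries:
    period = net.n_states / cfg.rate
    t_max = cfg.n_periods * period
    from .dynamics import StateDistribution

    dist0 = StateDistribution(probs=ic_probs, time=0.0)
    if cfg.regime == "clockwork":
        n_steps = int(round(t_max * cfg.rate))
        _, dists = clockwork_propagate(net, dist0, n_steps)
    else:
        dt = cfg.dt if cfg.dt is not None else 1.0 / cfg.rate
        grid = np.arange(0.0, t_max + dt / 2, dt)
        dists = propagate(net, dist0, grid, method="expm")
    return chip_signal(binding, dists)


def run_scenario(cfg: ScenarioConfig, outdir: str | Path | None = None) -> dict:
    """Run a scenario end to end.

    Builds the network and binding matrix, propagates every requested
    initial condition, predicts (and optionally noisily measures) the ChIP
    signals, runs oscillation detection — synchronized conditions over
    ``detect_periods`` cycles, de-synchronized ones over the transient
    window of ``desync_detect_periods`` cycles — and classifies the
    recruitment process.  Writes CSVs, a JSON report and a provenance
    sidecar when ``outdir`` is given.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    net, binding = build_from_config(cfg)
    period = net.n_states / cfg.rate

    series_by_kind: dict[str, ChIPSeries] = {}
    reports_by_kind: dict[str, dict] = {}
    for kind in cfg.initial_conditions:
        if kind == "desynchronized":
            base = make_initial_condition(
                "gaussian", net, center=cfg.ic_center, sigma=cfg.sigma
            )
            ic = desynchronize(base, n_subpopulations=50,
                               seed=int(rng.integers(2**31)))
        else:
            ic = make_initial_condition(
                kind, net, center=cfg.ic_center, sigma=cfg.sigma,
                seed=int(rng.integers(2**31)),
            )
        series = _simulate(cfg, net, binding, ic.probs)
        if cfg.n_cells is not None:
            series = measure(
                series, n_cells=cfg.n_cells, noise_sd=cfg.noise_sd,
                sampling_interval=cfg.sampling_interval,
                seed=int(rng.integers(2**31)),
            )
        series_by_kind[kind] = series
        window = (cfg.desync_detect_periods if kind in DESYNCHRONIZED_KINDS
                  else cfg.detect_periods)
        reports_by_kind[kind] = detect_oscillations(
            series.truncated(window * period), seed=int(rng.integers(2**31))
        )

    report = classify_recruitment(reports_by_kind)
    bundle = {
        "config": cfg,
        "network": net,
        "binding": binding,
        "series": series_by_kind,
        "report": report,
        "period": period,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_network(net, outdir / "network.tsv")
        binding.to_csv(outdir / "binding.csv")
        for kind, series in series_by_kind.items():
            write_chip_csv(series, outdir / f"chip_{kind}.csv")
        report.to_json(outdir / "report.json")
        cfg_dict = cfg.to_dict()
        provenance = {
            "package": "grm",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg_dict,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True).encode()
            ).hexdigest(),
            "tolerances": {"rtol": 1e-8, "atol": 1e-10, "renorm": 1e-7},
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    return bundle


def classify_file(
    chip_csv_by_condition: dict[str, str | Path],
    **thresholds,
) -> DiscriminationReport:
    """Run the discrimination test on measured ChIP CSV files.

    ``chip_csv_by_condition`` maps the initial-condition kind under which
    each time course was recorded (gaussian/synchronized, uniform, random,
    desynchronized) to a wide-format CSV path.
    """
    reports = {}
    for kind, path in chip_csv_by_condition.items():
        series = read_chip_csv(path)
        reports[kind] = detect_oscillations(series)
    return classify_recruitment(reports, **thresholds)


# ---------------------------------------------------------------------------
# bundled study scenarios


def _sc(name: str, **kw) -> ScenarioConfig:
    return ScenarioConfig(name=name, **kw)


SCENARIOS: dict[str, ScenarioConfig] = {
    # pure sequential recruitment, N=200 complexes, unit cycle rate
    "fig3_sr": _sc("fig3_sr", topology="sr"),
    # 100 weak short-range random transitions: indistinguishable from SR
    "fig4_weak": _sc(
        "fig4_weak", topology="random_weak", random_count=100,
        random_rate_range=(0.01, 0.05), random_span_range=(1, 3),
    ),
    # one long-range backward shortcut (embedded probability 0.3)
    "fig5_one_shortcut": _sc(
        "fig5_one_shortcut", topology="shortcuts",
        shortcuts=[{"source": 140, "target": 40, "probability": 0.3}],
    ),
    # two shortcuts: one backward, one forward
    "fig6_two_shortcuts": _sc(
        "fig6_two_shortcuts", topology="shortcuts",
        shortcuts=[
            {"source": 140, "target": 40, "probability": 0.3},
            {"source": 60, "target": 160, "probability": 0.3},
        ],
    ),
    # 100 random long-range shortcuts: relaxes immediately under any IC
    "fig7_100shortcuts": _sc(
        "fig7_100shortcuts", topology="random_weak", random_count=100,
        random_rate_range=(0.3, 0.6), random_span_range=(20, 180),
    ),
    # double transcription cycle with probabilistic promoter clearance
    "fig8_ps2": _sc(
        "fig8_ps2", topology="ps2", ps2_n_per_cycle=100,
        ps2_clearance_probability=0.5,
    ),
}


def scenario_config(name: str, **overrides) -> ScenarioConfig:
    """A fresh copy of a bundled scenario config, with optional overrides."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    return dataclasses.replace(SCENARIOS[name], **overrides)
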