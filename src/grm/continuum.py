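"""Analytic limits of the recruitment model.

In the limit of many intermediate substeps (m -> inf) the sequential cycle
becomes an advection equation on the circle: the initial population
distribution translates periodically with frequency omega = 2*pi*rate/N and
does not change shape.  Making the steps reversible (forward rate lam_f,
backward rate lam_b, lam_b < lam_f) yields, for large N, a Fokker-Planck
equation with drift v = lam_f - lam_b and diffusion D = (lam_f + lam_b) / 2
(per landmark step); diffusion broadens the initial condition by
sqrt(2*D*t) over time t.  Short-range extra transitions only renormalize v
and omega; long-range ones add visible diffusion — this is the quantity the
short/long-range classification is built on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import StateDistribution

__all__ = [
    "ContinuumCoefficients",
    "sr_advection_solution",
    "fokker_planck_coefficients",
    "broadening",
]


@dataclass(frozen=True)
class ContinuumCoefficients:
    """Drift/diffusion summary of a (near-)sequential recruitment process.

    drift: landmark units per time; diffusion: landmark units^2 per time;
    effective_frequency: radians per time for the paired cycle length;
    observation_time: the horizon the broadening is judged over.
    """

    drift: float
    diffusion: float
    effective_frequency: float | None = None
    observation_time: float | None = None

    def __post_init__(self) -> None:
        if self.diffusion < 0:
            raise ValueError("diffusion constant must be non-negative")


def sr_advection_solution(
    dist0: StateDistribution, rate: float, t: float
) -> StateDistribution:
    """Advection (clockwork-limit) solution of the sequential cycle.

    The distribution translates circularly by ``rate * t`` landmark units
    with no change of shape.  Non-integer shifts are realized by linear
    interpolation between the two neighbouring integer translates, which
    preserves total probability.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    shift = rate * t
    k = int(np.floor(shift))
    frac = shift - k
    p = dist0.probs
    rolled = np.roll(p, k)
    if frac > 0:
        rolled = (1.0 - frac) * rolled + frac * np.roll(p, k + 1)
    return StateDistribution(probs=rolled, time=dist0.time + t)


def fokker_planck_coefficients(
    forward_rate: float,
    backward_rate: float,
    n_states: int | None = None,
    observation_time: float | None = None,
) -> ContinuumCoefficients:
    """Drift and diffusion of the reversible sequential cycle.

    Biased nearest-neighbour walk limit: v = lam_f - lam_b,
    D = (lam_f + lam_b) / 2 (landmark units).  At lam_f == lam_b the drift
    vanishes and the process is pure diffusion — the "reversibility only
    rescales the frequency" picture no longer applies.
    """
    if forward_rate < 0 or backward_rate < 0:
        raise ValueError("rates must be non-negative")
    v = forward_rate - backward_rate
    d = (forward_rate + backward_rate) / 2.0
    omega = None
    if n_states is not None:
        omega = 2.0 * np.pi * v / n_states
    return ContinuumCoefficients(
        drift=v,
        diffusion=d,
        effective_frequency=omega,
        observation_time=observation_time,
    )


def broadening(diffusion: float, observation_time: float) -> float:
    """Width gained by the population distribution: sqrt(2 * D * t_obs)."""
    if diffusion < 0 or observation_time < 0:
        raise ValueError("diffusion and observation_time must be non-negative")
    return float(np.sqrt(2.0 * diffusion * observation_time))
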