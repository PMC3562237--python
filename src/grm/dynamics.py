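"""State-distribution dynamics of the recruitment model.

The population of cells is described by a probability vector p(t) over the
recruitment states.  Its evolution is the linear master equation

    dp_i/dt = sum_j lambda_ji p_j - p_i sum_j lambda_ij,

i.e. ``dp/dt = Q.T @ p`` with the generator ``Q = rates - diag(row sums)``.
This module integrates that equation, samples exact stochastic trajectories
of single cells (competing exponential clocks), and provides the landmark
waiting-time law for the m-substep ("clockwork") regime plus the discrete
clockwork propagator used for large-m scenario runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg
import scipy.stats
from scipy.integrate import solve_ivp

from .network import RecruitmentNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "StateDistribution",
    "Trajectory",
    "generator_matrix",
    "master_equation_rhs",
    "propagate",
    "stationary_distribution",
    "sample_trajectory",
    "sample_ensemble",
    "landmark_waiting_time_pdf",
    "embedded_jump_probability",
    "embedded_transition_matrix",
    "expand_substeps",
    "clockwork_propagate",
]

_SIMPLEX_TOL = 1e-9
_RENORM_TOL = 1e-7


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector over recruitment states at a time point."""

    probs: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 1:
            raise ValueError("probs must be a 1-D vector")
        if probs.min() < -_SIMPLEX_TOL:
            raise ValueError(f"negative probability: min={probs.min()}")
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {probs.sum()}")
        probs = np.clip(probs, 0.0, None)
        probs = probs / probs.sum()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @property
    def n_states(self) -> int:
        return self.probs.size


@dataclass(frozen=True)
class Trajectory:
    """One exact stochastic realization: jump times and visited states.

    ``states[0]`` is occupied on ``[0, jump_times[0])``; ``states[k]`` from
    ``jump_times[k-1]`` on.
    """

    jump_times: np.ndarray
    states: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.jump_times, dtype=float)
        states = np.asarray(self.states, dtype=int)
        if times.size != states.size - 1:
            raise ValueError("need exactly one more state than jump times")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "jump_times", times)
        object.__setattr__(self, "states", states)

    def state_at(self, t: float) -> int:
        k = int(np.searchsorted(self.jump_times, t, side="right"))
        return int(self.states[k])


def generator_matrix(net: RecruitmentNetwork) -> np.ndarray:
    """Dense generator Q with Q[i, j] = lambda_ij and Q[i, i] = -sum_j lambda_ij."""
    q = np.array(net.rates)
    q[np.diag_indices_from(q)] = -net.total_exit_rates
    return q


def master_equation_rhs(net: RecruitmentNetwork, dist: StateDistribution) -> np.ndarray:
    """Rate of change of the state distribution, ``Q.T @ p``.

    Inflow ``sum_j lambda_ji p_j`` minus outflow ``p_i sum_j lambda_ij``;
    components sum to zero (probability conservation).
    """
    if dist.n_states != net.n_states:
        raise ValueError(
            f"distribution has {dist.n_states} states, network {net.n_states}"
        )
    p = dist.probs
    return net.rates.T @ p - net.total_exit_rates * p


def _as_distributions(times: np.ndarray, probs: np.ndarray) -> list[StateDistribution]:
    out = []
    for k, t in enumerate(times):
        p = probs[:, k]
        drift = abs(p.sum() - 1.0)
        if drift > _RENORM_TOL:
            logger.warning("probability drift %.3e at t=%g; renormalizing", drift, t)
        p = np.clip(p, 0.0, None)
        out.append(StateDistribution(probs=p / p.sum(), time=float(t)))
    return out


def propagate(
    net: RecruitmentNetwork,
    dist0: StateDistribution,
    time_grid,
    method: str = "bdf",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[StateDistribution]:
    """Integrate the master equation over a non-decreasing time grid.

    ``method="bdf"`` uses a stiff-capable implicit integrator; ``"expm"``
    applies the exact matrix-exponential propagator interval by interval
    (sparse ``expm_multiply``), which is preferable for large expanded
    substep networks.
    """
    if dist0.n_states != net.n_states:
        raise ValueError("initial distribution does not match network size")
    times = np.asarray(time_grid, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(times) < 0):
        raise ValueError("time grid must be non-decreasing")

    if method == "expm":
        qt = scipy.sparse.csr_matrix(generator_matrix(net).T)
        probs = np.empty((net.n_states, times.size))
        p = np.array(dist0.probs)
        t_prev = times[0]
        if times[0] != 0.0:
            p = scipy.sparse.linalg.expm_multiply(qt * times[0], p)
        probs[:, 0] = p
        for k in range(1, times.size):
            dt = times[k] - t_prev
            if dt > 0:
                p = scipy.sparse.linalg.expm_multiply(qt * dt, p)
            probs[:, k] = p
            t_prev = times[k]
        return _as_distributions(times, probs)

    if method not in ("bdf", "lsoda"):
        raise ValueError(f"unknown method {method!r}")
    qt = generator_matrix(net).T
    sol = solve_ivp(
        lambda _t, p: qt @ p,
        t_span=(float(times[0] if times[0] < times[-1] else 0.0), float(times[-1])),
        y0=np.array(dist0.probs),
        method="BDF" if method == "bdf" else "LSODA",
        t_eval=times if times[-1] > times[0] else None,
        jac=lambda _t, _p: qt,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    if times[-1] == times[0]:
        probs = np.tile(np.array(dist0.probs)[:, None], (1, times.size))
    else:
        probs = sol.y
    return _as_distributions(times, probs)


def stationary_distribution(net: RecruitmentNetwork) -> StateDistribution:
    """Unique stationary distribution of a strongly connected network."""
    adj = scipy.sparse.csr_matrix((net.rates > 0).astype(int))
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong"
    )
    if n_comp > 1:
        comps = [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]
        raise ValueError(
            f"network is not strongly connected; components: {comps}"
        )
    q = generator_matrix(net)
    ns = scipy.linalg.null_space(q.T)
    if ns.shape[1] != 1:
        raise RuntimeError("generator null space is not one-dimensional")
    pi = ns[:, 0]
    pi = np.abs(pi) / np.abs(pi).sum()
    return StateDistribution(probs=pi, time=np.inf)


def sample_trajectory(
    net: RecruitmentNetwork,
    start_state: int,
    t_max: float,
    seed: int | np.random.Generator | None = None,
) -> Trajectory:
    """Exact event-driven (Gillespie) simulation of one cell.

    Holding time in state i is exponential with the total exit rate; the next
    state is chosen with probability proportional to its rate.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not (0 <= start_state < net.n_states):
        raise ValueError("start_state out of range")
    rng = np.random.default_rng(seed)
    exit_rates = net.total_exit_rates
    # per-state cumulative jump distributions of the embedded chain
    cum = np.cumsum(net.rates / exit_rates[:, None], axis=1)
    times: list[float] = []
    states = [int(start_state)]
    t = 0.0
    s = int(start_state)
    while True:
        t += rng.exponential(1.0 / exit_rates[s])
        if t >= t_max:
            break
        s = int(np.searchsorted(cum[s], rng.random(), side="right"))
        times.append(t)
        states.append(s)
    return Trajectory(
        jump_times=np.array(times),
        states=np.array(states),
        seed=seed if isinstance(seed, int) else None,
    )


def sample_ensemble(
    net: RecruitmentNetwork,
    start_state: int,
    t_max: float,
    n_trajectories: int,
    seed: int | np.random.Generator | None = None,
    track_displacement: bool = False,
):
    """Vectorized exact sampling of many trajectories' endpoints.

    Returns the final states at ``t_max`` as an int array of length
    ``n_trajectories``; with ``track_displacement=True`` also returns the
    signed cumulative displacement (each jump counted as the minimal circular
    step), useful for drift/diffusion checks on ring topologies.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    n = net.n_states
    exit_rates = net.total_exit_rates
    cum = np.cumsum(net.rates / exit_rates[:, None], axis=1)
    states = np.full(n_trajectories, start_state, dtype=np.int64)
    t = np.zeros(n_trajectories)
    disp = np.zeros(n_trajectories, dtype=np.int64)
    active = np.ones(n_trajectories, dtype=bool)
    while active.any():
        idx = np.flatnonzero(active)
        s = states[idx]
        dt = rng.exponential(1.0 / exit_rates[s])
        t_new = t[idx] + dt
        done = t_new >= t_max
        t[idx] = t_new
        active[idx[done]] = False
        move = idx[~done]
        if move.size:
            s_move = states[move]
            u = rng.random(move.size)
            nxt = (cum[s_move] > u[:, None]).argmax(axis=1)
            if track_displacement:
                step = (nxt - s_move + n // 2) % n - n // 2
                disp[move] += step
            states[move] = nxt
    if track_displacement:
        return states, disp
    return states


def landmark_waiting_time_pdf(rate: float, substeps: int, t) -> np.ndarray:
    """Waiting-time density between landmark states with m substeps.

    Each landmark transition is a chain of m exponential substeps of rate
    ``m * rate``, so the landmark waiting time is Erlang(m, m * rate): mean
    ``1 / rate``, variance ``1 / (m * rate**2)``.  m=1 recovers the plain
    exponential; as m grows the law concentrates toward a delta at
    ``1 / rate`` and recruitment works like a clockwork.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    return scipy.stats.gamma.pdf(np.asarray(t, dtype=float), a=substeps,
                                 scale=1.0 / (substeps * rate))


def embedded_jump_probability(net: RecruitmentNetwork, source: int, target: int) -> float:
    """Probability that the transition source->target wins the race of
    competing exponential clocks out of ``source``."""
    total = net.total_exit_rates[source]
    if total <= 0:
        raise ValueError(f"state {source} has no outgoing rate")
    if net.rates[source, target] <= 0:
        raise ValueError(f"no transition {source}->{target}")
    return float(net.rates[source, target] / total)


def embedded_transition_matrix(net: RecruitmentNetwork) -> np.ndarray:
    """Jump-chain matrix T[i, j] = lambda_ij / sum_k lambda_ik."""
    return net.rates / net.total_exit_rates[:, None]


def expand_substeps(net: RecruitmentNetwork, m: int) -> RecruitmentNetwork:
    """Explicit substep expansion of the network into ``N * m`` states.

    Landmark i becomes substate ``i * m``; each transition ``i -> j`` of the
    landmark network is replaced by a chain of m exponential substeps with
    per-substep rate ``m * lambda_ij`` leaving from landmark i's chain...
    For the pure-cycle part every landmark edge gets its own m-substep chain;
    off-cycle transitions are attached at the landmark substates directly
    (shortcuts act between landmarks, not between intermediates).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m == 1:
        return net
    n = net.n_states
    idx = np.arange(n)
    nxt = (idx + 1) % n
    fwd = net.rates[idx, nxt]
    if np.any(fwd <= 0):
        raise ValueError("substep expansion requires a full forward cycle")
    big = np.zeros((n * m, n * m))
    for i in range(n):
        rate_sub = m * fwd[i]
        base = i * m
        for k in range(m - 1):
            big[base + k, base + k + 1] = rate_sub
        big[base + m - 1, ((i + 1) % n) * m] = rate_sub
    # off-cycle edges live on landmark substates
    off = np.array(net.rates)
    off[idx, nxt] = 0.0
    for i, j in zip(*np.nonzero(off)):
        big[i * m, j * m] += off[i, j]
    return RecruitmentNetwork(n_states=n * m, rates=big, substeps=1)


def landmark_marginal(dist: StateDistribution, n_landmarks: int) -> np.ndarray:
    """Aggregate an expanded-network distribution back onto landmarks.

    Substates ``i*m .. (i+1)*m - 1`` all belong to landmark i (they are
    ChIP-invisible intermediates of the transition leaving landmark i).
    """
    m = dist.n_states // n_landmarks
    if m * n_landmarks != dist.n_states:
        raise ValueError("distribution size is not a multiple of n_landmarks")
    return dist.probs.reshape(n_landmarks, m).sum(axis=1)


def clockwork_propagate(
    net: RecruitmentNetwork,
    dist0: StateDistribution,
    n_steps: int,
) -> tuple[np.ndarray, list[StateDistribution]]:
    """Large-m ("clockwork") propagation of the population distribution.

    In the limit of many intermediate substeps the landmark waiting time is
    a delta at ``1 / rate``: between landmarks the population advances
    deterministically, and at each landmark the outgoing edges branch with
    their embedded jump probabilities.  The distribution therefore evolves
    in discrete steps of duration ``1 / cycle_rate``:

        p[k + 1] = T.T @ p[k],   T = embedded transition matrix.

    Requires a uniform forward cycle rate.  Returns ``(times, dists)`` with
    ``n_steps + 1`` entries (including t=0).
    """
    if dist0.n_states != net.n_states:
        raise ValueError("initial distribution does not match network size")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    idx = np.arange(net.n_states)
    fwd = net.rates[idx, (idx + 1) % net.n_states]
    pos = fwd[fwd > 0]
    if pos.size == 0 or not np.allclose(pos, pos[0]):
        raise ValueError("clockwork propagation requires a uniform forward cycle rate")
    dt = 1.0 / float(pos[0])
    tt = embedded_transition_matrix(net).T
    times = np.arange(n_steps + 1) * dt
    p = np.array(dist0.probs)
    dists = [StateDistribution(probs=p, time=0.0)]
    for k in range(1, n_steps + 1):
        p = tt @ p
        dists.append(StateDistribution(probs=p, time=float(times[k])))
    return times, dists
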