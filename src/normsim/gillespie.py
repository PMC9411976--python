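"""Exact stochastic simulation of the cell-state model (Doob-Gillespie).

Each of T cells performs a continuous-time Markov jump process over the
states negative/positive/NRS/NRPS; the population-level reactions and
propensities are::

    N  -> P     N * alpha * (1 + mu * L(t))
    P  -> N     beta * P
    P  -> NR    gamma1 * P
    NR -> N     beta2 * NR
    NR -> NRPS  gamma2 * NR

The N->P propensity varies continuously in time through the decaying LPS
concentration.  It is handled exactly by thinning: between stimulation
events L(t) is non-increasing, so the total propensity evaluated at the
current time bounds all future propensities within the segment.  Candidate
jump times are drawn against that bound and accepted with probability
(actual total)/(bound); rejected candidates advance the clock without a
reaction.  Segments are never stepped across: the clock is capped at the
next stimulation event, where L jumps and the bound is refreshed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigurationError, DomainError
from .params import HOURS_PER_DAY, ModelSpec, RateParameters
from .protocol import StimulationProtocol
from .trajectory import StateTrajectory


@njit(cache=True)
def _gillespie_core(
    t_cells,
    alpha,
    beta,
    beta2,
    gamma1,
    gamma2,
    mu,
    delta_h,
    seg_bounds_h,
    seg_l0,
    report_h,
    seed,
):
    """Simulate on [0, seg_bounds_h[-1]]; report the state just before each
    reporting time.  ``seg_bounds_h`` has one more entry than ``seg_l0``;
    segment i spans [seg_bounds_h[i], seg_bounds_h[i+1]) with initial LPS
    concentration seg_l0[i] at its left edge.  Returns (states, events)."""
    np.random.seed(seed)
    n_rep = report_h.shape[0]
    out = np.zeros((n_rep, 4), dtype=np.int64)
    state = np.zeros(4, dtype=np.int64)
    state[0] = t_cells
    events = 0
    ridx = 0
    t = 0.0
    for seg in range(seg_l0.shape[0]):
        t_seg = seg_bounds_h[seg]
        t_seg_end = seg_bounds_h[seg + 1]
        if t < t_seg:
            t = t_seg
        while t < t_seg_end:
            L_now = seg_l0[seg] * np.exp(-delta_h * (t - t_seg))
            a1_bound = alpha * (1.0 + mu * L_now) * state[0]
            rest = beta * state[1] + gamma1 * state[1] + beta2 * state[2] + gamma2 * state[2]
            bound = a1_bound + rest
            if bound <= 0.0:
                # idle until the next event / end of segment
                while ridx < n_rep and report_h[ridx] <= t_seg_end:
                    out[ridx] = state
                    ridx += 1
                t = t_seg_end
                break
            t_prop = t + np.random.exponential(1.0 / bound)
            if t_prop >= t_seg_end:
                while ridx < n_rep and report_h[ridx] <= t_seg_end:
                    out[ridx] = state
                    ridx += 1
                t = t_seg_end
                break
            # flush reporting times passed strictly before the candidate jump
            while ridx < n_rep and report_h[ridx] <= t_prop:
                out[ridx] = state
                ridx += 1
            L_prop = seg_l0[seg] * np.exp(-delta_h * (t_prop - t_seg))
            a1 = alpha * (1.0 + mu * L_prop) * state[0]
            a2 = beta * state[1]
            a3 = gamma1 * state[1]
            a4 = beta2 * state[2]
            a5 = gamma2 * state[2]
            u = np.random.random() * bound
            if u < a1:
                state[0] -= 1
                state[1] += 1
                events += 1
            elif u < a1 + a2:
                state[1] -= 1
                state[0] += 1
                events += 1
            elif u < a1 + a2 + a3:
                state[1] -= 1
                state[2] += 1
                events += 1
            elif u < a1 + a2 + a3 + a4:
                state[2] -= 1
                state[0] += 1
                events += 1
            elif u < a1 + a2 + a3 + a4 + a5:
                state[2] -= 1
                state[3] += 1
                events += 1
            # else: thinning rejection — clock advances, no reaction
            t = t_prop
    while ridx < n_rep:
        out[ridx] = state
        ridx += 1
    return out, events


@dataclass(frozen=True)
class SimulationRun:
    """One seeded stochastic realisation reported on a time grid."""

    seed: int
    trajectory: StateTrajectory
    event_count: int


@dataclass(frozen=True)
class EnsembleSummary:
    """Mean and standard error over independent stochastic replicates."""

    n_reps: int
    times_h: np.ndarray
    mean: np.ndarray  # (n_times, 4) counts
    se: np.ndarray  # (n_times, 4); NaN when n_reps == 1
    t_cells: float


def _seed_for(base_seed: int, rep: int) -> int:
    """Per-replicate 32-bit seed; independent of replicate evaluation order."""
    ss = np.random.SeedSequence([int(base_seed), int(rep)])
    return int(ss.generate_state(1, np.uint32)[0])


def _segments(protocol: StimulationProtocol, delta: float, t_max_h: float):
    ev_times = protocol.event_times_h
    l0s = protocol.initial_concentrations(delta)
    keep = ev_times < t_max_h
    ev_times, l0s = ev_times[keep], l0s[keep]
    bounds = [0.0]
    seg_l0 = []
    if ev_times.size == 0 or ev_times[0] > 0:
        seg_l0.append(0.0)
        bounds.extend(ev_times.tolist())
    else:
        bounds.extend(ev_times[1:].tolist())
    for l0 in l0s:
        seg_l0.append(float(l0))
    bounds.append(float(t_max_h))
    return np.array(bounds), np.array(seg_l0)


def gillespie_run(
    spec: ModelSpec,
    params: RateParameters,
    protocol: StimulationProtocol,
    t_cells: int,
    t_max_h: float,
    seed: int,
    report_times_h=None,
) -> SimulationRun:
    """One exact stochastic realisation.

    The reported state at each grid time is the state just before that time
    (piecewise-constant interpolation of the jump process).  Identical
    (seed, params, protocol, t_cells) reproduce the trajectory bit for bit.
    """
    spec.validate_params(params)
    if t_cells < 1:
        raise DomainError("t_cells must be >= 1")
    if t_max_h <= 0:
        raise DomainError("t_max_h must be > 0")
    if report_times_h is None:
        report_times_h = np.linspace(0.0, t_max_h, 49)
    report = np.asarray(report_times_h, dtype=float)
    if np.any(report < 0) or np.any(report > t_max_h) or np.any(np.diff(report) <= 0):
        raise DomainError("report times must be increasing within [0, t_max_h]")

    # rates converted to per-hour so the core works in one time unit
    per_h = 1.0 / HOURS_PER_DAY
    bounds, seg_l0 = _segments(protocol, params.delta, t_max_h)
    states, n_events = _gillespie_core(
        np.int64(t_cells),
        params.alpha * per_h,
        params.beta * per_h,
        params.beta2 * per_h,
        params.gamma1 * per_h,
        params.gamma2 * per_h,
        params.mu,
        params.delta * per_h,
        bounds,
        seg_l0,
        report,
        np.uint32(seed % (2**32)),
    )
    lps = np.atleast_1d(np.asarray(protocol.concentration(report, params.delta)))
    traj = StateTrajectory(report, states.astype(float), lps, float(t_cells))
    return SimulationRun(seed=int(seed), trajectory=traj, event_count=int(n_events))


def ensemble(
    spec: ModelSpec,
    params: RateParameters,
    protocol: StimulationProtocol,
    t_cells: int,
    t_max_h: float,
    n_reps: int,
    base_seed: int,
    report_times_h=None,
) -> EnsembleSummary:
    """Mean/SE trajectories over ``n_reps`` independently seeded runs."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be >= 1")
    runs = [
        gillespie_run(
            spec, params, protocol, t_cells, t_max_h,
            seed=_seed_for(base_seed, rep), report_times_h=report_times_h,
        )
        for rep in range(n_reps)
    ]
    stack = np.stack([r.trajectory.states for r in runs])  # (reps, times, 4)
    mean = stack.mean(axis=0)
    if n_reps > 1:
        se = stack.std(axis=0, ddof=1) / np.sqrt(n_reps)
    else:
        se = np.full_like(mean, np.nan)
    return EnsembleSummary(
        n_reps=n_reps,
        times_h=runs[0].trajectory.times_h,
        mean=mean,
        se=se,
        t_cells=float(t_cells),
    )
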