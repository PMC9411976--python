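"""Deterministic (mean-field) formulations of the cell-state models.

The four-state ODE system, with ``aL = alpha * (1 + mu * L(t))``::

    dN/dt    = -aL*N + beta*P + beta2*NR
    dP/dt    =  aL*N - beta*P - gamma1*P
    dNR/dt   =  gamma1*P - (beta2 + gamma2)*NR
    dNRPS/dt =  gamma2*NR

Setting gamma2 = 0 gives the three-state model; additionally gamma1 = 0
(and beta2 = 0) gives the two-state model, whose positive count under a
single decaying dose admits an exact integrating-factor solution evaluated
by :func:`closed_form_two_state`.

Rates are per day; all public time arguments are in hours.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate as sp_integrate

from .errors import DomainError, NumericalError
from .params import HOURS_PER_DAY, ModelSpec, RateParameters
from .protocol import StimulationProtocol
from .trajectory import CellStateCounts, StateTrajectory


def effective_alpha(params: RateParameters, L: float) -> float:
    """LPS-boosted forward rate ``alpha * (1 + mu * L)`` (per day)."""
    if L < 0:
        raise DomainError("LPS concentration must be >= 0")
    return params.alpha * (1.0 + params.mu * L)


def ode_rhs(
    spec: ModelSpec,
    params: RateParameters,
    state: CellStateCounts | np.ndarray,
    L: float,
) -> np.ndarray:
    """Time derivative of (negative, positive, nrs, nrps) counts, per day."""
    spec.validate_params(params)
    y = state.as_array() if isinstance(state, CellStateCounts) else np.asarray(state, float)
    n, p, nr = y[0], y[1], y[2]
    a_l = effective_alpha(params, L)
    d_n = -a_l * n + params.beta * p + params.beta2 * nr
    d_p = a_l * n - params.beta * p - params.gamma1 * p
    d_nr = params.gamma1 * p - (params.beta2 + params.gamma2) * nr
    d_nrps = params.gamma2 * nr
    return np.array([d_n, d_p, d_nr, d_nrps])


def _rhs_fractions(t_h, y, params, l0_seg, t_seg_h):
    # derivative in per-hour units of the state fractions
    L = l0_seg * np.exp(-params.delta * (t_h - t_seg_h) / HOURS_PER_DAY)
    a_l = params.alpha * (1.0 + params.mu * L)
    n, p, nr = y[0], y[1], y[2]
    d_n = -a_l * n + params.beta * p + params.beta2 * nr
    d_p = a_l * n - params.beta * p - params.gamma1 * p
    d_nr = params.gamma1 * p - (params.beta2 + params.gamma2) * nr
    d_nrps = params.gamma2 * nr
    return np.array([d_n, d_p, d_nr, d_nrps]) / HOURS_PER_DAY


def integrate_ode(
    spec: ModelSpec,
    params: RateParameters,
    protocol: StimulationProtocol,
    t_grid_h,
    t_cells: float = 1000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> StateTrajectory:
    """Integrate the mean-field ODE from the all-negative initial condition.

    The integration restarts at every stimulation event, where the ambient
    LPS concentration is discontinuous.  Output states are counts on
    ``t_grid_h`` (strictly increasing, hours).
    """
    spec.validate_params(params)
    t_grid = np.asarray(t_grid_h, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid_h must be a non-empty strictly increasing 1-d array")
    if t_grid[0] < 0:
        raise DomainError("t_grid_h must be >= 0")

    t_end = float(t_grid[-1])
    ev_times = protocol.event_times_h
    l0s = protocol.initial_concentrations(params.delta)
    # segment boundaries: start, interior event times, end
    bounds = np.unique(np.concatenate([[0.0], ev_times[(ev_times > 0) & (ev_times < t_end)], [t_end]]))
    if t_end == 0.0:
        bounds = np.array([0.0, 0.0])

    y = np.array([1.0, 0.0, 0.0, 0.0])
    out = np.empty((t_grid.size, 4))
    filled = 0
    if t_grid[0] == 0.0:
        out[0] = y
        filled = 1
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        # LPS level just after the segment start
        idx = np.searchsorted(ev_times, a, side="right") - 1
        if idx >= 0:
            l0_seg = l0s[idx] * np.exp(-params.delta * (a - ev_times[idx]) / HOURS_PER_DAY)
        else:
            l0_seg = 0.0
        t_eval = t_grid[(t_grid > a) & (t_grid <= b)]
        sol = sp_integrate.solve_ivp(
            _rhs_fractions,
            (a, b),
            y,
            method="LSODA",
            dense_output=True,
            rtol=rtol,
            atol=atol,
            args=(params, l0_seg, a),
        )
        if not sol.success:
            raise NumericalError(f"ODE integration failed on [{a}, {b}]: {sol.message}")
        if t_eval.size:
            out[filled : filled + t_eval.size] = sol.sol(t_eval).T
            filled += t_eval.size
        y = sol.y[:, -1]
    lps = np.asarray(protocol.concentration(t_grid, params.delta))
    return StateTrajectory(t_grid, out * t_cells, np.atleast_1d(lps), t_cells)


def equilibrium_positive(params: RateParameters, t_cells: float = 1000.0) -> float:
    """No-LPS two-state equilibrium positive count ``T * alpha/(alpha+beta)``."""
    if params.alpha + params.beta <= 0:
        raise DomainError("alpha + beta must be > 0")
    return t_cells * params.alpha / (params.alpha + params.beta)


def quasi_equilibrium_positive(
    params: RateParameters, L0: float, t_h: float, t_cells: float = 1000.0
) -> float:
    """Quasi-static positive count with dP/dt = 0 at L = L0*exp(-delta*t).

    Valid when LPS decay is slow relative to the state-switching dynamics;
    reduces to :func:`equilibrium_positive` at L0 = 0 or as t grows.
    """
    if L0 < 0:
        raise DomainError("L0 must be >= 0")
    if t_h < 0:
        raise DomainError("time must be >= 0")
    L = L0 * np.exp(-params.delta * t_h / HOURS_PER_DAY)
    a_l = effective_alpha(params, L)
    if a_l + params.beta <= 0:
        raise DomainError("alpha + beta must be > 0")
    return t_cells * a_l / (a_l + params.beta)


def closed_form_two_state(
    params: RateParameters, L0: float, t_h: float, t_cells: float = 1000.0
) -> float:
    """Exact positive count of the two-state model under one decaying dose.

    With P(0)=0 and L(t) = L0*exp(-delta*t), the integrating-factor solution is

        P(t) = integral_0^t T*alpha*(1 + mu*L(s))
               * exp((alpha+beta)*(s-t) + (alpha*mu*L0/delta)*(e^{-dt} - e^{-ds})) ds

    (t, s in days).  The exponent is <= 0 on the whole range, so the integrand
    is bounded by T*alpha*(1+mu*L0) and the quadrature is well conditioned.
    """
    if L0 < 0:
        raise DomainError("L0 must be >= 0")
    if t_h < 0:
        raise DomainError("time must be >= 0")
    a, b, mu, d = params.alpha, params.beta, params.mu, params.delta
    t = t_h / HOURS_PER_DAY
    if t == 0.0:
        return 0.0
    if L0 == 0.0 or mu == 0.0:
        if a + b == 0:
            return 0.0
        return t_cells * a / (a + b) * (1.0 - np.exp(-(a + b) * t))
    if d == 0.0:
        a_l = a * (1.0 + mu * L0)
        return t_cells * a_l / (a_l + b) * (1.0 - np.exp(-(a_l + b) * t))

    c = a * mu * L0 / d
    e_t = np.exp(-d * t)

    def integrand(s):
        expo = (a + b) * (s - t) + c * (e_t - np.exp(-d * s))
        return t_cells * a * (1.0 + mu * L0 * np.exp(-d * s)) * np.exp(expo)

    val, err = sp_integrate.quad(integrand, 0.0, t, epsabs=1e-10, epsrel=1e-10, limit=200)
    if err > max(1e-6, 1e-8 * abs(val)):
        raise NumericalError(f"quadrature error estimate too large: {err}")
    return float(val)
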