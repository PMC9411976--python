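"""Variance-based global sensitivity analysis by the extended FAST method.

eFAST explores parameter space along sinusoidal search curves: each model
parameter is assigned an integer frequency, with the parameter of interest
carrying a distinguished high frequency ``omega_max`` and all complementary
parameters low, non-interfering frequencies.  The model output along the
curve is Fourier-analysed; the spectral power at ``omega_max`` and its first
M harmonics estimates the first-order index Si, while the power at the
complementary low frequencies estimates the variance *not* involving the
parameter, giving the total-order index STi = 1 - V_complement / V.

A "dummy" parameter that feeds nothing in the model is carried through the
design; its indices estimate the noise floor of the estimator, and a
parameter is only called influential when its indices exceed the dummy's
(the SPARTAN convention).  Several resample curves (random phase shifts)
give replicate index estimates for that test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._batch import integrate_batch
from .errors import ConfigurationError
from .gillespie import ensemble
from .params import ModelSpec, RateParameters, build_rate_parameters
from .protocol import StimulationProtocol
from .trajectory import STATE_NAMES

#: model parameters varied in the standard design: the five transition rates
#: plus the LPS coupling constants, and one inert dummy
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "alpha": (0.01, 1.0),
    "beta": (0.01, 1.0),
    "beta2": (0.01, 1.0),
    "gamma1": (0.01, 1.0),
    "gamma2": (0.01, 1.0),
    "mu": (1.0, 20.0),
    "delta": (0.1, 1.0),
    "dummy": (0.01, 1.0),
}


@dataclass(frozen=True)
class EfastDesign:
    """The full eFAST sampling plan.

    ``sets`` has one row per simulation; rows are grouped in blocks of
    ``n_samples_per_curve`` per (parameter of interest, resample curve).
    """

    names: tuple[str, ...]
    ranges: dict[str, tuple[float, float]]
    n_curves: int
    n_samples_per_curve: int
    m_harmonics: int
    omega_max: int
    sets: np.ndarray  # (n_total, n_params)
    poi_index: np.ndarray  # (n_total,) which parameter owns the block
    curve_index: np.ndarray  # (n_total,)

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.sets, columns=list(self.names))
        df.insert(0, "poi", [self.names[i] for i in self.poi_index])
        df.insert(1, "curve", self.curve_index)
        return df


def _complementary_frequencies(omega_max: int, m_harmonics: int, n_other: int) -> np.ndarray:
    # standard assignment: complementary frequencies stay below
    # omega_max / (2M) so their harmonics cannot alias onto omega_max
    m = omega_max // (2 * m_harmonics)
    if m >= n_other:
        return np.floor(np.linspace(1, m, n_other)).astype(int)
    return np.arange(n_other) % max(m, 1) + 1


def efast_design(
    ranges: Mapping[str, tuple[float, float]],
    n_curves: int = 3,
    n_samples_per_curve: int = 65,
    seed: int = 0,
    m_harmonics: int = 4,
) -> EfastDesign:
    """Generate the eFAST sampling plan.

    Emits exactly ``n_curves * n_samples_per_curve * len(ranges)`` parameter
    sets.  ``n_samples_per_curve`` must exceed ``4 * M**2`` so the highest
    harmonic of the distinguished frequency stays below the Nyquist limit.
    """
    names = tuple(ranges)
    d = len(names)
    if d < 1:
        raise ConfigurationError("need at least one parameter")
    ns = int(n_samples_per_curve)
    m = int(m_harmonics)
    if ns <= 4 * m * m:
        raise ConfigurationError(
            f"n_samples_per_curve must exceed 4*M^2 = {4 * m * m} for M={m}"
        )
    for name, (lo, hi) in ranges.items():
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigurationError(f"invalid range for {name!r}: ({lo}, {hi})")
    omega_max = (ns - 1) // (2 * m)
    omega_others = _complementary_frequencies(omega_max, m, d - 1) if d > 1 else np.empty(0, int)

    rng = np.random.default_rng(seed)
    s = (2.0 * np.pi / ns) * np.arange(ns)
    lows = np.array([ranges[n][0] for n in names])
    spans = np.array([ranges[n][1] - ranges[n][0] for n in names])

    blocks = []
    poi_idx = []
    curve_idx = []
    for i in range(d):
        omega = np.empty(d)
        omega[i] = omega_max
        others = [j for j in range(d) if j != i]
        for j, w in zip(others, omega_others):
            omega[j] = w
        for c in range(n_curves):
            phase = rng.uniform(0.0, 2.0 * np.pi, size=d)
            angle = np.outer(s, omega) + phase  # (ns, d)
            x01 = 0.5 + np.arcsin(np.sin(angle)) / np.pi
            blocks.append(lows + x01 * spans)
            poi_idx.extend([i] * ns)
            curve_idx.extend([c] * ns)
    return EfastDesign(
        names=names,
        ranges=dict(ranges),
        n_curves=int(n_curves),
        n_samples_per_curve=ns,
        m_harmonics=m,
        omega_max=int(omega_max),
        sets=np.vstack(blocks),
        poi_index=np.array(poi_idx),
        curve_index=np.array(curve_idx),
    )


def efast_run(
    design: EfastDesign,
    spec: ModelSpec,
    protocol: StimulationProtocol,
    readout_time_h: float = 16.0,
    t_cells: int = 1000,
    n_replicates: int = 30,
    base_seed: int = 0,
    engine: str = "stochastic",
    base_params: RateParameters | None = None,
) -> np.ndarray:
    """Evaluate the cell-state model for every design row.

    Returns the (replicate-averaged) counts of the four states at
    ``readout_time_h`` as an array of shape ``(n_sets, 4)``.  Design columns
    that are not model parameters (the dummy) feed nothing.  The stochastic
    engine averages ``n_replicates`` seeded runs per set; the ODE engine is
    deterministic and evaluates all sets in one vectorised pass.
    """
    base = base_params or RateParameters(alpha=0.0, beta=0.0)
    cols = {n: j for j, n in enumerate(design.names)}

    def col(name, default):
        if name in cols:
            return design.sets[:, cols[name]]
        return np.full(design.n_sets, default)

    arrays = {
        "alpha": col("alpha", base.alpha),
        "beta": col("beta", base.beta),
        "beta2": col("beta2", base.beta2),
        "gamma1": col("gamma1", base.gamma1),
        "gamma2": col("gamma2", base.gamma2),
        "mu": col("mu", base.mu),
        "delta": col("delta", base.delta),
    }
    if spec.n_states < 4:
        arrays["gamma2"] = np.zeros(design.n_sets)
    if spec.n_states < 3:
        arrays["beta2"] = np.zeros(design.n_sets)
        arrays["gamma1"] = np.zeros(design.n_sets)

    if engine == "ode":
        frac = integrate_batch(arrays, protocol, [readout_time_h])[:, 0, :]
        return frac * t_cells
    if engine != "stochastic":
        raise ConfigurationError(f"unknown engine {engine!r}")
    out = np.empty((design.n_sets, 4))
    for i in range(design.n_sets):
        params = build_rate_parameters(
            ("alpha", "beta", "beta2", "gamma1", "gamma2"),
            [arrays[n][i] for n in ("alpha", "beta", "beta2", "gamma1", "gamma2")],
        ).replace(mu=float(arrays["mu"][i]), delta=float(arrays["delta"][i]))
        summ = ensemble(
            spec, params, protocol, t_cells, t_max_h=readout_time_h,
            n_reps=n_replicates, base_seed=base_seed + i,
            report_times_h=[readout_time_h],
        )
        out[i] = summ.mean[0]
    return out


@dataclass(frozen=True)
class SensitivityResult:
    """First-order (Si) and total-order (STi) indices per parameter/output."""

    names: tuple[str, ...]
    output_names: tuple[str, ...]
    si: pd.DataFrame  # params x outputs, curve-averaged
    sti: pd.DataFrame
    si_curves: np.ndarray  # (n_params, n_outputs, n_curves)
    sti_curves: np.ndarray

    def dummy_floor_pvalues(self, dummy: str = "dummy") -> pd.DataFrame:
        """One-sided t-test across resample curves that the dummy's indices
        exceed zero; large p-values mean the dummy sits at the noise floor."""
        i = self.names.index(dummy)
        rows = {}
        for j, out in enumerate(self.output_names):
            p_si = stats.ttest_1samp(self.si_curves[i, j], 0.0, alternative="greater").pvalue
            p_sti = stats.ttest_1samp(self.sti_curves[i, j], 0.0, alternative="greater").pvalue
            rows[out] = {"p_si": float(p_si), "p_sti": float(p_sti)}
        return pd.DataFrame(rows).T

    def significant_vs_dummy(self, alpha: float = 0.05, dummy: str = "dummy") -> pd.DataFrame:
        """Which parameters have STi significantly above the dummy's.

        Welch's one-sided t-test across resample curves against the dummy's
        replicate indices — the dummy is the empirical noise floor of the
        estimator, so only parameters that beat it are called influential.
        """
        i = self.names.index(dummy)
        rows = {}
        for j, out in enumerate(self.output_names):
            row = {}
            for k, name in enumerate(self.names):
                if name == dummy:
                    continue
                t = stats.ttest_ind(
                    self.sti_curves[k, j], self.sti_curves[i, j],
                    equal_var=False, alternative="greater",
                )
                row[name] = bool(t.pvalue < alpha)
            rows[out] = row
        return pd.DataFrame(rows).T

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (output, parameter, curve, Si, STi)."""
        rows = []
        for i, name in enumerate(self.names):
            for j, out in enumerate(self.output_names):
                for c in range(self.si_curves.shape[2]):
                    rows.append(
                        {
                            "output": out,
                            "parameter": name,
                            "curve": c,
                            "si": self.si_curves[i, j, c],
                            "sti": self.sti_curves[i, j, c],
                        }
                    )
        return pd.DataFrame(rows)


def efast_analyze(
    design: EfastDesign,
    outputs: np.ndarray,
    output_names: tuple[str, ...] | None = None,
) -> SensitivityResult:
    """Fourier-partition output variance into Si and STi per parameter.

    ``outputs`` is ``(n_sets,)`` or ``(n_sets, n_outputs)`` aligned with
    ``design.sets`` rows.  Blocks with zero output variance yield NaN
    indices and a warning.
    """
    y_all = np.asarray(outputs, float)
    if y_all.ndim == 1:
        y_all = y_all[:, None]
    if y_all.shape[0] != design.n_sets:
        raise ConfigurationError("outputs are not aligned with the design")
    if output_names is None:
        output_names = (
            tuple(STATE_NAMES) if y_all.shape[1] == 4
            else tuple(f"y{j}" for j in range(y_all.shape[1]))
        )
    ns = design.n_samples_per_curve
    m = design.m_harmonics
    omega = design.omega_max
    d, n_out, n_curves = design.n_params, y_all.shape[1], design.n_curves
    si = np.full((d, n_out, n_curves), np.nan)
    sti = np.full((d, n_out, n_curves), np.nan)
    degenerate = False
    for i in range(d):
        for c in range(n_curves):
            mask = (design.poi_index == i) & (design.curve_index == c)
            block = y_all[mask]  # (ns, n_out)
            spectrum = np.abs(np.fft.rfft(block, axis=0)) ** 2  # freq 0..ns//2
            nyq = (ns - 1) // 2
            power = spectrum[1 : nyq + 1]  # frequencies 1..nyq
            total = power.sum(axis=0)
            harmonics = np.arange(1, m + 1) * omega
            harmonics = harmonics[harmonics <= nyq]
            d1 = power[harmonics - 1].sum(axis=0)
            d_comp = power[: omega // 2].sum(axis=0)  # frequencies < omega/2
            ok = total > 0
            degenerate |= bool(np.any(~ok))
            si[i, :, c] = np.where(ok, d1 / np.where(ok, total, 1.0), np.nan)
            sti[i, :, c] = np.where(ok, 1.0 - d_comp / np.where(ok, total, 1.0), np.nan)
    if degenerate:
        import warnings

        warnings.warn("zero output variance in at least one eFAST block; indices NaN")
    si_mean = pd.DataFrame(si.mean(axis=2), index=list(design.names), columns=list(output_names))
    sti_mean = pd.DataFrame(sti.mean(axis=2), index=list(design.names), columns=list(output_names))
    return SensitivityResult(
        names=design.names,
        output_names=tuple(output_names),
        si=si_mean,
        sti=sti_mean,
        si_curves=si,
        sti_curves=sti,
    )
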