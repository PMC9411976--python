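"""Rejection-sampling inference for the cell-state models.

The modelling object follows the statsmodels convention: a
:class:`NoRMModel` is constructed from an observation table plus the
stimulation protocols that produced it, and :meth:`NoRMModel.fit` returns a
:class:`NoRMResults` carrying the retained parameter sets, their scores and
a ``summary()`` table.

Fitting draws ``n_samples`` candidate rate vectors from an independent prior
(default U[0.01, 1] per rate), simulates every candidate under every observed
condition, scores the joint root-mean-square deviation between predicted and
observed positive fractions, converts it to an AIC, and retains the
``top_k`` lowest-AIC sets.  The AIC uses the Gaussian-residual form

    AIC = n_obs * ln(RSS / n_obs) + 2 * k

with k the number of free transition rates (4 for the three-state model,
5 for the four-state model); a binomial-likelihood alternative on the raw
positive-cell counts is available via ``aic_mode="binomial"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._batch import predict_positive_fraction
from .errors import ConfigurationError, DomainError
from .gillespie import ensemble
from .params import (
    ModelSpec,
    PriorSpec,
    RateParameters,
    build_rate_parameters,
    sample_parameters,
)
from .protocol import STANDARD_CONDITIONS, StimulationProtocol
from .kinetics import integrate_ode

OBS_COLUMNS = ("condition", "time_h", "fraction_positive")


class ObservationSet:
    """Tidy table of positive-fraction measurements.

    Required columns: ``condition``, ``time_h``, ``fraction_positive``;
    optional: ``protein``, ``cell_type``, ``n_cells``.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(OBS_COLUMNS) - set(frame.columns)
        if missing:
            raise ConfigurationError(f"observations missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise DomainError("observation set is empty")
        frac = frame["fraction_positive"].to_numpy(float)
        if np.any(frac < 0) or np.any(frac > 1):
            raise DomainError("fraction_positive must lie in [0, 1]")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def fractions(self) -> np.ndarray:
        return self.frame["fraction_positive"].to_numpy(float)


def rmsd(predicted, observed) -> float:
    """Root-mean-square deviation between aligned predictions and observations."""
    obs = observed.fractions if isinstance(observed, ObservationSet) else np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size == 0:
        raise DomainError("cannot score an empty observation set")
    if pred.shape[-1] != obs.size:
        raise DomainError("predictions are not aligned with observations")
    out = np.sqrt(np.mean((pred - obs) ** 2, axis=-1))
    return float(out) if out.ndim == 0 else out


def aic(rss: float, n_obs: int, k_params: int) -> float:
    """Gaussian-residual AIC ``n*ln(RSS/n) + 2k``; RSS=0 maps to -inf."""
    if n_obs < 1:
        raise DomainError("n_obs must be >= 1")
    if rss < 0:
        raise DomainError("rss must be >= 0")
    if rss == 0:
        warnings.warn("zero residual sum of squares: AIC degenerate (-inf)")
        return -np.inf
    return float(n_obs * np.log(rss / n_obs) + 2 * k_params)


class NoRMModel:
    """Cell-state transition model bound to an observation table.

    Parameters
    ----------
    observations
        :class:`ObservationSet` or a tidy DataFrame with the same columns.
    protocols
        Mapping from condition label to :class:`StimulationProtocol`.  When
        omitted, condition labels are looked up among the standard
        pre-treatment conditions (Media/1000, 10/1000, 1000/1000).
    n_states
        2, 3 or 4; fixes which rates are free (see :class:`ModelSpec`).
    t_cells
        In-silico population size used by the stochastic engine.
    mu, delta
        Fixed LPS coupling coefficient and decay rate (per day).
    """

    def __init__(
        self,
        observations: ObservationSet | pd.DataFrame,
        protocols: Mapping[str, StimulationProtocol] | None = None,
        n_states: int = 3,
        t_cells: int = 1000,
        mu: float = 10.0,
        delta: float = 0.5,
        dt_h: float = 0.1,
    ):
        self.observations = (
            observations
            if isinstance(observations, ObservationSet)
            else ObservationSet(observations)
        )
        self.spec = ModelSpec(n_states=n_states)
        self.t_cells = int(t_cells)
        self.mu = float(mu)
        self.delta = float(delta)
        self.dt_h = float(dt_h)
        if protocols is None:
            protocols = STANDARD_CONDITIONS
        missing = set(self.observations.conditions) - set(protocols)
        if missing:
            raise ConfigurationError(f"no protocol for conditions: {sorted(missing)}")
        self.protocols = {c: protocols[c] for c in self.observations.conditions}
        # per-condition observation layout (record indices and sorted times)
        self._layout = []
        frame = self.observations.frame
        for cond in self.observations.conditions:
            idx = np.flatnonzero((frame["condition"] == cond).to_numpy())
            times = frame.loc[idx, "time_h"].to_numpy(float)
            order = np.argsort(times, kind="stable")
            self._layout.append((cond, idx[order], times[order]))
            if np.any(np.diff(times[order]) == 0):
                raise ConfigurationError(
                    f"duplicate measurement times within condition {cond!r}"
                )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "NoRMModel":
        return cls(ObservationSet(frame), **kwargs)

    # ---- prediction -----------------------------------------------------

    def predict_batch(self, free_values: np.ndarray, engine: str = "ode",
                      n_replicates: int = 3, base_seed: int = 0) -> np.ndarray:
        """Predicted positive fractions, shape (n_sets, n_records)."""
        free_values = np.atleast_2d(np.asarray(free_values, float))
        names = self.spec.free_parameter_names
        if free_values.shape[1] != len(names):
            raise ConfigurationError(
                f"expected {len(names)} free values {names}, got shape {free_values.shape}"
            )
        n = free_values.shape[0]
        pred = np.empty((n, len(self.observations)))
        arrays = {name: free_values[:, j] for j, name in enumerate(names)}
        for name in ("beta2", "gamma1", "gamma2"):
            arrays.setdefault(name, np.zeros(n))
        arrays["mu"] = np.full(n, self.mu)
        arrays["delta"] = np.full(n, self.delta)
        if engine == "ode":
            for cond, idx, times in self._layout:
                pred[:, idx] = predict_positive_fraction(
                    arrays, self.protocols[cond], times, dt_h=self.dt_h
                )
        elif engine == "gillespie":
            for i in range(n):
                params = build_rate_parameters(names, free_values[i]).replace(
                    mu=self.mu, delta=self.delta
                )
                for cond, idx, times in self._layout:
                    summ = ensemble(
                        self.spec, params, self.protocols[cond], self.t_cells,
                        t_max_h=float(times[-1]), n_reps=n_replicates,
                        base_seed=int(base_seed) + i, report_times_h=times,
                    )
                    pred[i, idx] = summ.mean[:, 1] / self.t_cells
        else:
            raise ConfigurationError(f"unknown engine {engine!r}")
        return pred

    def predict(self, params: RateParameters) -> np.ndarray:
        """Predicted positive fraction for each observation record."""
        self.spec.validate_params(params)
        values = [getattr(params, n) for n in self.spec.free_parameter_names]
        return self.predict_batch(np.array([values]))[0]

    def simulate(self, params: RateParameters, condition: str, t_grid_h):
        """Reference-accuracy deterministic trajectory for one condition."""
        return integrate_ode(self.spec, params, self.protocols[condition],
                             t_grid_h, t_cells=self.t_cells)

    # ---- scoring --------------------------------------------------------

    def _scores(self, pred: np.ndarray, aic_mode: str) -> tuple[np.ndarray, np.ndarray]:
        obs = self.observations.fractions
        n_obs = obs.size
        k = self.spec.k_free
        resid = pred - obs[None, :]
        rss = np.einsum("ij,ij->i", resid, resid)
        rmsd_vals = np.sqrt(rss / n_obs)
        if aic_mode == "gaussian":
            with np.errstate(divide="ignore"):
                aic_vals = np.where(
                    rss > 0, n_obs * np.log(np.maximum(rss, 1e-300) / n_obs) + 2 * k, -np.inf
                )
        elif aic_mode == "binomial":
            if "n_cells" not in self.observations.frame:
                raise ConfigurationError("binomial AIC requires an n_cells column")
            n_cells = self.observations.frame["n_cells"].to_numpy(float)
            x = np.round(obs * n_cells)
            p = np.clip(pred, 1e-12, 1 - 1e-12)
            loglik = (x[None, :] * np.log(p) + (n_cells - x)[None, :] * np.log1p(-p)).sum(axis=1)
            aic_vals = -2.0 * loglik + 2 * k
        else:
            raise ConfigurationError(f"unknown aic_mode {aic_mode!r}")
        return rmsd_vals, aic_vals

    # ---- fitting --------------------------------------------------------

    def fit(
        self,
        n_samples: int = 100_000,
        top_k: int = 50,
        prior: PriorSpec | None = None,
        seed: int = 0,
        engine: str = "ode",
        aic_mode: str = "gaussian",
        n_replicates: int = 3,
        chunk_size: int = 100_000,
    ) -> "NoRMResults":
        """Rejection-sampling fit: keep the ``top_k`` lowest-AIC draws."""
        if n_samples < top_k:
            raise ConfigurationError("n_samples must be >= top_k")
        prior = prior or PriorSpec.uniform()
        names = self.spec.free_parameter_names
        rng = np.random.default_rng(seed)
        n_failed = 0
        kept_values: list[np.ndarray] = []
        kept_rmsd: list[np.ndarray] = []
        kept_aic: list[np.ndarray] = []
        done = 0
        while done < n_samples:
            m = min(chunk_size, n_samples - done)
            values = sample_parameters(prior, names, m, rng)
            try:
                pred = self.predict_batch(values, engine=engine,
                                          n_replicates=n_replicates, base_seed=seed + done)
            except Exception as exc:  # engine failure: drop the chunk set-wise
                warnings.warn(f"prediction failed for a chunk of {m} sets: {exc}")
                n_failed += m
                done += m
                continue
            ok = np.isfinite(pred).all(axis=1)
            n_failed += int((~ok).sum())
            rmsd_vals, aic_vals = self._scores(pred[ok], aic_mode)
            order = np.argsort(aic_vals, kind="stable")[:top_k]
            kept_values.append(values[ok][order])
            kept_rmsd.append(rmsd_vals[order])
            kept_aic.append(aic_vals[order])
            done += m
        if not kept_aic or sum(len(a) for a in kept_aic) < top_k:
            raise ConfigurationError("not enough successful simulations to fill top_k")
        all_values = np.concatenate(kept_values)
        all_rmsd = np.concatenate(kept_rmsd)
        all_aic = np.concatenate(kept_aic)
        order = np.argsort(all_aic, kind="stable")[:top_k]
        table = pd.DataFrame(all_values[order], columns=list(names))
        table["rmsd"] = all_rmsd[order]
        table["aic"] = all_aic[order]
        return NoRMResults(
            model=self,
            table=table,
            n_sampled=n_samples,
            n_failed=n_failed,
            seed=int(seed),
            prior=prior,
            engine=engine,
            aic_mode=aic_mode,
        )


@dataclass
class NoRMResults:
    """Retained parameter sets and scores from a rejection-sampling fit."""

    model: NoRMModel
    table: pd.DataFrame  # top_k rows, ascending AIC
    n_sampled: int
    n_failed: int
    seed: int
    prior: PriorSpec
    engine: str
    aic_mode: str = "gaussian"

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def free_names(self) -> tuple[str, ...]:
        return self.model.spec.free_parameter_names

    @property
    def best_params(self) -> RateParameters:
        row = self.table.iloc[0]
        return build_rate_parameters(
            self.free_names, [row[n] for n in self.free_names]
        ).replace(mu=self.model.mu, delta=self.model.delta)

    @property
    def aic_mean(self) -> float:
        return float(self.table["aic"].mean())

    @property
    def rmsd_best(self) -> float:
        return float(self.table["rmsd"].min())

    def envelope(self, name: str, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
        """Percentile envelope of one parameter over the retained sets."""
        vals = self.table[name].to_numpy()
        return float(np.percentile(vals, lo)), float(np.percentile(vals, hi))

    def predict(self, condition: str, t_grid_h):
        """Best-set deterministic trajectory for ``condition``."""
        return self.model.simulate(self.best_params, condition, t_grid_h)

    def summary(self) -> str:
        lines = [
            f"NoRM rejection-sampling fit ({self.spec.n_states}-state model)",
            f"  observations: {len(self.model.observations)} records, "
            f"{len(self.model.observations.conditions)} conditions",
            f"  sampled: {self.n_sampled} sets "
            f"({self.n_failed} failed), prior: {self.prior.family}, engine: {self.engine}",
            f"  retained: {len(self.table)} sets | mean AIC {self.aic_mean:.3f} | "
            f"best RMSD {self.rmsd_best:.5f}",
            "  parameter   median     2.5%    97.5%   (per day)",
        ]
        for name in self.free_names:
            med = float(self.table[name].median())
            lo, hi = self.envelope(name)
            lines.append(f"  {name:<10} {med:8.4f} {lo:8.4f} {hi:8.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "n_states": self.spec.n_states,
            "n_sampled": self.n_sampled,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "prior": self.prior.family,
            "engine": self.engine,
            "aic_mode": self.aic_mode,
            "mean_aic": self.aic_mean,
            "best_rmsd": self.rmsd_best,
            "sets": self.table.to_dict(orient="records"),
        }

    def plot_fit(self, condition: str, ax=None, t_grid_h=None):
        """Overlay the best-set trajectory on the observations (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        frame = self.model.observations.frame
        sub = frame[frame["condition"] == condition]
        if t_grid_h is None:
            t_grid_h = np.linspace(0, float(sub["time_h"].max()), 200)[1:]
        traj = self.predict(condition, t_grid_h)
        ax.plot(traj.times_h, traj.positive_fraction, label="best fit")
        ax.plot(sub["time_h"], sub["fraction_positive"], "ro", label="observed")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("positive fraction")
        ax.set_title(condition)
        ax.legend()
        return ax


@dataclass(frozen=True)
class ModelComparison:
    """AIC comparison of two fits to the same observations."""

    mean_aic: dict[int, float]
    delta_aic: float  # mean AIC (smaller model) - mean AIC (larger model)
    preferred_n_states: int

    def summary(self) -> str:
        states = sorted(self.mean_aic)
        lines = ["Model comparison (mean AIC over retained sets)"]
        for s in states:
            mark = "  <-- preferred" if s == self.preferred_n_states else ""
            lines.append(f"  {s}-state: {self.mean_aic[s]:.3f}{mark}")
        lines.append(f"  delta AIC: {self.delta_aic:.3f}")
        return "\n".join(lines)


def compare_models(fit_a: NoRMResults, fit_b: NoRMResults) -> ModelComparison:
    """Prefer the model with the lower mean AIC over its retained sets."""
    obs_a, obs_b = fit_a.model.observations.frame, fit_b.model.observations.frame
    if not obs_a[list(OBS_COLUMNS)].equals(obs_b[list(OBS_COLUMNS)]):
        raise ConfigurationError("fits were produced against different observations")
    small, large = sorted([fit_a, fit_b], key=lambda r: r.spec.n_states)
    if small.spec.n_states == large.spec.n_states:
        raise ConfigurationError("fits use the same n_states; nothing to compare")
    means = {r.spec.n_states: r.aic_mean for r in (small, large)}
    preferred = min(means, key=means.get)
    return ModelComparison(
        mean_aic=means,
        delta_aic=means[small.spec.n_states] - means[large.spec.n_states],
        preferred_n_states=preferred,
    )


def rmsd_convergence(
    model: NoRMModel,
    checkpoints: Sequence[int],
    prior: PriorSpec | None = None,
    seed: int = 0,
    top_k: int = 50,
    chunk_size: int = 50_000,
) -> pd.DataFrame:
    """Best-so-far and top-k-average RMSD after each checkpoint of draws.

    Both statistics are running functions of a single sample stream, so both
    columns are non-increasing in the number of draws; the relative
    improvement between consecutive checkpoints flags the plateau.
    """
    checkpoints = list(checkpoints)
    if any(b <= a for a, b in zip(checkpoints, checkpoints[1:])) or not checkpoints:
        raise ConfigurationError("checkpoints must be strictly increasing and non-empty")
    prior = prior or PriorSpec.uniform()
    rng = np.random.default_rng(seed)
    names = model.spec.free_parameter_names
    total = checkpoints[-1]
    pool = np.empty(0)
    rows = []
    done = 0
    next_cp = iter(checkpoints)
    cp = next(next_cp)
    best = np.inf
    while done < total:
        m = min(chunk_size, cp - done)
        values = sample_parameters(prior, names, m, rng)
        pred = model.predict_batch(values)
        rmsd_vals, _ = model._scores(pred, "gaussian")
        best = min(best, float(rmsd_vals.min()))
        pool = np.sort(np.concatenate([pool, rmsd_vals]))[: max(top_k, 1)]
        done += m
        if done == cp:
            rows.append(
                {
                    "n_sampled": done,
                    "best_rmsd": best,
                    "topk_mean_rmsd": float(pool[: min(top_k, pool.size)].mean()),
                }
            )
            try:
                cp = next(next_cp)
            except StopIteration:
                break
    out = pd.DataFrame(rows)
    prev = out["best_rmsd"].shift(1)
    out["rel_improvement"] = np.where(prev > 0, (prev - out["best_rmsd"]) / prev, np.nan)
    return out
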