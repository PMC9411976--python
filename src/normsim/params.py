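"""Rate parameters, model specification, and prior distributions.

The cell-state model tracks a fixed population of T cells, each of which is in
one of four states with respect to a single inflammatory protein:

* ``negative`` (N) — not producing the protein but able to respond,
* ``positive`` (P) — producing the protein,
* ``nrs`` (NR) — reversibly non-responsive,
* ``nrps`` (NRPS) — permanently (absorbingly) non-responsive.

Transitions occur at constant per-cell rates except for N→P, whose rate is
boosted by the ambient LPS concentration, ``alpha * (1 + mu * L)``.  All rates
are expressed per day; public interfaces accept time in hours and convert.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

HOURS_PER_DAY = 24.0

#: canonical ordering of the estimable transition rates
RATE_NAMES = ("alpha", "beta", "beta2", "gamma1", "gamma2")


@dataclass(frozen=True)
class RateParameters:
    """Transition rates (per day) plus the fixed LPS coupling constants.

    Parameters
    ----------
    alpha
        Baseline negative→positive rate in the absence of LPS.
    beta
        Positive→negative relaxation rate.
    beta2
        NRS→negative recovery rate.
    gamma1
        Positive→NRS silencing rate.
    gamma2
        NRS→NRPS permanent-silencing rate.
    mu
        Dimensionless LPS response coefficient multiplying the normalized
        LPS concentration in the forward rate ``alpha * (1 + mu * L)``.
    delta
        First-order LPS decay rate (per day).
    """

    alpha: float
    beta: float
    beta2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    mu: float = 10.0
    delta: float = 0.5

    def __post_init__(self) -> None:
        for name in RATE_NAMES + ("mu", "delta"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {value!r}")

    def replace(self, **kwargs: float) -> "RateParameters":
        return replace(self, **kwargs)

    def rates_array(self) -> np.ndarray:
        """The five transition rates in canonical order."""
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """Which nested variant of the model is in play.

    ``n_states=2`` frees (alpha, beta); ``3`` adds (beta2, gamma1); ``4`` adds
    gamma2.  ``mu`` and ``delta`` are never free.  Setting gamma2=0 collapses
    the four-state model onto the three-state one, and additionally
    gamma1=0 collapses onto the two-state model.
    """

    n_states: int = 3

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3, 4):
            raise ConfigurationError(f"n_states must be 2, 3 or 4, got {self.n_states}")

    @property
    def free_parameter_names(self) -> tuple[str, ...]:
        if self.n_states == 2:
            return ("alpha", "beta")
        if self.n_states == 3:
            return ("alpha", "beta", "beta2", "gamma1")
        return ("alpha", "beta", "beta2", "gamma1", "gamma2")

    @property
    def k_free(self) -> int:
        return len(self.free_parameter_names)

    def validate_params(self, params: RateParameters) -> None:
        """Raise if ``params`` activate transitions the spec excludes."""
        if self.n_states < 4 and params.gamma2 != 0:
            raise ConfigurationError(
                f"gamma2 must be 0 for an n_states={self.n_states} model"
            )
        if self.n_states < 3 and (params.gamma1 != 0 or params.beta2 != 0):
            raise ConfigurationError("gamma1 and beta2 must be 0 for a 2-state model")


@dataclass(frozen=True)
class PriorSpec:
    """Independent prior over each free transition rate, truncated to [0, inf).

    Supported families: ``uniform`` (low, high), ``normal`` (mean, sd, sampled
    by rejection to respect the truncation) and ``gamma`` (a, b, with ``b``
    read as the scale by default or as the rate when ``convention='rate'``).
    """

    family: str = "uniform"
    low: float = 0.01
    high: float = 1.0
    mean: float = 0.03
    sd: float = 0.01
    a: float = 0.68
    b: float = 0.2
    convention: str = "scale"

    @classmethod
    def uniform(cls, low: float = 0.01, high: float = 1.0) -> "PriorSpec":
        return cls(family="uniform", low=low, high=high)

    @classmethod
    def truncated_normal(cls, mean: float = 0.03, sd: float = 0.01) -> "PriorSpec":
        return cls(family="normal", mean=mean, sd=sd)

    @classmethod
    def gamma(cls, a: float = 0.68, b: float = 0.2, convention: str = "scale") -> "PriorSpec":
        return cls(family="gamma", a=a, b=b, convention=convention)

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "normal", "gamma"):
            raise ConfigurationError(f"unknown prior family {self.family!r}")
        if self.family == "uniform" and not (0 <= self.low < self.high):
            raise ConfigurationError("uniform prior requires 0 <= low < high")
        if self.family == "normal" and self.sd <= 0:
            raise ConfigurationError("normal prior requires sd > 0")
        if self.family == "gamma" and (self.a <= 0 or self.b <= 0):
            raise ConfigurationError("gamma prior requires a > 0 and b > 0")
        if self.convention not in ("scale", "rate"):
            raise ConfigurationError("gamma convention must be 'scale' or 'rate'")

    def sample(self, size: int | tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        if self.family == "uniform":
            return rng.uniform(self.low, self.high, size=size)
        if self.family == "gamma":
            scale = self.b if self.convention == "scale" else 1.0 / self.b
            return rng.gamma(self.a, scale, size=size)
        # truncated normal by rejection; the truncation point is 0
        out = rng.normal(self.mean, self.sd, size=size)
        bad = out < 0
        while np.any(bad):
            out[bad] = rng.normal(self.mean, self.sd, size=int(bad.sum()))
            bad = out < 0
        return out


def sample_parameters(
    prior: PriorSpec,
    free_names: Sequence[str],
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` independent parameter sets from ``prior``.

    Returns an array of shape ``(n, len(free_names))`` in the order given.
    Reproducible: an integer ``seed`` always yields the same draws.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    unknown = set(free_names) - set(RATE_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown free parameters: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return prior.sample((n, len(free_names)), rng)


def build_rate_parameters(
    free_names: Iterable[str],
    values: Iterable[float],
    base: RateParameters | None = None,
) -> RateParameters:
    """Assemble a full :class:`RateParameters` from free values plus a base."""
    base = base or RateParameters(alpha=0.0, beta=0.0)
    return base.replace(**dict(zip(free_names, values)))
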