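"""State-count containers and tidy trajectory tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

STATE_NAMES = ("negative", "positive", "nrs", "nrps")


@dataclass(frozen=True)
class CellStateCounts:
    """Cells per state; the total is conserved over time."""

    negative: float
    positive: float
    nrs: float = 0.0
    nrps: float = 0.0

    def __post_init__(self) -> None:
        if min(self.negative, self.positive, self.nrs, self.nrps) < 0:
            raise DomainError("state counts must be >= 0")

    @property
    def total(self) -> float:
        return self.negative + self.positive + self.nrs + self.nrps

    def as_array(self) -> np.ndarray:
        return np.array([self.negative, self.positive, self.nrs, self.nrps])


@dataclass(frozen=True)
class StateTrajectory:
    """Cell-state counts and LPS concentration on a reporting time grid.

    ``states`` has shape ``(n_times, 4)`` in the order
    (negative, positive, nrs, nrps); ``lps`` is the normalized concentration
    at each reporting time.
    """

    times_h: np.ndarray
    states: np.ndarray
    lps: np.ndarray
    t_cells: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(self, "states", np.asarray(self.states, dtype=float))
        object.__setattr__(self, "lps", np.asarray(self.lps, dtype=float))
        if self.states.shape != (self.times_h.size, 4):
            raise DomainError("states must have shape (n_times, 4)")

    @property
    def fractions(self) -> np.ndarray:
        return self.states / self.t_cells

    @property
    def positive_fraction(self) -> np.ndarray:
        return self.states[:, 1] / self.t_cells

    def max_conservation_error(self) -> float:
        return float(np.abs(self.states.sum(axis=1) - self.t_cells).max())

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time, LPS, then counts and fractions per state."""
        df = pd.DataFrame({"time_h": self.times_h, "lps": self.lps})
        for j, name in enumerate(STATE_NAMES):
            df[name] = self.states[:, j]
        for j, name in enumerate(STATE_NAMES):
            df[f"frac_{name}"] = self.states[:, j] / self.t_cells
        return df
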