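"""Timed LPS stimulation protocols and the ambient-concentration model.

LPS concentration is expressed in normalized units where a 1000 ng/ml dose
maps to 1.0 (so the standard titration 1/10/100/1000 ng/ml becomes
0.001/0.01/0.1/1.0).  Between stimulation events the concentration decays
exponentially at rate ``delta`` per day.  At a re-stimulation event, residual
LPS from earlier doses is by default washed out (set to zero) before the new
dose is applied, mirroring a PBS wash; setting ``washout=False`` on an event
adds the new dose on top of the residual instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError
from .params import HOURS_PER_DAY

#: dose (ng/ml) that maps to a normalized concentration of 1.0
DOSE_NORMALIZATION_NG_ML = 1000.0


@dataclass(frozen=True)
class StimulationEvent:
    time_h: float
    dose_ng_ml: float
    washout: bool = True

    def __post_init__(self) -> None:
        if self.dose_ng_ml < 0:
            raise ConfigurationError("dose must be >= 0")
        if self.time_h < 0:
            raise ConfigurationError("event time must be >= 0")

    @property
    def dose_normalized(self) -> float:
        return self.dose_ng_ml / DOSE_NORMALIZATION_NG_ML


@dataclass(frozen=True)
class StimulationProtocol:
    """An ordered sequence of timed LPS doses."""

    events: tuple[StimulationEvent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        events = tuple(
            e if isinstance(e, StimulationEvent) else StimulationEvent(*e)
            for e in self.events
        )
        object.__setattr__(self, "events", events)
        times = [e.time_h for e in events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ConfigurationError("event times must be strictly increasing")

    @property
    def event_times_h(self) -> np.ndarray:
        return np.array([e.time_h for e in self.events], dtype=float)

    def initial_concentrations(self, delta: float) -> np.ndarray:
        """Normalized concentration immediately after each event.

        Without washout the residual from earlier events carries over; the
        residual depends on ``delta``, so it is recomputed per decay rate.
        """
        l0 = np.empty(len(self.events))
        prev_l0, prev_t = 0.0, 0.0
        for i, ev in enumerate(self.events):
            residual = prev_l0 * np.exp(-delta * (ev.time_h - prev_t) / HOURS_PER_DAY)
            l0[i] = ev.dose_normalized + (0.0 if ev.washout else residual)
            prev_l0, prev_t = l0[i], ev.time_h
        return l0

    def concentration(self, t_h, delta: float) -> np.ndarray | float:
        """Normalized LPS concentration at time(s) ``t_h`` (hours)."""
        if delta < 0:
            raise DomainError("delta must be >= 0")
        t = np.asarray(t_h, dtype=float)
        scalar = t.ndim == 0
        t1 = np.atleast_1d(t)
        if np.any(t1 < 0):
            raise DomainError("time must be >= 0")
        out = np.zeros_like(t1)
        if self.events:
            l0 = self.initial_concentrations(delta)
            times = self.event_times_h
            idx = np.searchsorted(times, t1, side="right") - 1
            has = idx >= 0
            out[has] = l0[idx[has]] * np.exp(
                -delta * (t1[has] - times[idx[has]]) / HOURS_PER_DAY
            )
        return float(out[0]) if scalar else out

    def with_horizon(self, t_max_h: float) -> "StimulationProtocol":
        """Drop events beyond ``t_max_h``."""
        return StimulationProtocol(
            tuple(e for e in self.events if e.time_h <= t_max_h)
        )


def lps_concentration(protocol: StimulationProtocol, t_h, delta: float = 0.5):
    """Normalized LPS concentration under ``protocol`` at ``t_h`` hours."""
    return protocol.concentration(t_h, delta)


def single_dose(dose_ng_ml: float, time_h: float = 0.0) -> StimulationProtocol:
    return StimulationProtocol((StimulationEvent(time_h, dose_ng_ml),))


def pretreatment_protocol(
    primary_dose_ng_ml: float,
    challenge_dose_ng_ml: float = 1000.0,
    challenge_time_h: float = 24.0,
    washout: bool = True,
) -> StimulationProtocol:
    """Pre-treatment followed by a challenge dose (e.g. 10/1000, 1000/1000).

    A zero primary dose (media pre-treatment) yields a single challenge event.
    """
    events = []
    if primary_dose_ng_ml > 0:
        events.append(StimulationEvent(0.0, primary_dose_ng_ml))
    events.append(StimulationEvent(challenge_time_h, challenge_dose_ng_ml, washout))
    return StimulationProtocol(tuple(events))


#: the three pre-treatment conditions used throughout: media, low- and
#: high-dose pre-treatment, each challenged with 1000 ng/ml at 24 h
STANDARD_CONDITIONS = {
    "Media/1000": pretreatment_protocol(0.0),
    "10/1000": pretreatment_protocol(10.0),
    "1000/1000": pretreatment_protocol(1000.0),
}
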