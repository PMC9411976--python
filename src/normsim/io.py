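"""Reading and writing the package's tabular and configuration formats."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigurationError
from .model import ObservationSet
from .params import ModelSpec, RateParameters
from .protocol import StimulationEvent, StimulationProtocol
from .trajectory import StateTrajectory


def read_observations(path) -> ObservationSet:
    return ObservationSet(pd.read_csv(path))


def write_observations(obs: ObservationSet, path) -> None:
    obs.frame.to_csv(path, index=False)


def write_trajectory(traj: StateTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def write_truth(truth: dict[str, RateParameters], path) -> None:
    payload = {name: asdict(p) for name, p in truth.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> dict[str, RateParameters]:
    payload = json.loads(Path(path).read_text())
    return {name: RateParameters(**vals) for name, vals in payload.items()}


def protocol_from_config(events: list[dict]) -> StimulationProtocol:
    try:
        return StimulationProtocol(
            tuple(
                StimulationEvent(
                    time_h=float(e["time_h"]),
                    dose_ng_ml=float(e["dose_ng_ml"]),
                    washout=bool(e.get("washout", True)),
                )
                for e in events
            )
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed protocol events: {exc}") from exc


def load_config(path) -> dict:
    """Model/experiment configuration from YAML.

    Recognised keys: ``model`` (2|3|4), ``rates`` (mapping of transition
    rates), ``mu``, ``delta``, ``protocol`` (list of events with time_h,
    dose_ng_ml, washout), ``t_grid_h``, ``n_cells``.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    return raw


def build_from_config(cfg: dict):
    """Turn a config mapping into (spec, params, protocol, t_grid_h, n_cells)."""
    try:
        spec = ModelSpec(n_states=int(cfg.get("model", 3)))
        rates = dict(cfg.get("rates", {}))
        params = RateParameters(
            alpha=float(rates.get("alpha", 0.1)),
            beta=float(rates.get("beta", 0.1)),
            beta2=float(rates.get("beta2", 0.0)),
            gamma1=float(rates.get("gamma1", 0.0)),
            gamma2=float(rates.get("gamma2", 0.0)),
            mu=float(cfg.get("mu", 10.0)),
            delta=float(cfg.get("delta", 0.5)),
        )
        protocol = protocol_from_config(cfg.get("protocol", [{"time_h": 0.0, "dose_ng_ml": 1000.0}]))
        t_grid_h = [float(t) for t in cfg.get("t_grid_h", [])]
        n_cells = int(cfg.get("n_cells", 1000))
    except (TypeError, ValueError, KeyError) as exc:
        if isinstance(exc, ConfigurationError):
            raise
        raise ConfigurationError(f"malformed configuration: {exc}") from exc
    spec.validate_params(params)
    return spec, params, protocol, t_grid_h, n_cells
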