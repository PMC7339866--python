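"""Structured-text (YAML/JSON) configuration for the command-line entry points.

Each command takes one config file whose keys mirror the dataclass fields of
the module it drives.  Validation is explicit and errors name the offending
field so a broken config fails fast with a usable message.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .controllers import ControllerConfig
from .dde_core import IntegratorConfig
from .model import ActivationParams, InputSignal, LoopParams
from .surrogate_plant import PiecewiseSchedule, PlantParams, ScenarioSpec

__all__ = ["ConfigError", "load_config", "config_hash",
           "loop_params_from_dict", "input_from_dict", "controller_from_dict",
           "integrator_from_dict", "scenario_from_dict", "plant_from_dict",
           "activation_from_dict"]


class ConfigError(ValueError):
    """A config file failed schema validation; the message names the field."""


def load_config(path) -> dict:
    """Parse a YAML (or JSON) config file into a dict."""
    import yaml

    p = Path(path)
    if not p.is_file():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{p}: top level must be a mapping")
    return data


def config_hash(resolved: dict) -> str:
    """Stable hash of a resolved configuration (for run manifests)."""
    import hashlib

    text = json.dumps(resolved, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _check_keys(d: dict, allowed: set, where: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"{where}: unknown field(s) {sorted(extra)}; "
                          f"allowed: {sorted(allowed)}")


def activation_from_dict(d: dict, where: str = "activation") -> ActivationParams:
    _check_keys(d, {"m", "b", "scale"}, where)
    try:
        return ActivationParams(m=float(d["m"]), b=float(d["b"]),
                                scale=float(d.get("scale", 1.0)))
    except KeyError as exc:
        raise ConfigError(f"{where}: missing field {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def loop_params_from_dict(d: dict, where: str = "model") -> LoopParams:
    if "preset" in d:
        presets = {"endogenous": LoopParams.endogenous,
                   "exogenous": LoopParams.exogenous,
                   "map_template": LoopParams.map_template}
        name = d["preset"]
        if name not in presets:
            raise ConfigError(f"{where}.preset: unknown preset {name!r}; "
                              f"choose from {sorted(presets)}")
        base = presets[name]()
        overrides = {k: v for k, v in d.items() if k != "preset"}
    else:
        base = None
        overrides = dict(d)

    scalar = {"c11", "c12", "c21", "c22", "b1", "b2", "tau1", "tau2",
              "d11", "d12", "d21", "d22"}
    _check_keys(overrides, scalar | {"s1", "s2"}, where)
    kwargs = {}
    for k, v in overrides.items():
        if k in ("s1", "s2"):
            kwargs[k] = activation_from_dict(v, where=f"{where}.{k}")
        else:
            kwargs[k] = float(v)
    try:
        if base is None:
            return LoopParams(**kwargs)
        from dataclasses import replace

        return replace(base, **kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def input_from_dict(d: dict, where: str = "input") -> InputSignal:
    _check_keys(d, {"kind", "level", "amplitude", "frequency_hz",
                    "switch_times_ms", "samples", "sample_dt_ms"}, where)
    kw = dict(d)
    for seq_key in ("level", "amplitude"):
        if isinstance(kw.get(seq_key), list):
            kw[seq_key] = tuple(float(v) for v in kw[seq_key])
    if "switch_times_ms" in kw:
        kw["switch_times_ms"] = tuple(float(v) for v in kw["switch_times_ms"])
    if kw.get("samples") is not None:
        kw["samples"] = np.asarray(kw["samples"], dtype=float)
    try:
        return InputSignal(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def controller_from_dict(d: dict, where: str = "controller") -> ControllerConfig:
    _check_keys(d, {"mode", "theta", "theta0", "tau_theta_ms", "sigma",
                    "target", "window_ms", "t_on_ms", "drive_refresh_ms"}, where)
    try:
        return ControllerConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def integrator_from_dict(d: dict, where: str = "integrator") -> IntegratorConfig:
    _check_keys(d, {"dt", "duration", "method"}, where)
    try:
        return IntegratorConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _schedule_from_dict(d, where: str) -> PiecewiseSchedule:
    if isinstance(d, (int, float)):
        return PiecewiseSchedule.constant(float(d))
    _check_keys(d, {"times", "values", "interp"}, where)
    try:
        return PiecewiseSchedule(times=tuple(float(v) for v in d["times"]),
                                 values=tuple(float(v) for v in d["values"]),
                                 interp=d.get("interp", "previous"))
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def scenario_from_dict(d: dict, where: str = "scenario") -> ScenarioSpec:
    if isinstance(d, str):
        try:
            return ScenarioSpec.by_name(d)
        except ValueError as exc:
            raise ConfigError(f"{where}: {exc}") from exc
    _check_keys(d, {"name", "target_uv", "background_uv", "impedance_kohm",
                    "duration_s"}, where)
    try:
        return ScenarioSpec(
            name=d.get("name", "custom"),
            target_uv=_schedule_from_dict(d["target_uv"], f"{where}.target_uv"),
            background_uv=_schedule_from_dict(d["background_uv"],
                                              f"{where}.background_uv"),
            impedance_kohm=_schedule_from_dict(d["impedance_kohm"],
                                               f"{where}.impedance_kohm"),
            duration_s=float(d.get("duration_s", 130.0)),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def plant_from_dict(d: dict, where: str = "plant") -> PlantParams:
    _check_keys(d, {"background_uv", "impedance_kohm", "i_half_ma", "width_ma",
                    "floor", "noise_uv", "lag_ms", "dt_ms"}, where)
    kw = dict(d)
    for sched in ("background_uv", "impedance_kohm"):
        if sched in kw:
            kw[sched] = _schedule_from_dict(kw[sched], f"{where}.{sched}")
    try:
        return PlantParams(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc
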