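"""Run configuration: flat key/value files (YAML subset or JSON) plus overrides.

Every field has a documented default; unknown keys are rejected by name with
a nearest-valid-key suggestion.  CLI flag overrides are applied after file
values, so the precedence is defaults < file < flags.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .model_core import DEFAULT_ATOL, DEFAULT_RTOL, ModelParams, NutrientParams

__all__ = ["RunConfig", "load_config", "DEFAULTS"]

logger = logging.getLogger("ooidgrowth")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for a model run.

    Kinetic defaults put the model in both the limiting-size regime
    (c*k_b_I - k_m = 0.5 > 0) and the finite-upper-bound regime (0.3 > 0)
    with the canonical time scaling k_b_I = 1; nutrient defaults give an
    outer-layer width w = 1.
    """

    k_m: float = 0.5        # mineralisation rate (1/time)
    k_b: float = 0.1        # outer -> inner transition rate (1/time)
    k_b_I: float = 1.0      # inner-zone decay rate (1/time)
    k_b_II: float = 0.2     # outer-layer growth rate (1/time)
    c: float = 1.0          # biofilm/microbe volume scale factor (-)
    c_I: float = 0.5        # survival-threshold nutrient concentration
    c_II: float = 1.0       # background nutrient concentration
    D: float = 1.0          # nutrient diffusivity (length^2/time)
    k: float = 1.0          # nutrient consumption rate (concentration/time)
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    seed: int = 0
    verbose: bool = False
    out: str | None = None

    def model_params(self) -> ModelParams:
        return ModelParams(k_m=self.k_m, k_b=self.k_b, k_b_I=self.k_b_I,
                           k_b_II=self.k_b_II, c=self.c)

    def nutrient_params(self) -> NutrientParams:
        return NutrientParams(c_I=self.c_I, c_II=self.c_II, D=self.D, k=self.k)


DEFAULTS: dict[str, Any] = {f.name: f.default for f in fields(RunConfig)}
_VALID_KEYS = tuple(DEFAULTS)

_TYPES = {f.name: f.type for f in fields(RunConfig)}


def _coerce(key: str, value: Any) -> Any:
    """Coerce a raw config value to the field's type, with a named error."""
    if key == "out":
        return None if value is None else str(value)
    if key == "verbose":
        if isinstance(value, bool):
            return value
        raise ConfigError(f"config key 'verbose' must be a boolean, got {value!r}")
    if key == "seed":
        try:
            iv = int(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"config key 'seed' must be an integer, got {value!r}") from exc
        return iv
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config key '{key}' must be numeric, got {value!r}") from exc


def _reject_unknown(keys) -> None:
    for key in keys:
        if key not in _VALID_KEYS:
            hint = difflib.get_close_matches(str(key), _VALID_KEYS, n=1)
            suggestion = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown config key '{key}'{suggestion}")


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Load a config file (YAML/JSON mapping; empty file means all defaults)
    and apply overrides on top.  ``None`` values in ``overrides`` are ignored
    (an unset CLI flag does not override the file)."""
    resolved = dict(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse config file {path}: {exc}") from exc
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a key/value mapping")
        _reject_unknown(raw)
        for key, value in raw.items():
            resolved[key] = _coerce(key, value)
    if overrides:
        supplied = {k: v for k, v in overrides.items() if v is not None}
        _reject_unknown(supplied)
        for key, value in supplied.items():
            resolved[key] = _coerce(key, value)
    cfg = RunConfig(**resolved)
    logger.debug("resolved config: %s", cfg)
    return cfg
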