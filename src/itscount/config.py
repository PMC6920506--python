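"""Configuration files: YAML/JSON parsing, validation, default materialization.

A run configuration names a command and a scenario block; every default
(beta0=2.0, beta1=0.1, phi=2, R=200, alpha=0.05, explosion threshold 1e6,
log time transform, equal split, y0=0) is made explicit in the returned
object so that logged configurations always show effective values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .power import DEFAULT_GAMMA1_GRID, DEFAULT_N_GRID, Scenario

__all__ = ["RunConfig", "load_config"]

_COMMANDS = ("simulate", "fit", "test", "power-table", "sample-size")

_SCENARIO_KEYS = {
    "family",
    "n",
    "gamma1",
    "beta2",
    "beta3",
    "total_change",
    "split_rule",
    "split_weight",
    "beta0",
    "beta1",
    "phi",
    "y0",
    "transform",
    "anchor",
    "explosion_threshold",
    "R",
    "alpha",
    "hypothesis",
    "base_seed",
    "estimate_phi",
    "denominator",
    "na_threshold",
}

_TOP_KEYS = {
    "command",
    "scenario",
    "gamma1_grid",
    "n_grid",
    "target_power",
    "n_candidates",
    "out_dir",
    "log_level",
    "base_seed",
}


@dataclass
class RunConfig:
    """Validated configuration with all defaults materialized."""

    scenario: Scenario
    command: str | None = None
    gamma1_grid: list = field(default_factory=lambda: list(DEFAULT_GAMMA1_GRID))
    n_grid: list = field(default_factory=lambda: list(DEFAULT_N_GRID))
    target_power: float | None = None
    n_candidates: list | None = None
    out_dir: str = "."
    log_level: str = "INFO"

    def effective(self) -> dict:
        """The fully-resolved configuration, for logging."""
        d = asdict(self)
        d["scenario"]["hypothesis"] = self.scenario.resolved_hypothesis().kind
        return d


def _validate_scenario(raw: dict) -> Scenario:
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"unknown scenario field(s): {sorted(unknown)}")
    try:
        sc = Scenario(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
    # Scenario.__post_init__ raises ConfigError naming the offending field
    sc.resolved_hypothesis()
    sc.effect()
    return sc


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON configuration file.

    Parse failures raise :class:`ConfigError` carrying the parser's
    line/column information; validation failures name the offending field.
    """
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from None
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a mapping at top level")

    unknown = set(raw) - _TOP_KEYS - _SCENARIO_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")

    command = raw.get("command")
    if command is not None and command not in _COMMANDS:
        raise ConfigError(f"unknown command {command!r}; expected one of {_COMMANDS}")

    # scenario fields may live in a nested block or at top level
    scen_raw = dict(raw.get("scenario") or {})
    for key in _SCENARIO_KEYS:
        if key in raw and key not in scen_raw:
            scen_raw[key] = raw[key]
    if "base_seed" in raw:
        scen_raw["base_seed"] = raw["base_seed"]
    scenario = _validate_scenario(scen_raw)

    target_power = raw.get("target_power")
    if target_power is not None and not (0.0 < float(target_power) < 1.0):
        raise ConfigError(f"target_power must lie in (0, 1), got {target_power}")

    n_candidates = raw.get("n_candidates")
    if n_candidates is not None:
        n_candidates = [int(v) for v in n_candidates]

    return RunConfig(
        scenario=scenario,
        command=command,
        gamma1_grid=[float(g) for g in raw.get("gamma1_grid", DEFAULT_GAMMA1_GRID)],
        n_grid=[int(n) for n in raw.get("n_grid", DEFAULT_N_GRID)],
        target_power=None if target_power is None else float(target_power),
        n_candidates=n_candidates,
        out_dir=str(raw.get("out_dir", ".")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(config.effective(), indent=2, default=str))
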