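"""Run configuration: defaults replicating the reference study, YAML loading
with schema validation, and stable hashing for provenance headers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import yaml

from . import calibration as cal
from .dosimetry import AntennaSpec, ComplianceLimits, ExposureScenario

__all__ = ["RunConfig", "ConfigError", "default_config", "load_config",
           "config_hash"]


class ConfigError(ValueError):
    """Invalid run configuration; the message lists the offending keys."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs.

    ``cohorts`` is a list of (age_group, arm) pairs simulated from the
    default calibration; ``master_seed`` deterministically spawns one child
    seed per cohort, so adding a cohort never perturbs the others.
    """

    antenna: AntennaSpec
    scenarios: dict          # name -> ExposureScenario
    limits: ComplianceLimits
    cohorts: tuple           # of (age_group, arm)
    alpha: float = 0.05
    method: str = "auto"     # mann-whitney method
    continuity: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not 0 < self.alpha < 1:
            problems.append(f"analysis.alpha must lie in (0, 1), got {self.alpha}")
        if self.method not in ("auto", "exact", "approx"):
            problems.append(f"analysis.method must be auto|exact|approx, got {self.method!r}")
        if not isinstance(self.master_seed, int):
            problems.append(f"seed must be an integer, got {self.master_seed!r}")
        for pair in self.cohorts:
            if tuple(pair) not in cal.BODY_WEIGHT_G:
                problems.append(f"cohorts: unknown (age_group, arm) {tuple(pair)!r}")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        return {
            "antenna": asdict(self.antenna),
            "scenarios": {k: asdict(v) for k, v in self.scenarios.items()},
            "limits": asdict(self.limits),
            "cohorts": [list(c) for c in self.cohorts],
            "analysis": {"alpha": self.alpha, "method": self.method,
                         "continuity": self.continuity},
            "seed": self.master_seed,
        }


def config_hash(config: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form (first 12 hex chars)."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def default_config(master_seed: int = 0) -> RunConfig:
    """The reference study: two exposure scenarios, six cohorts."""
    scenarios = {}
    for name, s in cal.EXPOSURE_SCENARIOS.items():
        scenarios[name] = ExposureScenario(
            r_near_m=s["r_near_m"], cage_extent_m=s["cage_extent_m"],
            mean_mass_kg=s["mean_mass_kg"], mean_length_m=s["mean_length_m"],
            name=name)
    cohorts = tuple((age, arm) for age in cal.AGE_GROUPS for arm in cal.ARMS)
    return RunConfig(
        antenna=AntennaSpec(**cal.ANTENNA),
        scenarios=scenarios,
        limits=ComplianceLimits(),
        cohorts=cohorts,
        master_seed=master_seed,
    )


def _pop_block(data: dict, key: str, required: dict, problems: list,
               optional: dict | None = None) -> dict:
    """Extract one mapping block, recording missing/unknown keys."""
    block = data.get(key)
    if block is None:
        return {}
    if not isinstance(block, dict):
        problems.append(f"{key}: expected a mapping")
        return {}
    out = {}
    for k, target in required.items():
        if k not in block:
            problems.append(f"{key}.{k}: missing")
        else:
            out[target] = block[k]
    for k, target in (optional or {}).items():
        if k in block:
            out[target] = block[k]
    known = set(required) | set(optional or {})
    for k in block:
        if k not in known:
            problems.append(f"{key}.{k}: unknown key")
    return out


def load_config(path) -> RunConfig:
    """Load a YAML run configuration.

    Schema (all blocks optional; omitted blocks fall back to the study
    defaults)::

        antenna:   {power_w, gain_db, frequency_ghz}
        scenarios: {<name>: {r_near_m, cage_extent_m, mean_mass_kg, mean_length_m}}
        limits:    {sar_wkg, density_wm2}
        cohorts:   [{age_group, arm}, ...]
        analysis:  {alpha, method, continuity}
        seed:      <int>
    """
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level of the config must be a mapping")

    base = default_config()
    problems: list = []

    known_top = {"antenna", "scenarios", "limits", "cohorts", "analysis", "seed"}
    for k in data:
        if k not in known_top:
            problems.append(f"{k}: unknown top-level key")

    antenna_kw = _pop_block(data, "antenna",
                            {"power_w": "power_input_w", "gain_db": "gain_db",
                             "frequency_ghz": "frequency_ghz"}, problems)
    limits_kw = _pop_block(data, "limits",
                           {"sar_wkg": "sar_whole_body_wkg",
                            "density_wm2": "power_density_wm2"}, problems)
    analysis_kw = _pop_block(data, "analysis", {}, problems,
                             optional={"alpha": "alpha", "method": "method",
                                       "continuity": "continuity"})

    scenarios = dict(base.scenarios)
    if "scenarios" in data:
        scenarios = {}
        if not isinstance(data["scenarios"], dict):
            problems.append("scenarios: expected a mapping of name -> block")
        else:
            for name, block in data["scenarios"].items():
                kw = _pop_block({name: block}, name,
                                {"r_near_m": "r_near_m",
                                 "cage_extent_m": "cage_extent_m",
                                 "mean_mass_kg": "mean_mass_kg",
                                 "mean_length_m": "mean_length_m"}, problems)
                if len(kw) == 4:
                    try:
                        scenarios[name] = ExposureScenario(name=name, **kw)
                    except ValueError as err:
                        problems.append(f"scenarios.{name}: {err}")

    cohorts = base.cohorts
    if "cohorts" in data:
        raw = data["cohorts"]
        if not isinstance(raw, list):
            problems.append("cohorts: expected a list of {age_group, arm}")
        else:
            pairs = []
            for i, item in enumerate(raw):
                if (not isinstance(item, dict)
                        or set(item) != {"age_group", "arm"}):
                    problems.append(f"cohorts[{i}]: expected keys age_group and arm")
                else:
                    pairs.append((item["age_group"], item["arm"]))
            cohorts = tuple(pairs)

    if problems:
        raise ConfigError("; ".join(problems))

    try:
        antenna = (AntennaSpec(**antenna_kw) if antenna_kw else base.antenna)
        limits = (ComplianceLimits(**limits_kw) if limits_kw else base.limits)
        return RunConfig(
            antenna=antenna, scenarios=scenarios, limits=limits,
            cohorts=cohorts,
            alpha=analysis_kw.get("alpha", base.alpha),
            method=analysis_kw.get("method", base.method),
            continuity=analysis_kw.get("continuity", base.continuity),
            master_seed=int(data.get("seed", base.master_seed)),
        )
    except ConfigError:
        raise
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err
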