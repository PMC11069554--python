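"""End-to-end orchestration: dosimetry planning, cohort simulation,
endpoint analysis, group comparison and reporting.

A run is fully determined by its :class:`~rfcohort.config.RunConfig`
(including the master seed).  Each cohort gets a child seed spawned from
``SeedSequence([master_seed, age_index, arm_index])``, so the same cohort
is bit-identical across runs regardless of which other cohorts are
requested.  Every output file carries the config hash and seed in a '#'
header line, and ``manifest.json`` records sha256 checksums of all outputs
plus one structured log line per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import endpoints as ep
from .cohort import (default_calibration, generate_cohort, animals_to_frame,
                     trials_to_frame, write_animals_csv, write_trials_csv)
from .config import RunConfig, config_hash, default_config
from .dosimetry import FarFieldWarning, icnirp_check, sar_range, summary_as_dict
from .stats import ENDPOINT_DECIMALS, compare_groups, format_summary_cell

__all__ = ["cohort_seed", "run_experiment", "plan_dosimetry",
           "simulate_cohorts", "analyze_tables", "format_report"]


def cohort_seed(master_seed: int, age_group: str, arm: str) -> int:
    """Deterministic child seed for one cohort (< 2**31)."""
    entropy = [master_seed, cal.AGE_GROUPS.index(age_group),
               cal.ARMS.index(arm)]
    state = np.random.SeedSequence(entropy).generate_state(1)[0]
    return int(state) & 0x7FFF_FFFF


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def plan_dosimetry(config: RunConfig) -> dict:
    """SarSummary + compliance verdict for every configured scenario."""
    out = {}
    for name, scenario in config.scenarios.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FarFieldWarning)
            summary = sar_range(config.antenna, scenario)
        report = icnirp_check(summary, config.limits)
        entry = summary_as_dict(summary, report)
        entry["scenario"] = {
            "r_near_m": scenario.r_near_m,
            "cage_extent_m": scenario.cage_extent_m,
            "mean_mass_kg": scenario.mean_mass_kg,
            "mean_length_m": scenario.mean_length_m,
            # mean animal lengths are working assumptions, not measured values
            "mean_length_is_assumed": cal.ASSUMED_MEAN_LENGTHS,
        }
        out[name] = entry
    return out


def simulate_cohorts(config: RunConfig) -> tuple:
    """Generate every configured cohort; returns (animals_df, trials_df)."""
    animal_frames, trial_frames = [], []
    for age, arm in config.cohorts:
        spec = default_calibration(age, arm)
        animals, trials = generate_cohort(spec, cohort_seed(config.master_seed, age, arm))
        animal_frames.append(animals_to_frame(animals))
        trial_frames.append(trials_to_frame(trials))
    return (pd.concat(animal_frames, ignore_index=True),
            pd.concat(trial_frames, ignore_index=True))


def analyze_tables(animals: pd.DataFrame, trials: pd.DataFrame) -> dict:
    """All endpoint tables from stored (or fresh) animal/trial tables."""
    rectal = ep.summarize_temperatures(animals, "rectal")
    skin = ep.summarize_temperatures(animals, "skin")
    tables = {
        "body_weight": ep.summarize_weights(animals).data,
        "weight_gain": ep.weekly_weight_gain(animals).data,
        "organ_coefficients": ep.summarize_organs(animals).data,
        "rectal_temperature": rectal.data,
        "skin_temperature": skin.data,
        "temperature_differential": ep.temperature_differential(rectal, skin).data,
        "mwm_summary": ep.mwm_daily_summary(trials),
    }
    passive = {}
    for (age, arm), grp in trials.groupby(["age_group", "arm"]):
        passive[f"{age}/{arm}"] = {
            str(day): ids for day, ids in ep.passive_swimmers(grp).items()}
    return {"tables": tables, "passive_swimmers": passive}


def _pivot_paper_style(comparisons: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """One published-style table: rows (age_group, arm), columns timepoints."""
    sub = comparisons[comparisons["endpoint"] == endpoint]
    decimals = ENDPOINT_DECIMALS.get(endpoint, 1)
    rows = {}
    for age in cal.AGE_GROUPS:
        asub = sub[sub["age_group"] == age]
        if asub.empty:
            continue
        ctrl, expo = {}, {}
        for _, r in asub.iterrows():
            ctrl[r["timepoint"]] = format_summary_cell(
                r["control_mean"], r["control_dispersion"], None, decimals)
            expo[r["timepoint"]] = format_summary_cell(
                r["exposed_mean"], r["exposed_dispersion"], r["p_value"], decimals)
        rows[(age, "control")] = ctrl
        rows[(age, "exposed")] = expo
    return pd.DataFrame(rows).T


def format_report(comparisons: pd.DataFrame, analysis: dict) -> str:
    """The six published-style tables as plain text."""
    sections = [
        ("Body weight (g)", "body_weight_g"),
        ("Organ weight coefficients (% of body weight)", "organ_coefficient_pct"),
        ("Rectal temperature (C)", "rectal_temperature_c"),
        ("Skin surface temperature (C)", "skin_temperature_c"),
        ("Water maze: mean successful latency (s)", "mwm_latency_s"),
    ]
    parts = []
    for title, endpoint in sections:
        parts.append(title)
        parts.append("=" * len(title))
        parts.append(_pivot_paper_style(comparisons, endpoint).to_string())
        parts.append("")
    parts.append("Water maze: percentage of successful swims")
    parts.append("=" * 42)
    mwm = analysis["tables"]["mwm_summary"]
    pct = mwm.pivot_table(index=["age_group", "arm"], columns="day",
                          values="percent_successful")
    parts.append(pct.round(1).to_string())
    parts.append("")
    parts.append("Passive swimmers (animal ids per testing day)")
    parts.append("=" * 45)
    for cohort, days in analysis["passive_swimmers"].items():
        listed = "; ".join(f"day {d}: {', '.join(ids) if ids else '-'}"
                           for d, ids in days.items())
        parts.append(f"{cohort}: {listed}")
    parts.append("")
    return "\n".join(parts)


def run_experiment(config: RunConfig | None = None, outdir=".",
                   master_seed: int | None = None) -> dict:
    """Run the full replica pipeline and write the report bundle.

    Outputs under ``outdir``: ``dosimetry.json``, per-cohort
    ``animals_<age>_<arm>.csv`` / ``trials_<age>_<arm>.csv``, endpoint CSVs,
    ``comparisons.csv``, ``report.txt``, ``run.log`` and ``manifest.json``.
    Returns the manifest dict.
    """
    if config is None:
        config = default_config()
    if master_seed is not None:
        config = dataclasses.replace(config, master_seed=master_seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    header = f"rfcohort config={chash} seed={config.master_seed}"
    log: list = []

    def stage(name: str, **params) -> None:
        log.append({"stage": name, **params})

    # 1. dosimetry
    dosimetry = plan_dosimetry(config)
    (outdir / "dosimetry.json").write_text(
        json.dumps({"_provenance": header, **dosimetry}, indent=2))
    stage("plan_dosimetry", scenarios=sorted(dosimetry),
          compliant=all(d["compliant"] for d in dosimetry.values()))

    # 2. simulation
    animal_frames, trial_frames = [], []
    for age, arm in config.cohorts:
        seed = cohort_seed(config.master_seed, age, arm)
        spec = default_calibration(age, arm)
        animals, trials = generate_cohort(spec, seed)
        adf, tdf = animals_to_frame(animals), trials_to_frame(trials)
        write_animals_csv(adf, outdir / f"animals_{age}_{arm}.csv", header)
        write_trials_csv(tdf, outdir / f"trials_{age}_{arm}.csv", header)
        animal_frames.append(adf)
        trial_frames.append(tdf)
        stage("simulate", age_group=age, arm=arm, seed=seed,
              n_animals=len(adf), n_trials=len(tdf))
    animals = pd.concat(animal_frames, ignore_index=True)
    trials = pd.concat(trial_frames, ignore_index=True)

    # 3. endpoints
    analysis = analyze_tables(animals, trials)
    for name, table in analysis["tables"].items():
        path = outdir / f"endpoint_{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {header}\n")
            table.to_csv(fh, index=False)
    (outdir / "passive_swimmers.json").write_text(
        json.dumps({"_provenance": header, **analysis["passive_swimmers"]},
                   indent=2))
    stage("analyze", endpoints=sorted(analysis["tables"]))

    # 4. statistics + report
    comparisons = compare_groups(animals, trials, alpha=config.alpha,
                                 method=config.method,
                                 continuity=config.continuity)
    with open(outdir / "comparisons.csv", "w", encoding="utf-8") as fh:
        fh.write(f"# {header}\n")
        comparisons.to_csv(fh, index=False)
    (outdir / "report.txt").write_text(
        f"# {header}\n" + format_report(comparisons, analysis))
    stage("compare", rows=len(comparisons),
          significant=int(comparisons["significant"].sum()),
          alpha=config.alpha)

    # 5. manifest
    (outdir / "run.log").write_text(
        "\n".join(json.dumps(line, sort_keys=True) for line in log) + "\n")
    files = sorted(p.name for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_hash": chash,
        "master_seed": config.master_seed,
        "config": config.to_dict(),
        "files": {name: _sha256(outdir / name) for name in files},
        "log": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
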