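"""Endpoint computation: weight dynamics, organ coefficients, temperatures,
and water-maze daily summaries from per-animal / per-trial tables.

All functions accept the tidy tables produced by
:func:`rfcohort.cohort.animals_to_frame` / ``trials_to_frame`` (or read back
from their CSVs) and return group summaries in the study's reporting
format: mean, dispersion (per-animal SD) and n per (age_group, arm,
timepoint).  Water-maze latency averages are computed over *successful*
swims only; censored 60 s failures enter the success percentage, never the
latency mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal

__all__ = [
    "EndpointTable",
    "summarize_weights",
    "summarize_temperatures",
    "summarize_organs",
    "weekly_weight_gain",
    "organ_weight_coefficient",
    "temperature_differential",
    "mwm_daily_summary",
    "passive_swimmers",
]

GROUP_KEYS = ["age_group", "arm"]


@dataclass
class EndpointTable:
    """One endpoint's group summaries: name + tidy DataFrame.

    ``data`` columns: age_group, arm, timepoint, mean, dispersion, n.
    """

    endpoint: str
    data: pd.DataFrame

    def to_csv(self, path, **kwargs) -> None:
        self.data.to_csv(path, index=False, **kwargs)


def _summarize_wide(animals: pd.DataFrame, columns: dict, endpoint: str) -> EndpointTable:
    """Melt wide per-animal columns into (group, timepoint) mean/sd/n rows."""
    missing = [c for c in columns if c not in animals.columns]
    if missing:
        raise ValueError(f"animal table lacks expected columns: {missing}")
    rows = []
    for (age, arm), grp in animals.groupby(GROUP_KEYS, sort=False):
        for col, timepoint in columns.items():
            vals = grp[col].to_numpy(float)
            rows.append({"age_group": age, "arm": arm, "timepoint": timepoint,
                         "mean": vals.mean(),
                         "dispersion": vals.std(ddof=1) if len(vals) > 1 else 0.0,
                         "n": len(vals)})
    return EndpointTable(endpoint, pd.DataFrame(rows))


def summarize_weights(animals: pd.DataFrame) -> EndpointTable:
    """Body weight [g] per group and timepoint (baseline + weeks 1-5)."""
    cols = {f"weight_{tp}_g": tp for tp in cal.WEIGHT_TIMEPOINTS}
    return _summarize_wide(animals, cols, "body_weight_g")


def summarize_temperatures(animals: pd.DataFrame, kind: str) -> EndpointTable:
    """Rectal or skin temperature [C] per group and timepoint."""
    if kind not in ("rectal", "skin"):
        raise ValueError(f"kind must be 'rectal' or 'skin', got {kind!r}")
    cols = {f"{kind}_{tp}_c": tp for tp in cal.TEMP_TIMEPOINTS}
    return _summarize_wide(animals, cols, f"{kind}_temperature_c")


def summarize_organs(animals: pd.DataFrame) -> EndpointTable:
    """Organ weight coefficients [% of terminal body weight] per group."""
    rows = []
    for (age, arm), grp in animals.groupby(GROUP_KEYS, sort=False):
        for organ in cal.ORGANS:
            col = f"{organ}_g"
            if col not in grp.columns:
                raise ValueError(f"animal table lacks organ column {col!r}")
            coeff = organ_weight_coefficient(
                grp[col].to_numpy(float), grp["terminal_weight_g"].to_numpy(float))
            rows.append({"age_group": age, "arm": arm, "timepoint": organ,
                         "mean": coeff.mean(),
                         "dispersion": coeff.std(ddof=1) if len(coeff) > 1 else 0.0,
                         "n": len(coeff)})
    return EndpointTable("organ_coefficient_pct", pd.DataFrame(rows))


def weekly_weight_gain(animals: pd.DataFrame) -> EndpointTable:
    """Consecutive-timepoint body-weight gains [g] per group.

    The group gain is the difference of consecutive group means (equal to
    the mean of per-animal gains); the dispersion is the SD of the
    per-animal gains.  Gains telescope: they sum to final - baseline.
    """
    cols = [f"weight_{tp}_g" for tp in cal.WEIGHT_TIMEPOINTS]
    missing = [c for c in cols if c not in animals.columns]
    if missing:
        raise ValueError(f"animal table lacks weight columns: {missing}")
    if animals[cols].isna().any().any():
        raise ValueError("weight trajectories contain missing timepoints")
    rows = []
    for (age, arm), grp in animals.groupby(GROUP_KEYS, sort=False):
        w = grp[cols].to_numpy(float)
        gains = np.diff(w, axis=1)
        for j in range(gains.shape[1]):
            interval = f"{cal.WEIGHT_TIMEPOINTS[j]}_to_{cal.WEIGHT_TIMEPOINTS[j + 1]}"
            g = gains[:, j]
            rows.append({"age_group": age, "arm": arm, "timepoint": interval,
                         "mean": g.mean(),
                         "dispersion": g.std(ddof=1) if len(g) > 1 else 0.0,
                         "n": len(g)})
    return EndpointTable("weekly_weight_gain_g", pd.DataFrame(rows))


def organ_weight_coefficient(organ_mass_g, terminal_weight_g):
    """Organ mass as a percentage of body weight, 100 * organ / body.

    Accepts scalars or arrays; unit-rescaling both masses leaves the
    coefficient unchanged.
    """
    organ = np.asarray(organ_mass_g, dtype=float)
    body = np.asarray(terminal_weight_g, dtype=float)
    if np.any(organ <= 0) or np.any(body <= 0):
        raise ValueError("masses must be > 0")
    if np.any(organ >= body):
        raise ValueError("organ mass must be below body weight")
    out = 100.0 * organ / body
    return float(out) if out.ndim == 0 else out


def temperature_differential(rectal: EndpointTable,
                             skin: EndpointTable) -> EndpointTable:
    """Core-minus-surface differential (rectal - skin mean) per group/timepoint."""
    keys = GROUP_KEYS + ["timepoint"]
    r = rectal.data.set_index(keys)
    s = skin.data.set_index(keys)
    if not r.index.equals(s.index):
        raise ValueError("rectal and skin tables have mismatched group/timepoint keys")
    merged = r[["mean"]].rename(columns={"mean": "rectal_mean"}).join(
        s[["mean"]].rename(columns={"mean": "skin_mean"}))
    merged["mean"] = merged["rectal_mean"] - merged["skin_mean"]
    out = merged.reset_index()[keys + ["mean"]]
    out["dispersion"] = np.nan  # difference of group means; no per-animal pairing implied
    out["n"] = r["n"].to_numpy()
    return EndpointTable("rectal_minus_skin_c", out)


def mwm_daily_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Water-maze summary per (age_group, arm, day).

    Columns: mean_successful_latency_s and dispersion_s over successful
    trials only; percent_successful = 100 * n_successful / n_attempted
    (exact integer arithmetic before the division); latency_defined is
    False on days without a single success (latency reported as NaN).
    """
    if trials.empty:
        raise ValueError("trial table is empty")
    rows = []
    for (age, arm, day), grp in trials.groupby(GROUP_KEYS + ["day"], sort=False):
        succ = grp.loc[grp["success"], "latency_s"].to_numpy(float)
        n_succ, n_att = int(grp["success"].sum()), int(len(grp))
        rows.append({
            "age_group": age, "arm": arm, "day": int(day),
            "mean_successful_latency_s": succ.mean() if n_succ else np.nan,
            "dispersion_s": succ.std(ddof=1) if n_succ > 1 else (0.0 if n_succ else np.nan),
            "percent_successful": 100.0 * n_succ / n_att,
            "n_successful": n_succ,
            "n_attempted": n_att,
            "latency_defined": n_succ > 0,
        })
    return pd.DataFrame(rows).sort_values(GROUP_KEYS + ["day"],
                                          ignore_index=True)


def passive_swimmers(trials: pd.DataFrame) -> dict:
    """Per-day sorted unique ids of animals with at least one passive trial.

    Expects trials of a single cohort (one age_group/arm); every listed
    animal necessarily had a failed trial that day (passive implies failure).
    """
    if trials[GROUP_KEYS].drop_duplicates().shape[0] > 1:
        raise ValueError("passive_swimmers expects trials from one cohort; "
                         "group by (age_group, arm) first")
    out: dict = {int(day): [] for day in sorted(trials["day"].unique())}
    flagged = trials[trials["passive"]]
    for day, grp in flagged.groupby("day"):
        out[int(day)] = sorted(grp["animal_id"].unique())
    return out
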