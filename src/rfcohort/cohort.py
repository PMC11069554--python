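"""Seeded synthetic-cohort generator calibrated to the published summaries.

The study's raw per-animal data are not redistributed here; instead this
module draws cohorts whose statistical structure matches the printed group
summaries (means and dispersions of weights, temperatures, organ weight
coefficients, and water-maze latencies/success rates):

* body weight: baseline ~ Normal truncated to (0, inf); weekly values are
  previous + an independent Normal increment whose mean equals the printed
  consecutive-mean difference, so trajectories are autocorrelated and mean
  growth matches the tables (increments may be negative);
* rectal / skin temperature: independent Normals truncated to [30, 42] C;
* organ masses: a weight-coefficient draw (% of body weight, truncated > 0)
  times the terminal body weight;
* water maze: per trial an independent Bernoulli success; successful
  latencies come from a truncated Normal on (0, 60) s whose *post-truncation*
  mean and SD are root-found to equal the printed cell (moment matching);
  failed trials are censored at exactly 60 s; a failed trial is flagged as
  passive swimming with a day-dependent probability that decays after day 1.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed
(spec, seed) pair reproduces the cohort bit for bit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import calibration as cal

__all__ = [
    "CohortSpec",
    "AnimalRecord",
    "TrialRecord",
    "MomentMatchError",
    "default_calibration",
    "zero_dispersion",
    "match_truncated_normal_moments",
    "generate_cohort",
    "animals_to_frame",
    "trials_to_frame",
    "write_animals_csv",
    "write_trials_csv",
    "read_table_csv",
]

LATENCY_CAP_S = 60.0
TEMP_LO_C, TEMP_HI_C = 30.0, 42.0

_ID_RE = re.compile(r"^\d+-\d+$")


class MomentMatchError(ValueError):
    """Requested truncated-normal moments are unattainable on the interval."""


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class AnimalRecord:
    """One synthetic animal's longitudinal measurements.

    ``animal_id`` follows the ear-tag scheme "cage-number" (first digit the
    cage, second the individual within the cage).
    """

    animal_id: str
    age_group: str
    arm: str
    cage: int
    weights_g: tuple  # baseline + weeks 1-5
    rectal_c: tuple   # baseline + weeks 1-4
    skin_c: tuple
    organ_masses_g: dict
    terminal_weight_g: float

    def __post_init__(self) -> None:
        if not _ID_RE.match(self.animal_id):
            raise ValueError(f"animal_id must look like 'cage-number', got {self.animal_id!r}")
        if len(self.weights_g) != len(cal.WEIGHT_TIMEPOINTS):
            raise ValueError("expected one weight per timepoint")
        if any(w <= 0 for w in self.weights_g):
            raise ValueError("body weights must be > 0")
        if any(m >= self.terminal_weight_g for m in self.organ_masses_g.values()):
            raise ValueError("organ masses must be below terminal body weight")


@dataclass(frozen=True)
class TrialRecord:
    """One water-maze swim: 60 s cap, censored failures, passive flag."""

    animal_id: str
    age_group: str
    arm: str
    day: int
    trial_index: int
    latency_s: float
    success: bool
    passive: bool

    def __post_init__(self) -> None:
        if self.day not in cal.MWM_DAYS:
            raise ValueError(f"day must be one of {cal.MWM_DAYS}, got {self.day}")
        if not 1 <= self.trial_index <= cal.TRIALS_PER_DAY:
            raise ValueError("trial_index out of range")
        if self.success:
            if not 0 < self.latency_s < LATENCY_CAP_S:
                raise ValueError("successful latency must lie in (0, 60) s")
        elif self.latency_s != LATENCY_CAP_S:
            raise ValueError("failed trials are censored at exactly 60 s")
        if self.passive and self.success:
            raise ValueError("passive swimming implies an unsuccessful trial")


@dataclass(frozen=True)
class CohortSpec:
    """Calibration of one (age group, arm) cohort.

    ``weight_calibration`` etc. hold per-timepoint ``(mean, sd)`` pairs;
    ``mwm_calibration`` maps testing day to ``(latency mean, latency sd,
    success probability)``; ``passive_propensity`` maps day to the
    probability that a failed trial is scored passive.
    """

    age_group: str
    arm: str
    n_animals: int
    cage_ids: tuple
    weight_calibration: tuple
    rectal_calibration: tuple
    skin_calibration: tuple
    organ_calibration: dict
    mwm_calibration: dict
    passive_propensity: dict

    def __post_init__(self) -> None:
        if self.n_animals <= 0:
            raise ValueError("n_animals must be > 0")
        if not self.cage_ids:
            raise ValueError("at least one cage id is required")
        if len(self.weight_calibration) != len(cal.WEIGHT_TIMEPOINTS):
            raise ValueError("weight_calibration must cover all timepoints")
        for tbl, npts in ((self.rectal_calibration, len(cal.TEMP_TIMEPOINTS)),
                          (self.skin_calibration, len(cal.TEMP_TIMEPOINTS))):
            if len(tbl) != npts:
                raise ValueError("temperature calibration must cover all timepoints")
        for mean, sd in self.weight_calibration:
            if mean <= 0 or sd < 0:
                raise ValueError("weight means must be > 0 and sds >= 0")
        for tbl in (self.rectal_calibration, self.skin_calibration):
            for mean, sd in tbl:
                if not TEMP_LO_C <= mean <= TEMP_HI_C or sd < 0:
                    raise ValueError("temperature means must lie in [30, 42] C")
        for organ, (mean, sd) in self.organ_calibration.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"invalid organ calibration for {organ}")
        for day, (mean, sd, p) in self.mwm_calibration.items():
            if not 0 < mean <= LATENCY_CAP_S or sd < 0 or not 0 <= p <= 1:
                raise ValueError(f"invalid water-maze calibration for day {day}")
        for day, p in self.passive_propensity.items():
            if not 0 <= p <= 1:
                raise ValueError(f"invalid passive propensity for day {day}")


def default_calibration(age_group: str, arm: str) -> CohortSpec:
    """CohortSpec whose cells equal the published summaries for that cohort."""
    key = (age_group, arm)
    if key not in cal.BODY_WEIGHT_G:
        raise ValueError(
            f"unknown cohort {key!r}; age_group in {cal.AGE_GROUPS}, arm in {cal.ARMS}")
    return CohortSpec(
        age_group=age_group,
        arm=arm,
        n_animals=cal.N_ANIMALS,
        cage_ids=cal.CAGE_IDS[key],
        weight_calibration=tuple(cal.BODY_WEIGHT_G[key]),
        rectal_calibration=tuple(cal.RECTAL_C[key]),
        skin_calibration=tuple(cal.SKIN_C[key]),
        organ_calibration=dict(cal.ORGAN_COEFF_PCT[key]),
        mwm_calibration={day: (*cal.MWM_LATENCY_S[key][day],
                               cal.MWM_SUCCESS_PCT[key][day] / 100.0)
                         for day in cal.MWM_DAYS},
        passive_propensity=dict(cal.PASSIVE_PROB_BY_DAY),
    )


def zero_dispersion(spec: CohortSpec) -> CohortSpec:
    """Copy of ``spec`` with every dispersion set to 0 (degenerate noise)."""
    return replace(
        spec,
        weight_calibration=tuple((m, 0.0) for m, _ in spec.weight_calibration),
        rectal_calibration=tuple((m, 0.0) for m, _ in spec.rectal_calibration),
        skin_calibration=tuple((m, 0.0) for m, _ in spec.skin_calibration),
        organ_calibration={k: (m, 0.0) for k, (m, _) in spec.organ_calibration.items()},
        mwm_calibration={d: (m, 0.0, p) for d, (m, _, p) in spec.mwm_calibration.items()},
    )


# ---------------------------------------------------------------------------
# truncated-normal moment matching

def _trunc_moments(loc: float, scale: float, lower: float, upper: float):
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
    return float(m), math.sqrt(float(v))


def _loc_for_mean(target_mean: float, scale: float,
                  lower: float, upper: float) -> float:
    # the truncated mean is strictly increasing in loc for fixed scale
    def f(loc: float) -> float:
        return _trunc_moments(loc, scale, lower, upper)[0] - target_mean

    lo = min(target_mean, lower) - 5.0 * scale
    hi = max(target_mean, upper) + 5.0 * scale
    for _ in range(200):
        if f(lo) <= 0:
            break
        lo -= 5.0 * scale
    for _ in range(200):
        if f(hi) >= 0:
            break
        hi += 5.0 * scale
    return float(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16))


@lru_cache(maxsize=4096)
def match_truncated_normal_moments(target_mean: float, target_sd: float,
                                   lower: float = 0.0,
                                   upper: float = LATENCY_CAP_S):
    """Parameters (loc, scale) whose truncation to (lower, upper) has the
    requested first two moments.

    Solved by nested root-finding: for each scale, the location matching the
    mean is found by bisection (the truncated mean is monotone in loc); the
    post-truncation SD of that mean-matched family increases with scale, so
    a second bisection pins the scale.  Moments of the returned parameters
    agree with the targets to well below 1e-6.

    Raises
    ------
    MomentMatchError
        If ``target_sd`` exceeds what any normal truncated to the interval
        can achieve (the SD approaches the uniform-limit value as the scale
        grows), or the mean is not interior to the interval.
    """
    if not lower < target_mean < upper:
        raise MomentMatchError(
            f"target mean {target_mean} must lie strictly inside "
            f"({lower}, {upper})")
    if target_sd <= 0:
        raise MomentMatchError(f"target sd must be > 0, got {target_sd}")
    span = upper - lower
    if target_sd >= span / 2.0:  # hard bound for any variable on the interval
        raise MomentMatchError(
            f"target sd {target_sd} is impossible on an interval of width {span}")

    def sd_at(scale: float) -> float:
        loc = _loc_for_mean(target_mean, scale, lower, upper)
        return _trunc_moments(loc, scale, lower, upper)[1]

    scale_lo = 1e-6 * span
    if sd_at(scale_lo) > target_sd:
        scale_lo = 1e-12 * span
    scale_hi = max(target_sd, span)
    for _ in range(60):
        if sd_at(scale_hi) >= target_sd:
            break
        scale_hi *= 2.0
        if scale_hi > 1e6 * span:
            raise MomentMatchError(
                f"requested sd {target_sd} is unattainable for mean "
                f"{target_mean} on ({lower}, {upper})")
    else:  # pragma: no cover - loop always breaks or raises
        raise MomentMatchError("scale bracketing failed")

    scale = float(optimize.brentq(lambda s: sd_at(s) - target_sd,
                                  scale_lo, scale_hi, xtol=1e-10))
    loc = _loc_for_mean(target_mean, scale, lower, upper)
    m, sd = _trunc_moments(loc, scale, lower, upper)
    if abs(m - target_mean) > 1e-6 or abs(sd - target_sd) > 1e-6:
        raise MomentMatchError(
            f"moment matching did not converge for mean {target_mean}, "
            f"sd {target_sd} on ({lower}, {upper})")
    return loc, scale


def _sample_truncated(rng: np.random.Generator, loc: float, scale: float,
                      lower: float, upper: float, size: int) -> np.ndarray:
    """Exact rejection sampling of a truncated normal (deterministic in rng)."""
    if scale == 0.0:
        if not lower < loc < upper:
            raise ValueError("degenerate draw outside the truncation interval")
        return np.full(size, loc)
    out = np.empty(size)
    pending = np.arange(size)
    for _ in range(10_000):
        draws = rng.normal(loc, scale, pending.size)
        ok = (draws > lower) & (draws < upper)
        out[pending[ok]] = draws[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise RuntimeError("truncated-normal rejection sampling did not terminate")


# ---------------------------------------------------------------------------
# cohort generation


def _animal_ids(spec: CohortSpec) -> list:
    """Ear-tag ids "cage-number", animals split evenly across cages."""
    n_cages = len(spec.cage_ids)
    base, extra = divmod(spec.n_animals, n_cages)
    ids = []
    for i, cage in enumerate(spec.cage_ids):
        for k in range(base + (1 if i < extra else 0)):
            ids.append((cage, f"{cage}-{k + 1}"))
    return ids


def _increment_sd(sd_prev: float, sd_now: float) -> float:
    """SD of the weekly weight increment.

    Chosen so the cross-sectional variance tracks the printed one when it
    grows (Var_t = Var_{t-1} + Var_inc); when the printed variance shrinks
    (independent increments cannot lose variance) a small floor keeps the
    trajectories noisy without biasing the mean.
    """
    var_diff = sd_now ** 2 - sd_prev ** 2
    if var_diff > 0:
        return math.sqrt(var_diff)
    return 0.1 * sd_now


def generate_cohort(spec: CohortSpec, seed) -> tuple:
    """Draw one cohort: (list of AnimalRecord, list of TrialRecord).

    Deterministic for a fixed (spec, seed); ``seed`` may be anything
    :func:`numpy.random.default_rng` accepts.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_animals
    ids = _animal_ids(spec)

    # --- weights: truncated-normal baseline, Normal increments -------------
    means = [m for m, _ in spec.weight_calibration]
    sds = [s for _, s in spec.weight_calibration]
    weights = np.empty((n, len(means)))
    weights[:, 0] = _sample_truncated(rng, means[0], sds[0], 0.0, np.inf, n)
    for t in range(1, len(means)):
        inc_mean = means[t] - means[t - 1]
        inc_sd = _increment_sd(sds[t - 1], sds[t])
        inc = rng.normal(inc_mean, inc_sd, n) if inc_sd > 0 else np.full(n, inc_mean)
        weights[:, t] = np.maximum(weights[:, t - 1] + inc, 1.0)

    # --- temperatures -------------------------------------------------------
    def temp_matrix(calibration) -> np.ndarray:
        cols = [_sample_truncated(rng, m, s, TEMP_LO_C, TEMP_HI_C, n)
                for m, s in calibration]
        return np.column_stack(cols)

    rectal = temp_matrix(spec.rectal_calibration)
    skin = temp_matrix(spec.skin_calibration)

    # --- organs: coefficient draw x terminal weight -------------------------
    terminal = weights[:, -1]
    organ_masses = {}
    for organ, (m, s) in spec.organ_calibration.items():
        coeff = _sample_truncated(rng, m, s, 0.0, np.inf, n)
        organ_masses[organ] = coeff * terminal / 100.0

    animals = []
    for i, (cage, aid) in enumerate(ids):
        animals.append(AnimalRecord(
            animal_id=aid, age_group=spec.age_group, arm=spec.arm, cage=cage,
            weights_g=tuple(weights[i]),
            rectal_c=tuple(rectal[i]), skin_c=tuple(skin[i]),
            organ_masses_g={o: organ_masses[o][i] for o in organ_masses},
            terminal_weight_g=float(terminal[i]),
        ))

    # --- water maze ----------------------------------------------------------
    trials = []
    k = cal.TRIALS_PER_DAY
    for day in sorted(spec.mwm_calibration):
        lat_mean, lat_sd, p_success = spec.mwm_calibration[day]
        q_passive = spec.passive_propensity.get(day, 0.0)
        success = rng.random((n, k)) < p_success
        n_succ = int(success.sum())
        if lat_sd > 0:
            loc, scale = match_truncated_normal_moments(
                lat_mean, lat_sd, 0.0, LATENCY_CAP_S)
            succ_lat = _sample_truncated(rng, loc, scale, 0.0, LATENCY_CAP_S, n_succ)
        else:
            succ_lat = np.full(n_succ, lat_mean)
        passive = (~success) & (rng.random((n, k)) < q_passive)
        lat = np.full((n, k), LATENCY_CAP_S)
        lat[success] = succ_lat
        for i, (_, aid) in enumerate(ids):
            for j in range(k):
                trials.append(TrialRecord(
                    animal_id=aid, age_group=spec.age_group, arm=spec.arm,
                    day=day, trial_index=j + 1,
                    latency_s=float(lat[i, j]),
                    success=bool(success[i, j]),
                    passive=bool(passive[i, j]),
                ))
    return animals, trials


# ---------------------------------------------------------------------------
# tabular views and CSV round trip


def animals_to_frame(animals: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Wide per-animal table (one row per animal, documented column schema)."""
    rows = []
    for a in animals:
        row = {"animal_id": a.animal_id, "age_group": a.age_group,
               "arm": a.arm, "cage": a.cage}
        row.update({f"weight_{tp}_g": w
                    for tp, w in zip(cal.WEIGHT_TIMEPOINTS, a.weights_g)})
        row.update({f"rectal_{tp}_c": t
                    for tp, t in zip(cal.TEMP_TIMEPOINTS, a.rectal_c)})
        row.update({f"skin_{tp}_c": t
                    for tp, t in zip(cal.TEMP_TIMEPOINTS, a.skin_c)})
        row.update({f"{organ}_g": m for organ, m in a.organ_masses_g.items()})
        row["terminal_weight_g"] = a.terminal_weight_g
        rows.append(row)
    return pd.DataFrame(rows)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Long per-trial table: one row per swim."""
    return pd.DataFrame([{
        "animal_id": t.animal_id, "age_group": t.age_group, "arm": t.arm,
        "day": t.day, "trial_index": t.trial_index,
        "latency_s": t.latency_s, "success": t.success, "passive": t.passive,
    } for t in trials])


def _write_csv(frame: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def write_animals_csv(animals, path, header_comment: str | None = None) -> None:
    frame = animals if isinstance(animals, pd.DataFrame) else animals_to_frame(animals)
    _write_csv(frame, path, header_comment)


def write_trials_csv(trials, path, header_comment: str | None = None) -> None:
    frame = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    _write_csv(frame, path, header_comment)


def read_table_csv(path) -> pd.DataFrame:
    """Read an animals or trials CSV written by this package ('#' comments)."""
    return pd.read_csv(path, comment="#")
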