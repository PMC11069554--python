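"""Two-sample Mann-Whitney U test (exact and approximate) and the
exposed-vs-control comparison tables.

The exact two-sided p-value enumerates the full null distribution of U by
dynamic programming over rank subsets (no ties), with the convention

    p = min(1, 2 * min(P(U <= u), P(U >= u))).

With ties, or for larger samples, a normal approximation with mid-ranks,
tie-corrected variance and (optional) continuity correction is used; the
exact path silently falls back to the approximation when ties are present,
because exact conditional tie handling is a different test.

No multiple-testing correction is applied by default (each endpoint is
tested at raw alpha, as in the reference study); a Holm adjustment is
available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from . import calibration as cal
from . import endpoints as ep

__all__ = [
    "TestResult",
    "mann_whitney_u",
    "exact_u_counts",
    "compare_groups",
    "holm_adjust",
    "format_summary_cell",
]

_SQRT2 = math.sqrt(2.0)

# display precision per endpoint, mirroring the published tables
ENDPOINT_DECIMALS = {
    "body_weight_g": 1,
    "rectal_temperature_c": 1,
    "skin_temperature_c": 1,
    "organ_coefficient_pct": 2,
    "mwm_latency_s": 1,
}


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sided Mann-Whitney comparison."""

    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approximation"
    n1: int
    n2: int
    tie_corrected: bool

    def __post_init__(self) -> None:
        if not 0 <= self.u_statistic <= self.n1 * self.n2:
            raise ValueError("U must lie in [0, n1*n2]")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value must lie in (0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    sorted_vals = values[order]
    ranks = np.empty(len(values), dtype=float)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=256)
def exact_u_counts(n1: int, n2: int) -> tuple:
    """Null distribution of U: counts[u] = number of rank subsets giving U=u.

    Dynamic programme over the ranks 1..n1+n2: ways to choose n1 of them
    with each possible rank sum; U = ranksum - n1*(n1+1)/2.  The counts sum
    to C(n1+n2, n1) and the distribution is symmetric about n1*n2/2.
    """
    total = n1 + n2
    min_sum = n1 * (n1 + 1) // 2
    max_sum = sum(range(total - n1 + 1, total + 1))
    # dp[k][s] = ways to pick k ranks so far with sum s (python ints, exact)
    dp = [[0] * (max_sum + 1) for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in range(1, total + 1):
        for k in range(min(r, n1), 0, -1):
            row, prev = dp[k], dp[k - 1]
            for s in range(max_sum, r - 1, -1):
                c = prev[s - r]
                if c:
                    row[s] += c
    return tuple(dp[n1][min_sum:max_sum + 1])


def _exact_p(u: float, n1: int, n2: int) -> float:
    counts = exact_u_counts(n1, n2)
    total = sum(counts)
    lo = int(math.floor(u + 1e-9))
    hi = int(math.ceil(u - 1e-9))
    p_le = sum(counts[:lo + 1]) / total
    p_ge = sum(counts[hi:]) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(x, y, method: str = "auto",
                   continuity: bool = True) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``method='auto'`` enumerates the exact null distribution when both
    samples have at most 12 observations and the pooled data are tie-free,
    and otherwise uses the tie-corrected normal approximation.  The
    reported U is that of the first sample, so U(x, y) + U(y, x) = n1*n2.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "approx"):
        raise ValueError(f"unknown method {method!r}")

    pooled = np.concatenate([x, y])
    if not np.all(np.isfinite(pooled)):
        raise ValueError("samples must be finite")
    ranks = _midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    use_exact = (method == "exact" or
                 (method == "auto" and n1 <= 12 and n2 <= 12))
    if use_exact and not has_ties:
        return TestResult(u_statistic=u1, p_value=_exact_p(u1, n1, n2),
                          method="exact", n1=n1, n2=n2, tie_corrected=False)

    # normal approximation, tie-corrected variance
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return TestResult(u_statistic=u1, p_value=1.0,
                          method="normal_approximation",
                          n1=n1, n2=n2, tie_corrected=has_ties)
    diff = u1 - mu
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var)
    p = min(1.0, math.erfc(abs(z) / _SQRT2))
    return TestResult(u_statistic=u1, p_value=max(p, 1e-300),
                      method="normal_approximation",
                      n1=n1, n2=n2, tie_corrected=has_ties)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (off by default in compare_groups)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# exposed-vs-control comparison tables


def _per_animal_mwm_latency(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-animal mean successful latency per day (animals w/o success drop out)."""
    succ = trials[trials["success"]]
    return (succ.groupby(["age_group", "arm", "day", "animal_id"])["latency_s"]
            .mean().reset_index())


def _endpoint_columns(animals: pd.DataFrame):
    for tp in cal.WEIGHT_TIMEPOINTS:
        yield "body_weight_g", tp, f"weight_{tp}_g"
    for tp in cal.TEMP_TIMEPOINTS:
        yield "rectal_temperature_c", tp, f"rectal_{tp}_c"
    for tp in cal.TEMP_TIMEPOINTS:
        yield "skin_temperature_c", tp, f"skin_{tp}_c"


def compare_groups(animals: pd.DataFrame, trials: pd.DataFrame,
                   alpha: float = 0.05, method: str = "auto",
                   continuity: bool = True,
                   holm: bool = False) -> pd.DataFrame:
    """One exposed-vs-control row per endpoint x age group x timepoint.

    Endpoints: body weight per timepoint, rectal and skin temperature per
    timepoint, organ weight coefficients per organ, and per-animal mean
    successful water-maze latency per testing day.  Each row carries the
    control and exposed summaries (mean, per-animal SD, n), the U statistic
    and two-sided p-value, and a significance flag at ``alpha``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rows = []
    for age in animals["age_group"].unique():
        sub = animals[animals["age_group"] == age]
        arms = set(sub["arm"].unique())
        if arms != {"exposed", "control"}:
            raise ValueError(
                f"age group {age!r} lacks a matched exposed/control pair (has {sorted(arms)})")
        ctrl = sub[sub["arm"] == "control"]
        expo = sub[sub["arm"] == "exposed"]

        def add_row(endpoint, timepoint, cvals, evals):
            cvals = np.asarray(cvals, float)
            evals = np.asarray(evals, float)
            if len(cvals) == 0 or len(evals) == 0:
                return
            res = mann_whitney_u(evals, cvals, method=method,
                                 continuity=continuity)
            rows.append({
                "endpoint": endpoint, "age_group": age, "timepoint": timepoint,
                "control_mean": cvals.mean(),
                "control_dispersion": cvals.std(ddof=1) if len(cvals) > 1 else 0.0,
                "control_n": len(cvals),
                "exposed_mean": evals.mean(),
                "exposed_dispersion": evals.std(ddof=1) if len(evals) > 1 else 0.0,
                "exposed_n": len(evals),
                "u_statistic": res.u_statistic,
                "p_value": res.p_value,
                "method": res.method,
            })

        for endpoint, tp, col in _endpoint_columns(animals):
            add_row(endpoint, tp, ctrl[col], expo[col])
        for organ in cal.ORGANS:
            add_row("organ_coefficient_pct", organ,
                    ep.organ_weight_coefficient(
                        ctrl[f"{organ}_g"].to_numpy(), ctrl["terminal_weight_g"].to_numpy()),
                    ep.organ_weight_coefficient(
                        expo[f"{organ}_g"].to_numpy(), expo["terminal_weight_g"].to_numpy()))

        lat = _per_animal_mwm_latency(trials[trials["age_group"] == age])
        for day in sorted(lat["day"].unique()):
            dsub = lat[lat["day"] == day]
            add_row("mwm_latency_s", f"day{day}",
                    dsub.loc[dsub["arm"] == "control", "latency_s"],
                    dsub.loc[dsub["arm"] == "exposed", "latency_s"])

    out = pd.DataFrame(rows)
    if holm and len(out):
        out["p_value_holm"] = holm_adjust(out["p_value"].to_numpy())
        out["significant"] = out["p_value_holm"] < alpha
    else:
        out["significant"] = out["p_value"] < alpha
    return out


def format_summary_cell(mean: float, dispersion: float, p_value: float | None,
                        decimals: int = 1) -> str:
    """Publication-style cell "mean +/- dispersion" with optional ", p = ...".

    >>> format_summary_cell(227.38, 15.84, None)
    '227.4 ± 15.8'
    """
    cell = f"{mean:.{decimals}f} ± {dispersion:.{decimals}f}"
    if p_value is not None:
        cell += f", p = {p_value:.3f}"
    return cell
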