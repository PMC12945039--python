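"""Cohort-level statistics for slide-derived Ki-67 metrics.

Implements the statistics layer applied to per-slide metrics joined with
signalment, grading, manual hotspot data, and survival outcome:
quality-stratified exclusion of heavily inflamed cases, fold changes of
cohort means after exclusion, two/three-group nonparametric comparisons
(Wilcoxon rank-sum with exact enumeration for small groups,
Kruskal-Wallis), Spearman correlation, univariable Cox proportional-hazards
regression (Efron tie handling via lifelines), and median-dichotomized
Kaplan-Meier curves.

No multiple-testing correction is applied by default — p-values are
exploratory — but Benjamini-Hochberg adjustment is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "exclude_inflamed",
    "fold_change",
    "round_half_away",
    "webster_summary",
    "pi_category_summary",
    "compare_groups",
    "spearman_correlation",
    "cox_univariable",
    "km_dichotomize",
    "interlab_intensity_compare",
    "benjamini_hochberg",
]

#: Group sizes at or below which rank-sum p-values are computed by exact
#: enumeration of all label assignments.
EXACT_LIMIT = 8


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    name: str
    statistic: float
    p_value: float
    effect: float | None = None
    ci: tuple[float, float] | None = None
    n: tuple[int, ...] = ()
    note: str = ""

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------- exclusion


def exclude_inflamed(cohort: pd.DataFrame, score_col: str = "q_inflammation") -> pd.DataFrame:
    """Drop cases with marked inflammation (quality score 0); keeps 1 and 2."""
    return cohort[cohort[score_col].astype(int).isin((1, 2))]


# -------------------------------------------------------------- fold change


def fold_change(mean_all: float, mean_excluded: float) -> float:
    """Signed fold change between cohort means before/after exclusion.

    Magnitude is max/min rounded to 2 decimals; the sign is negative when
    the excluded-subset mean is lower (a decrease), and +1.0 when equal.
    Undefined (NaN) for non-positive means.
    """
    if mean_all <= 0 or mean_excluded <= 0:
        return float("nan")
    if mean_all == mean_excluded:
        return 1.0
    magnitude = round(max(mean_all, mean_excluded) / min(mean_all, mean_excluded), 2)
    return -magnitude if mean_excluded < mean_all else magnitude


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ------------------------------------------------------- category summaries


def webster_summary(categories: pd.Series | list) -> pd.DataFrame:
    """Counts and integer percentages of manual hotspot categories.

    Missing values are dropped before percentages are formed.
    """
    cats = pd.Series(categories).dropna()
    cats = cats[cats.astype(str) != ""]
    if len(cats) == 0:
        raise ValueError("no hotspot categories available")
    n_total = len(cats)
    out = []
    for cat in ("low", "high"):
        n = int((cats == cat).sum())
        out.append({"category": cat, "n": n,
                    "percent": round_half_away(100.0 * n / n_total)})
    return pd.DataFrame(out)


def pi_category_summary(
    cohort: pd.DataFrame,
    pi_col: str = "pi_percent",
    low_cutoff: float = 15.0,
    high_cutoff: float = 30.0,
    inflammation_col: str | None = "q_inflammation",
) -> pd.DataFrame:
    """Fractions of low-PI (<= 15%) and high-PI (>= 30%) tumours.

    Reported for all slides and, when inflammation scores are present, for
    the subset excluding marked inflammation.
    """
    def _one(df: pd.DataFrame, label: str) -> list[dict]:
        pi = df[pi_col].dropna()
        n = len(pi)
        rows = []
        for name, sel in (
            ("low_pi", pi <= low_cutoff),
            ("high_pi", pi >= high_cutoff),
        ):
            k = int(sel.sum())
            rows.append(
                {
                    "subset": label,
                    "category": name,
                    "n": k,
                    "n_total": n,
                    "percent": round_half_away(100.0 * k / n) if n else 0,
                }
            )
        return rows

    rows = _one(cohort, "all")
    if inflammation_col is not None and inflammation_col in cohort:
        rows += _one(exclude_inflamed(cohort, inflammation_col), "excluded")
    return pd.DataFrame(rows)


# ------------------------------------------------------------- group tests


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact rank-sum p by full enumeration of label assignments.

    Returns (W, p) where W is the rank-sum of the first group (average
    ranks for ties).  p is the fraction of assignments whose rank-sum
    deviates from its null mean at least as much as observed.
    """
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    mu = ranks.sum() * n1 / len(pooled)
    dev = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mu) >= dev - 1e-12:
            hits += 1
    return float(w_obs), hits / total


def compare_groups(values, labels) -> TestResult:
    """Nonparametric comparison of a Ki-67 metric across groups.

    Two groups: Wilcoxon rank-sum, exact enumeration when both groups have
    <= 8 observations, normal approximation with tie correction otherwise.
    Three groups: Kruskal-Wallis.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    groups = [values[labels == g] for g in uniq]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    ns = tuple(len(g) for g in groups)

    if len(groups) == 2:
        x, y = groups
        if len(x) <= EXACT_LIMIT and len(y) <= EXACT_LIMIT:
            w, p = _exact_ranksum_p(x, y)
            return TestResult("wilcoxon-rank-sum-exact", w, p, n=ns)
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        w = float(sps.rankdata(np.concatenate([x, y]))[: len(x)].sum())
        return TestResult("wilcoxon-rank-sum", w, float(res.pvalue), n=ns)

    if len(groups) == 3:
        if np.ptp(values) == 0:
            return TestResult("kruskal-wallis", 0.0, 1.0, n=ns,
                              note="all values identical")
        stat, p = sps.kruskal(*groups)
        return TestResult("kruskal-wallis", float(stat), float(p), n=ns)
    raise ValueError("compare_groups supports two or three groups")


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired data with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult("spearman", float("nan"), float("nan"),
                          n=(len(x),), note="constant input; rho undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman", float(rho), float(p), effect=float(rho), n=(len(x),))


# ---------------------------------------------------------------- survival


def resolve_events(event_flag, censor_rule: str = "all-deaths") -> np.ndarray:
    """Map outcome flags to event indicators under a censoring rule.

    ``event_flag`` may already be boolean, or contain the strings
    'died-MCT', 'died-other', 'alive'.  Rules: 'all-deaths' treats any
    death as an event; 'mct-only' treats only MCT deaths as events and
    censors other deaths.
    """
    arr = np.asarray(event_flag)
    if arr.dtype == bool or np.issubdtype(arr.dtype, np.number):
        return arr.astype(bool)
    if censor_rule == "all-deaths":
        return np.isin(arr, ("died-MCT", "died-other"))
    if censor_rule == "mct-only":
        return arr == "died-MCT"
    raise ValueError(f"unknown censor rule {censor_rule!r}")


def cox_univariable(
    metric,
    survival_days,
    event_flag,
    censor_rule: str = "all-deaths",
) -> TestResult:
    """Univariable Cox proportional-hazards fit for one Ki-67 metric.

    Returns the hazard ratio per unit of the metric with a 95% Wald CI and
    p-value.  Ties are handled with Efron's method.  A constant metric
    carries no information and returns HR 1; non-convergence is flagged in
    the result note rather than raised.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    metric = np.asarray(metric, dtype=float)
    durations = np.asarray(survival_days, dtype=float)
    if (durations < 0).any():
        raise ValueError("survival_days must be non-negative")
    events = resolve_events(event_flag, censor_rule)
    if events.sum() < 2:
        raise ValueError("need at least two events for a Cox fit")
    n = (len(metric),)
    if np.ptp(metric) == 0:
        return TestResult("cox-univariable", 0.0, 1.0, effect=1.0,
                          ci=(1.0, 1.0), n=n, note="constant metric")
    df = pd.DataFrame({"metric": metric, "T": durations, "E": events})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="T", event_col="E")  # Efron ties (default)
    except ConvergenceError as err:
        return TestResult("cox-univariable", float("nan"), float("nan"),
                          n=n, note=f"non-convergence: {err}")
    coef = float(cph.params_["metric"])
    se = float(cph.standard_errors_["metric"])
    p = float(cph.summary.loc["metric", "p"])
    hr = math.exp(coef)
    ci = (math.exp(coef - 1.959963984540054 * se),
          math.exp(coef + 1.959963984540054 * se))
    return TestResult("cox-univariable", coef, p, effect=hr, ci=ci, n=n)


@dataclass
class KMResult:
    """Median-dichotomized Kaplan-Meier comparison."""

    threshold: float
    curve_table: pd.DataFrame  # columns: group, time, at_risk, events, survival
    n_low: int
    n_high: int
    flagged: bool = False
    note: str = ""


def km_dichotomize(
    cohort: pd.DataFrame,
    metric_col: str,
    duration_col: str = "survival_days",
    event_col: str = "event",
    threshold: float | None = None,
) -> KMResult:
    """Kaplan-Meier curves after dichotomizing a metric at its median.

    The high group is strictly above the threshold; records equal to the
    median go to the low group.  Returns product-limit estimates per group
    as a tidy curve table; a degenerate split (all records on one side) is
    flagged rather than raised.
    """
    from lifelines import KaplanMeierFitter

    vals = cohort[metric_col].to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError(f"{metric_col} contains missing values")
    thr = float(np.median(vals)) if threshold is None else float(threshold)
    high = vals > thr
    n_low, n_high = int((~high).sum()), int(high.sum())
    if n_low == 0 or n_high == 0:
        return KMResult(thr, pd.DataFrame(
            columns=["group", "time", "at_risk", "events", "survival"]),
            n_low, n_high, flagged=True,
            note="degenerate dichotomization: one group is empty")
    frames = []
    for name, sel in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(cohort[duration_col][sel], cohort[event_col][sel].astype(bool))
        tbl = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
        surv = kmf.survival_function_.iloc[:, 0].to_numpy()
        frames.append(pd.DataFrame({
            "group": name,
            "time": tbl["time"],
            "at_risk": tbl["at_risk"].astype(int),
            "events": tbl["observed"].astype(int),
            "survival": surv,
        }))
    return KMResult(thr, pd.concat(frames, ignore_index=True), n_low, n_high)


# ----------------------------------------------------- interlab comparison


def interlab_intensity_compare(values, protocol_group) -> TestResult:
    """Compare pooled per-nucleus DAB pseudo-intensities of positive nuclei
    between two staining-protocol series.

    Rank-sum p (exact for tiny groups) plus the absolute difference of
    group means in pseudo-intensity units as the effect.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(protocol_group)
    uniq = pd.unique(groups)
    if len(uniq) != 2:
        raise ValueError("need exactly two protocol groups")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty protocol group")
    res = compare_groups(values, groups)
    diff = float(abs(a.mean() - b.mean()))
    return TestResult("interlab-intensity", res.statistic, res.p_value,
                      effect=diff, n=(len(a), len(b)))


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
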