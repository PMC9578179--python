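"""Normality-routed two-group comparison pipeline and study-level report.

Every quantitative variable is routed through a composite-normality check
(Lilliefors-corrected Kolmogorov–Smirnov with the Dallal–Wilkinson p-value
approximation, alpha = 0.05).  If both arms pass, the variable is summarized
as mean [95% CI of the mean] and compared with a Student t-test; otherwise
it is summarized as median [p25, p75] and compared with a two-sided
Mann–Whitney test (exact null distribution for combined n <= 20 without
ties, normal approximation with tie and continuity corrections otherwise).
Qualitative 2x2 contrasts use chi-square without continuity correction when
every expected count is at least 5 and Fisher's exact test (two-sided,
point-probability method) below that.  No multiplicity adjustment is
applied by default; an optional Holm correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ALPHA",
    "NormalityResult",
    "SampleSummary",
    "GroupComparison",
    "normality_route",
    "compare_quantitative",
    "compare_qualitative",
    "summarize",
    "study_report",
    "mann_whitney",
    "fisher_exact_p",
]

ALPHA = 0.05
_MIN_NORMALITY_N = 5
_EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class NormalityResult:
    route: str  # "normal" | "non-normal"
    p_value: float  # NaN when the test could not be run
    flag: Optional[str] = None  # "small_n" | "degenerate"


@dataclass(frozen=True)
class SampleSummary:
    """Per-arm summary: mean [95% CI] on the normal route, median [p25, p75]
    otherwise."""

    n: int
    route: str
    location: float
    lo: float
    hi: float
    flag: Optional[str] = None


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    summary_x: SampleSummary
    summary_y: SampleSummary
    test: str  # "t" | "mann-whitney" | "chi-square" | "fisher"
    statistic: float
    p_value: float
    notes: str = ""


def normality_route(x) -> NormalityResult:
    """Route a sample: Lilliefors KS normality test at alpha = 0.05.

    Samples of fewer than 5 values, and constant samples, cannot support the
    test and are routed non-normal with a flag.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 1:
        raise ValueError("sample must be non-empty")
    if arr.size < _MIN_NORMALITY_N:
        return NormalityResult("non-normal", float("nan"), "small_n")
    if np.ptp(arr) == 0:
        return NormalityResult("non-normal", float("nan"), "degenerate")
    _, p = lilliefors(arr, dist="norm", pvalmethod="approx")
    return NormalityResult("normal" if p > ALPHA else "non-normal", float(p))


def summarize(x, route: str) -> SampleSummary:
    """Summarize a sample on the given route.

    Non-normal: median and quartiles by linear interpolation between order
    statistics (the inclusive method, numpy's default).  Normal: mean and
    t-based 95% confidence interval of the mean.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.size
    if n < 1:
        raise ValueError("sample must be non-empty")
    if route == "non-normal":
        med = float(np.median(arr))
        q25, q75 = np.percentile(arr, [25, 75])
        return SampleSummary(n=n, route=route, location=med, lo=float(q25), hi=float(q75))
    if route != "normal":
        raise ValueError(f"unknown route {route!r}")
    mean = float(np.mean(arr))
    if n == 1:
        return SampleSummary(n=1, route=route, location=mean, lo=mean, hi=mean, flag="single")
    sem = float(np.std(arr, ddof=1) / np.sqrt(n))
    half = float(sps.t.ppf(0.975, n - 1)) * sem
    return SampleSummary(n=n, route=route, location=mean, lo=mean - half, hi=mean + half)


def mann_whitney(x, y) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U test.

    Uses the exact null distribution when the combined sample size is at
    most 20 and there are no ties, else the normal approximation with tie
    and continuity corrections.  Returns (U of the first sample, p, note).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    if combined.size <= _EXACT_MW_MAX_N and no_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        note = "exact"
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        note = "normal approximation, tie/continuity corrected"
    return float(res.statistic), float(res.pvalue), note


def compare_quantitative(
    x, y, variable: str = "", welch: bool = False
) -> GroupComparison:
    """Route-and-test one quantitative variable across two arms.

    Both arms on the normal route: two-sided Student t-test (Welch behind
    the flag).  Any other routing: two-sided Mann–Whitney.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each arm needs at least 3 values")
    rx, ry = normality_route(x), normality_route(y)
    both_normal = rx.route == "normal" and ry.route == "normal"
    if both_normal:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        test, note = "t", "welch" if welch else "student"
        route_x = route_y = "normal"
    else:
        stat, p, note = mann_whitney(x, y)
        test = "mann-whitney"
        route_x = route_y = "non-normal"
    return GroupComparison(
        variable=variable,
        summary_x=summarize(x, route_x),
        summary_y=summarize(y, route_y),
        test=test,
        statistic=stat,
        p_value=p,
        notes=note,
    )


def compare_qualitative(table, variable: str = "") -> GroupComparison:
    """2x2 qualitative contrast: chi-square or Fisher's exact test.

    Chi-square (no continuity correction) when every expected count is at
    least 5; otherwise Fisher's exact, two-sided by the point-probability
    method.  A zero row or column margin is degenerate and rejected.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")

    total = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if np.all(expected >= 5):
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
        test, stat, note = "chi-square", float(chi2), "no continuity correction"
    else:
        p = fisher_exact_p(t)
        stat_ = sps.fisher_exact(t, alternative="two-sided")[0]
        test, stat, note = "fisher", float(stat_), "exact, point-probability two-sided"

    def _prop_summary(row: np.ndarray) -> SampleSummary:
        n = int(row.sum())
        frac = 100.0 * row[0] / n
        return SampleSummary(n=n, route="qualitative", location=frac, lo=frac, hi=frac)

    return GroupComparison(
        variable=variable,
        summary_x=_prop_summary(t[0]),
        summary_y=_prop_summary(t[1]),
        test=test,
        statistic=stat,
        p_value=float(p),
        notes=note,
    )


def fisher_exact_p(table) -> float:
    """Fisher's exact two-sided p (point-probability method) for a 2x2 table."""
    return float(sps.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _holm(pvals: Sequence[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


def study_report(
    cohort_df: pd.DataFrame,
    arm_col: str = "arm",
    variables: Optional[Sequence[str]] = None,
    qualitative: Optional[dict[str, pd.Series]] = None,
    holm: bool = False,
) -> pd.DataFrame:
    """One routed comparison per outcome variable over a two-arm cohort.

    ``cohort_df`` holds one row per subject with an arm column and numeric
    outcome columns; ``variables`` defaults to every numeric column.
    Variables with missing values in any subject are excluded with a note
    row.  ``qualitative`` maps a variable name to a boolean per-subject
    series compared as a 2x2 table.  No multiplicity adjustment unless
    ``holm`` is set (an adjusted-p column is then appended).

    Returns a tidy frame: variable, per-arm n/summary, route/test,
    statistic, p-value, note; arms ordered by first appearance.
    """
    arms = list(dict.fromkeys(cohort_df[arm_col]))
    if len(arms) != 2:
        raise ValueError(f"exactly two arms required, found {arms}")
    gx = cohort_df[cohort_df[arm_col] == arms[0]]
    gy = cohort_df[cohort_df[arm_col] == arms[1]]

    if variables is None:
        variables = [
            c
            for c in cohort_df.columns
            if c != arm_col and pd.api.types.is_numeric_dtype(cohort_df[c])
        ]

    rows = []
    comparisons: list[Optional[GroupComparison]] = []
    for var in variables:
        x = gx[var].to_numpy(dtype=float)
        y = gy[var].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            comparisons.append(None)
            rows.append(
                {"variable": var, "test": "excluded", "note": "missing values in cohort"}
            )
            continue
        gc = compare_quantitative(x, y, variable=var)
        comparisons.append(gc)
        rows.append(_comparison_row(gc, arms))

    for var, series in (qualitative or {}).items():
        flags = series.astype(bool)
        tab = [
            [int(flags[cohort_df[arm_col] == a].sum()), int((~flags[cohort_df[arm_col] == a]).sum())]
            for a in arms
        ]
        try:
            gc = compare_qualitative(tab, variable=var)
        except ValueError as exc:
            comparisons.append(None)
            rows.append({"variable": var, "test": "excluded", "note": str(exc)})
            continue
        comparisons.append(gc)
        rows.append(_comparison_row(gc, arms))

    report = pd.DataFrame(rows)
    if holm:
        mask = report["test"] != "excluded"
        adj = _holm(report.loc[mask, "p_value"].tolist())
        report.loc[mask, "p_holm"] = adj
    report.attrs["footer"] = (
        "alpha = 0.05; no multiple-testing adjustment applied"
        + ("" if not holm else " to p_value (see p_holm)")
    )
    return report


def _comparison_row(gc: GroupComparison, arms: Sequence[str]) -> dict:
    sx, sy = gc.summary_x, gc.summary_y
    return {
        "variable": gc.variable,
        f"n_{arms[0]}": sx.n,
        f"n_{arms[1]}": sy.n,
        "route": sx.route,
        f"loc_{arms[0]}": sx.location,
        f"lo_{arms[0]}": sx.lo,
        f"hi_{arms[0]}": sx.hi,
        f"loc_{arms[1]}": sy.location,
        f"lo_{arms[1]}": sy.lo,
        f"hi_{arms[1]}": sy.hi,
        "test": gc.test,
        "statistic": gc.statistic,
        "p_value": gc.p_value,
        "note": gc.notes,
    }
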