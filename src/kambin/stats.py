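"""Cohort statistics.

Normality-gated summaries and tests mirroring the reference analysis:
Shapiro-Wilk decides between parametric and rank-based procedures at a
configurable alpha; one-sample comparisons against trephine diameters use
the one-sample t-test or the one-sample Wilcoxon signed-rank test (the
rank-sum test needs two samples, so the one-sample signed-rank is the
coherent reading); correlations are Pearson with a least-squares line.
Raw p-values are reported without multiple-testing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, ValidationError

REQUIRED_COLUMNS = (
    "case_id", "side", "sex", "age", "bmi",
    "d_mm", "beta_deg", "quadrant", "L1_mm", "L2_mm",
)

QUADRANTS = ("A", "B", "C", "D")


def validate_cohort(table: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Check the cohort table contract: columns present, no missing values."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns: {missing}")
    if len(table) < min_n:
        raise ValidationError(f"cohort table needs n >= {min_n}, got {len(table)}")
    na = table[list(REQUIRED_COLUMNS)].isna()
    if na.any().any():
        bad = [c for c in REQUIRED_COLUMNS if na[c].any()]
        raise ValidationError(f"cohort table has missing values in: {bad}")
    bad_q = set(table["quadrant"]) - set(QUADRANTS)
    if bad_q:
        raise ValidationError(f"unknown quadrant labels: {sorted(bad_q)}")
    return table


@dataclass(frozen=True)
class SummaryStats:
    variable: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    minimum: float
    maximum: float
    normal: bool
    shapiro_p: float
    presentation: str  # 'mean±SD' | 'median(IQR)'

    def __post_init__(self) -> None:
        seq = (self.minimum, self.q1, self.median, self.q3, self.maximum)
        if any(a > b + 1e-12 for a, b in zip(seq, seq[1:])):
            raise ValidationError(f"inconsistent order statistics for {self.variable}")

    def to_dict(self) -> Dict[str, object]:
        return {
            "variable": self.variable, "n": self.n,
            "mean": self.mean, "sd": self.sd,
            "median": self.median, "q1": self.q1, "q3": self.q3,
            "min": self.minimum, "max": self.maximum,
            "normal": self.normal, "shapiro_p": self.shapiro_p,
            "presentation": self.presentation,
        }


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    ci: Optional[Tuple[float, float]] = None
    threshold: Optional[float] = None
    normal: Optional[bool] = None
    details: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValidationError(f"p-value out of [0, 1]: {self.p_value}")
        if self.ci is not None and self.ci[0] > self.ci[1] + 1e-12:
            raise ValidationError(f"inverted confidence interval: {self.ci}")

    def to_dict(self) -> Dict[str, object]:
        out: Dict[str, object] = {
            "test": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.ci is not None:
            out["ci95"] = list(self.ci)
        if self.threshold is not None:
            out["threshold"] = self.threshold
        if self.normal is not None:
            out["normal"] = self.normal
        out.update(self.details)
        return out


def _as_values(values: Sequence[float], min_n: int = 3) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValidationError("expected a 1-D value vector")
    if len(v) < min_n:
        raise DegenerateTestError(f"need n >= {min_n}, got {len(v)}")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite values in input")
    return v


def is_normal(values: np.ndarray, alpha: float = 0.05) -> Tuple[bool, float]:
    """Shapiro-Wilk normality gate; constant vectors count as non-normal."""
    if np.ptp(values) == 0.0:
        return False, 0.0
    p = float(sps.shapiro(values).pvalue)
    return p >= alpha, p


def summarize(
    values: Sequence[float], variable: str = "value", alpha: float = 0.05
) -> SummaryStats:
    """Five-number and moment summaries plus the normality decision."""
    v = _as_values(values)
    normal, shapiro_p = is_normal(v, alpha)
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return SummaryStats(
        variable=variable,
        n=len(v),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        minimum=float(v.min()),
        maximum=float(v.max()),
        normal=normal,
        shapiro_p=shapiro_p,
        presentation="mean±SD" if normal else "median(IQR)",
    )


def _hodges_lehmann_ci(diffs: np.ndarray, conf: float = 0.95) -> Tuple[float, float, float]:
    """Hodges-Lehmann pseudomedian and CI from the signed-rank procedure.

    Uses the large-sample normal approximation for the critical rank; the
    point estimate is the median of the Walsh averages.
    """
    n = len(diffs)
    walsh = np.sort(
        np.array([
            (diffs[i] + diffs[j]) / 2.0 for i in range(n) for j in range(i, n)
        ])
    )
    m = len(walsh)
    est = float(np.median(walsh))
    z = sps.norm.ppf(0.5 + conf / 2.0)
    k = int(math.floor(n * (n + 1) / 4.0 - z * math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    k = max(k, 1)
    lo = float(walsh[k - 1])
    hi = float(walsh[m - k])
    return est, lo, hi


def one_sample_threshold_test(
    values: Sequence[float], threshold: float, alpha: float = 0.05
) -> TestResult:
    """Location test of a sample against a fixed threshold (mm).

    One-sample t-test with a t-based CI when Shapiro-Wilk accepts
    normality; otherwise the one-sample Wilcoxon signed-rank test with a
    Hodges-Lehmann CI.  Two-sided throughout.
    """
    v = _as_values(values)
    diffs = v - threshold
    if np.all(np.abs(diffs) < 1e-12):
        raise DegenerateTestError("all values equal the threshold")
    normal, _ = is_normal(v, alpha)
    if normal:
        res = sps.ttest_1samp(v, popmean=threshold)
        ci = res.confidence_interval(0.95)
        return TestResult(
            name="one-sample t-test",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            ci=(float(ci.low), float(ci.high)),
            threshold=float(threshold),
            normal=True,
        )
    res = sps.wilcoxon(diffs, alternative="two-sided")
    est, lo, hi = _hodges_lehmann_ci(diffs)
    return TestResult(
        name="one-sample Wilcoxon signed-rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        ci=(lo + threshold, hi + threshold),
        threshold=float(threshold),
        normal=False,
        details={"hodges_lehmann": est + threshold},
    )


def linear_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the fitted least-squares line."""
    xv, yv = _as_values(x), _as_values(y)
    if len(xv) != len(yv):
        raise ValidationError("x and y lengths differ")
    if np.ptp(xv) == 0.0 or np.ptp(yv) == 0.0:
        raise DegenerateTestError("constant input to correlation")
    r, p = sps.pearsonr(xv, yv)
    fit = sps.linregress(xv, yv)
    return TestResult(
        name="Pearson correlation",
        statistic=float(r),
        p_value=float(p),
        details={
            "r": float(r),
            "slope": float(fit.slope),
            "intercept": float(fit.intercept),
        },
    )


def quadrant_chisq(labels: Sequence[str]) -> TestResult:
    """Chi-square goodness of fit of quadrant labels against uniform 1/4."""
    labels = list(labels)
    if len(labels) < 1:
        raise DegenerateTestError("no quadrant labels")
    bad = set(labels) - set(QUADRANTS)
    if bad:
        raise ValidationError(f"unknown quadrant labels: {sorted(bad)}")
    counts = np.array([labels.count(q) for q in QUADRANTS], dtype=float)
    res = sps.chisquare(counts)
    return TestResult(
        name="chi-square goodness-of-fit",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        details={q: float(c) for q, c in zip(QUADRANTS, counts)},
    )


def subgroup_compare(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> TestResult:
    """Two-group location comparison, normality-gated.

    Two-sample t-test (pooled variance) when both groups pass
    Shapiro-Wilk, otherwise the Wilcoxon rank-sum (Mann-Whitney) test.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g):
        raise ValidationError("values and groups lengths differ")
    names = sorted(set(g.tolist()))
    if len(names) < 2:
        raise DegenerateTestError(f"need two groups, got {names}")
    if len(names) > 2:
        raise ValidationError(f"expected exactly two groups, got {names}")
    a = v[g == names[0]]
    b = v[g == names[1]]
    if len(a) < 3 or len(b) < 3:
        raise DegenerateTestError("each group needs n >= 3")
    normal = is_normal(a, alpha)[0] and is_normal(b, alpha)[0]
    if normal:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "two-sample t-test"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "Wilcoxon rank-sum"
    return TestResult(
        name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        normal=normal,
        details={
            "group_a": names[0], "group_b": names[1],
            "n_a": float(len(a)), "n_b": float(len(b)),
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        },
    )


def cohort_report(
    table: pd.DataFrame,
    trephine_diameter: float = 8.0,
    comparison_diameter: float = 10.0,
    alpha: float = 0.05,
) -> Dict[str, object]:
    """The full statistics battery on a measurements table.

    Summaries for d, beta, L1, L2; one-sample tests of d against both
    configured diameters and of L1/L2 against 0; the beta-L1, d-L1 and
    beta-L2 correlations; the quadrant chi-square; and side/sex/age
    (median-split) subgroup comparisons for each measurement.
    """
    validate_cohort(table)
    measures = {"d_mm": "d", "beta_deg": "beta", "L1_mm": "L1", "L2_mm": "L2"}
    report: Dict[str, object] = {}
    report["summaries"] = {
        label: summarize(table[col], label, alpha).to_dict()
        for col, label in measures.items()
    }
    report["one_sample_tests"] = {
        f"d_vs_{trephine_diameter:g}mm": one_sample_threshold_test(
            table["d_mm"], trephine_diameter, alpha
        ).to_dict(),
        f"d_vs_{comparison_diameter:g}mm": one_sample_threshold_test(
            table["d_mm"], comparison_diameter, alpha
        ).to_dict(),
        "L1_vs_0mm": one_sample_threshold_test(table["L1_mm"], 0.0, alpha).to_dict(),
        "L2_vs_0mm": one_sample_threshold_test(table["L2_mm"], 0.0, alpha).to_dict(),
    }
    report["correlations"] = {
        "beta_vs_L1": linear_correlation(table["beta_deg"], table["L1_mm"]).to_dict(),
        "d_vs_L1": linear_correlation(table["d_mm"], table["L1_mm"]).to_dict(),
        "beta_vs_L2": linear_correlation(table["beta_deg"], table["L2_mm"]).to_dict(),
    }
    report["quadrants"] = quadrant_chisq(list(table["quadrant"])).to_dict()

    subgroups: Dict[str, object] = {}
    age_groups = np.where(table["age"] >= table["age"].median(), "older", "younger")
    for grouping, g in (
        ("side", table["side"].to_numpy()),
        ("sex", table["sex"].to_numpy()),
        ("age_median_split", age_groups),
    ):
        block = {}
        for col, label in measures.items():
            try:
                block[label] = subgroup_compare(table[col], g, alpha).to_dict()
            except DegenerateTestError as exc:
                block[label] = {"error": str(exc)}
        subgroups[grouping] = block
    report["subgroup_tests"] = subgroups
    return report
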