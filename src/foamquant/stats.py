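"""Statistical decision procedures for comparing cell populations.

The comparison of two feature samples follows a fixed test-selection
tree: if either sample fails a normality test, use the non-parametric
Mann-Whitney test; if both pass and variances are equal, a standard
two-sample t-test; if both pass but variances differ, a Welch-corrected
t-test.  Normality and variance equality are assessed at p < 0.05
(Shapiro-Wilk and Levene; neither choice is forced by the decision tree
and both are configurable).  A difference is *significant* at p < 0.05
and *notable* at the stricter p < 0.001.

Linear correlations between red intensity and area are only trusted
when both Pearson and Spearman reject at p < 0.05: Spearman-only
significance suggests a non-linear monotone relation, and Pearson-only
significance is unreliable under non-normality and outliers.

Population summaries report mean +/- SEM, the sample SD, the median and
the 1st/99th percentiles (the box-whisker convention used throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps

SIGNIFICANT_P = 0.05
NOTABLE_P = 0.001
ASSUMPTION_P = 0.05


class TestName(str, Enum):
    MANN_WHITNEY = "mann_whitney"
    T_TEST = "t_test"
    WELCH_T = "welch_t"


class Verdict(str, Enum):
    SIGNIFICANT_LINEAR = "significant_linear"
    POSSIBLE_NONLINEAR = "possible_nonlinear"
    NOT_SIGNIFICANT = "not_significant"


@dataclass
class TestResult:
    test_name: TestName
    p_value: float
    significant: bool = field(init=False)
    notable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = self.p_value < SIGNIFICANT_P
        self.notable = self.p_value < NOTABLE_P


@dataclass
class CorrelationVerdict:
    pearson_r: float
    pearson_p: float
    spearman_r: float
    spearman_p: float
    verdict: Verdict = field(init=False)

    def __post_init__(self) -> None:
        pearson_sig = self.pearson_p < SIGNIFICANT_P
        spearman_sig = self.spearman_p < SIGNIFICANT_P
        if pearson_sig and spearman_sig:
            self.verdict = Verdict.SIGNIFICANT_LINEAR
        elif spearman_sig and not pearson_sig:
            self.verdict = Verdict.POSSIBLE_NONLINEAR
        else:
            self.verdict = Verdict.NOT_SIGNIFICANT


@dataclass
class ConditionSummary:
    n: int
    mean: float
    sem: float
    sd: float
    median: float
    p1: float
    p99: float


@dataclass
class ManualComparison:
    """Agreement between manual trace areas (a^) and automated areas (a*)."""

    n_pairs: int
    mean_abs_pct_diff: float
    n_below: int
    n_above: int
    n_equal: int
    pct_below: float
    manual_areas: list[float]


def _as_sample(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("samples must be 1-D")
    return arr


def select_and_run_test(
    x: Sequence[float],
    y: Sequence[float],
    normality_test: str = "shapiro",
    variance_test: str = "levene",
) -> TestResult:
    """Compare two samples with the test the data warrant.

    Routes to Mann-Whitney when either sample is non-normal, to the
    pooled t-test when both are normal with equal variances, and to
    Welch's t-test when both are normal with unequal variances.  All
    p-values are two-sided.
    """
    x, y = _as_sample(x), _as_sample(y)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("insufficient sample (need n >= 3 in each group)")

    if normality_test == "shapiro":
        normal = all(sps.shapiro(s).pvalue >= ASSUMPTION_P for s in (x, y))
    elif normality_test == "normaltest":
        normal = all(sps.normaltest(s).pvalue >= ASSUMPTION_P for s in (x, y))
    else:
        raise ValueError(f"unknown normality test: {normality_test!r}")

    if not normal:
        stat = sps.mannwhitneyu(x, y, alternative="two-sided")
        return TestResult(TestName.MANN_WHITNEY, float(stat.pvalue))

    if variance_test == "levene":
        equal_var = sps.levene(x, y).pvalue >= ASSUMPTION_P
    elif variance_test == "bartlett":
        equal_var = sps.bartlett(x, y).pvalue >= ASSUMPTION_P
    else:
        raise ValueError(f"unknown variance test: {variance_test!r}")

    if equal_var:
        stat = sps.ttest_ind(x, y, equal_var=True)
        return TestResult(TestName.T_TEST, float(stat.pvalue))
    stat = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(TestName.WELCH_T, float(stat.pvalue))


def correlation_verdict(x: Sequence[float], y: Sequence[float]) -> CorrelationVerdict:
    """Dual Pearson/Spearman correlation with the both-must-agree rule."""
    x, y = _as_sample(x), _as_sample(y)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 10:
        raise ValueError("need n >= 10 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the samples")
    pear = sps.pearsonr(x, y)
    spear = sps.spearmanr(x, y)
    return CorrelationVerdict(
        pearson_r=float(pear.statistic),
        pearson_p=float(pear.pvalue),
        spearman_r=float(spear.statistic),
        spearman_p=float(spear.pvalue),
    )


def percent_change(control_mean: float, treated_mean: float) -> int:
    """Percent change of the treated mean relative to control, nearest integer."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return int(np.rint(100.0 * (treated_mean - control_mean) / control_mean))


def summarize_condition(values: Sequence[float]) -> ConditionSummary:
    """Population summary: n, mean, SEM, SD, median, 1st/99th percentiles.

    SD uses the n-1 denominator and SEM = SD / sqrt(n); percentiles use
    linear interpolation between order statistics.
    """
    v = _as_sample(values)
    n = len(v)
    if n < 2:
        raise ValueError("SEM undefined for n < 2")
    sd = float(np.std(v, ddof=1))
    p1, med, p99 = np.percentile(v, [1, 50, 99])
    return ConditionSummary(
        n=n,
        mean=float(np.mean(v)),
        sem=sd / np.sqrt(n),
        sd=sd,
        median=float(med),
        p1=float(p1),
        p99=float(p99),
    )


def compare_manual_auto(
    manual_traces: Sequence[Sequence[float]], auto_areas: Sequence[float]
) -> ManualComparison:
    """Score automated areas a* against repeated manual traces.

    Each cell's manual estimate a^ is the mean of its repeated traces;
    the per-cell error is 100 x |a^ - a*| / a^.  Cells are matched by
    position in the two sequences.
    """
    if len(manual_traces) != len(auto_areas):
        raise ValueError("mismatched pairing: need one trace list per automated area")
    a_hat = np.array([np.mean(np.asarray(t, dtype=float)) for t in manual_traces])
    a_star = _as_sample(auto_areas)
    if np.any(a_hat <= 0):
        raise ValueError("manual area estimates must be positive")
    pct_diff = 100.0 * np.abs(a_hat - a_star) / a_hat
    n_below = int(np.sum(a_hat < a_star))
    n_above = int(np.sum(a_hat > a_star))
    n_equal = int(np.sum(a_hat == a_star))
    n_pairs = len(a_hat)
    return ManualComparison(
        n_pairs=n_pairs,
        mean_abs_pct_diff=float(pct_diff.mean()),
        n_below=n_below,
        n_above=n_above,
        n_equal=n_equal,
        pct_below=100.0 * n_below / n_pairs,
        manual_areas=a_hat.tolist(),
    )
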