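"""The statistical decision tree used by all summary stages.

Group comparisons are parametric (two-sample t-test) when both samples pass
a Shapiro-Wilk normality gate at alpha = 0.05, with Welch's correction when
a Levene test rejects variance homogeneity; otherwise the rank-based
alternative is used (Wilcoxon signed-rank for paired data, Mann-Whitney U
for independent samples).  Families of comparisons are Holm-Bonferroni
corrected, and cumulative distributions are compared with the two-sample
Kolmogorov-Smirnov test.  Every result carries its gate p-values so the
branch taken is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import ValidationError

ALPHA_NORMALITY = 0.05
ALPHA_VARIANCE = 0.05


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test with its gating audit trail."""

    test_name: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    normality_p: tuple[float, ...] = ()
    variance_p: float | None = None
    n: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1):
            raise ValidationError(f"p_raw {self.p_raw} outside [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-12:
            raise ValidationError("adjusted p cannot fall below raw p")


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant sample: certainly not Gaussian-gate material
    return float(sps.shapiro(x).pvalue)


def compare_two_groups(
    x: np.ndarray, y: np.ndarray, paired: bool = False
) -> TestResult:
    """Two-group comparison through the normality-gated decision tree.

    Both samples must have n >= 3 (the Shapiro gate is undefined below
    that).  Branches: Shapiro on both groups (paired: on the differences and
    both groups' marginals are not needed — the differences carry the
    assumption) -> pooled or Welch t-test by a Levene gate -> otherwise
    Wilcoxon signed-rank (paired) or Mann-Whitney U (independent).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValidationError("each group needs n >= 3")
    if paired and x.size != y.size:
        raise ValidationError("paired comparison needs equal-length samples")

    if paired:
        d = x - y
        norm_p = (_shapiro_p(d),)
        normal = norm_p[0] > ALPHA_NORMALITY
        if np.ptp(d) == 0:
            # identical pairs: no evidence either way
            return TestResult(
                "paired t-test", 0.0, 1.0, normality_p=norm_p,
                n=(x.size, y.size),
            )
        if normal:
            res = sps.ttest_rel(x, y)
            return TestResult(
                "paired t-test", float(res.statistic), float(res.pvalue),
                normality_p=norm_p, n=(x.size, y.size),
            )
        res = sps.wilcoxon(x, y)
        return TestResult(
            "Wilcoxon signed-rank", float(res.statistic), float(res.pvalue),
            normality_p=norm_p, n=(x.size, y.size),
        )

    norm_p = (_shapiro_p(x), _shapiro_p(y))
    if min(norm_p) > ALPHA_NORMALITY:
        var_p = float(sps.levene(x, y, center="median").pvalue)
        equal_var = var_p > ALPHA_VARIANCE
        res = sps.ttest_ind(x, y, equal_var=equal_var)
        return TestResult(
            "two-sample t-test" if equal_var else "Welch t-test",
            float(res.statistic), float(res.pvalue),
            normality_p=norm_p, variance_p=var_p, n=(x.size, y.size),
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult(
        "Mann-Whitney U", float(res.statistic), float(res.pvalue),
        normality_p=norm_p, n=(x.size, y.size),
    )


def one_sample_test(x: np.ndarray, mu0: float = 0.0) -> TestResult:
    """Normality-gated one-sample test of a mean against ``mu0``."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("one-sample test needs n >= 3")
    if np.ptp(x) == 0 and x[0] == mu0:
        return TestResult(
            "one-sample t-test", 0.0, 1.0, normality_p=(0.0,), n=(x.size,)
        )
    norm_p = (_shapiro_p(x),)
    if norm_p[0] > ALPHA_NORMALITY:
        res = sps.ttest_1samp(x, mu0)
        return TestResult(
            "one-sample t-test", float(res.statistic), float(res.pvalue),
            normality_p=norm_p, n=(x.size,),
        )
    res = sps.wilcoxon(x - mu0)
    return TestResult(
        "one-sample Wilcoxon signed-rank", float(res.statistic),
        float(res.pvalue), normality_p=norm_p, n=(x.size,),
    )


def holm_bonferroni(p_values: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, input order preserved.

    Adjusted p for the i-th smallest raw p is
    ``max over j <= i of (m - j) * p_(j)``, capped at 1; the running-max
    enforces monotonicity.  Permutation-equivariant and never below the
    raw p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sample Kolmogorov-Smirnov comparison of cumulative distributions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return TestResult(
        "two-sample Kolmogorov-Smirnov", float(res.statistic),
        float(res.pvalue), n=(x.size, y.size),
    )
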