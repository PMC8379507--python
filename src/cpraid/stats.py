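"""Study statistics: ICC(A,1) reliability, normality-gated two-group
comparisons with effect sizes, Fisher's exact test, raw NASA-TLX, and an a
priori sample-size helper.

The comparison path mirrors the study protocol: each outcome is gated by a
Kolmogorov–Smirnov normality check; normal outcomes get an independent
t-test with Cohen's d (pooled SD) and a 95% CI of the mean difference,
non-normal outcomes a Mann–Whitney U test with a rank-biserial correlation.

ICC(A,1) — single rater, absolute agreement, two-way mixed model — is
computed from the two-way ANOVA mean squares with the F-based confidence
interval of McGraw & Wong; absolute agreement penalizes systematic offsets
between raters, not just disagreement in ordering.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "IccResult",
    "ComparisonResult",
    "ComparisonTest",
    "icc_a1",
    "ks_normality",
    "compare_groups",
    "rank_biserial",
    "fisher_exact",
    "tlx_raw",
    "sample_size_two_group",
]


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    model: str = "ICC(A,1): two-way mixed, absolute agreement, single rater"


def icc_a1(ratings, alpha: float = 0.05) -> IccResult:
    """Intraclass correlation ICC(A,1) for a complete raters × subjects table.

    ``ratings`` has one row per rater and one column per subject.  The
    estimate comes from the two-way ANOVA mean squares

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with n subjects and k raters; the 95% CI uses the Satterthwaite-style
    F approximation of McGraw & Wong.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D raters x subjects table")
    if np.isnan(x).any():
        raise ValueError("ratings table must be complete (no missing cells)")
    k, n = x.shape
    if k < 2 or n < 2:
        raise ValueError(f"need >=2 raters and >=2 subjects, got {k} x {n}")
    x = x.T  # rows = subjects
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ssr = k * float(((subj_means - grand) ** 2).sum())
    ssc = n * float(((rater_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        # all mean squares zero: constant table, perfect (degenerate) agreement
        return IccResult(estimate=1.0, ci_low=1.0, ci_high=1.0)
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return IccResult(estimate=icc, ci_low=icc, ci_high=icc)
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else math.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else math.inf
    if not math.isfinite(a):
        return IccResult(estimate=icc, ci_low=icc, ci_high=icc)
    num_v = (a * msc + b * mse) ** 2
    den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num_v / den_v if den_v > 0 else 1.0
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return IccResult(estimate=icc, ci_low=min(lower, icc), ci_high=max(upper, icc))


def ks_normality(sample: Sequence[float], alpha: float = 0.05, corrected: bool = True) -> bool:
    """Normality gate: True iff a KS-type test does not reject at ``alpha``.

    With ``corrected`` (default) the Lilliefors correction is applied, the
    appropriate form when the normal's parameters are estimated from the
    sample; ``corrected=False`` runs the plain KS test against a normal with
    the sample's mean and SD.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError(f"need n >= 5 for the normality gate, got {x.size}")
    if np.std(x) == 0:
        return False  # degenerate: a point mass is not normal
    if corrected:
        _, p = lilliefors(x, dist="norm")
    else:
        _, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return bool(p > alpha)


class ComparisonTest(str, enum.Enum):
    T_TEST = "T_TEST"
    MANN_WHITNEY = "MANN_WHITNEY"


@dataclass(frozen=True)
class ComparisonResult:
    test: ComparisonTest
    statistic: float
    p_value: float
    effect_size: float  # Cohen's d (t path) or rank-biserial r (MW path)
    effect_name: str
    mean_diff: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    summary_a: tuple[float, float] = (math.nan, math.nan)  # mean/SD or median/IQR
    summary_b: tuple[float, float] = (math.nan, math.nan)


def rank_biserial(u: float, n_a: int, n_b: int) -> float:
    """Rank-biserial correlation r = 1 - 2U/(n_a n_b).

    ``u`` is the Mann–Whitney statistic counting pairs where the *second*
    group exceeds the first (ties half-weighted), so r is positive when group
    a is stochastically larger and r = 1 under complete separation a > b.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= u <= n_a * n_b):
        raise ValueError(f"u = {u} outside [0, {n_a * n_b}]")
    return 1.0 - 2.0 * u / (n_a * n_b)


def compare_groups(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison with the study's normality gate.

    Both samples normal (KS/Lilliefors, alpha 0.05) → independent t-test,
    Cohen's d with pooled SD, 95% CI of the mean difference.  Otherwise →
    Mann–Whitney U (exact for small untied samples, normal approximation with
    tie correction beyond) with rank-biserial r.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    identical = x.size == y.size and np.array_equal(np.sort(x), np.sort(y))
    try:
        normal = ks_normality(x, alpha) and ks_normality(y, alpha)
    except ValueError:
        normal = False  # samples too small for the gate -> rank test
    if normal or identical:
        t, p = sps.ttest_ind(x, y, equal_var=True)
        na, nb = x.size, y.size
        sp2 = ((na - 1) * x.var(ddof=1) + (nb - 1) * y.var(ddof=1)) / (na + nb - 2)
        sp = math.sqrt(sp2)
        diff = float(x.mean() - y.mean())
        d = diff / sp if sp > 0 else 0.0
        se = sp * math.sqrt(1 / na + 1 / nb)
        tcrit = sps.t.ppf(1 - alpha / 2, na + nb - 2)
        p = 1.0 if math.isnan(p) else float(p)  # zero-variance identical samples
        return ComparisonResult(
            test=ComparisonTest.T_TEST,
            statistic=0.0 if math.isnan(t) else float(t),
            p_value=p,
            effect_size=d,
            effect_name="cohens_d",
            mean_diff=diff,
            ci_low=diff - tcrit * se,
            ci_high=diff + tcrit * se,
            summary_a=(float(x.mean()), float(x.std(ddof=1))),
            summary_b=(float(y.mean()), float(y.std(ddof=1))),
        )
    n_a, n_b = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n_a + n_b
    method = "exact" if (max(n_a, n_b) <= 8 and not has_ties) else "asymptotic"
    # U of the second sample: pairs where b exceeds a -> r > 0 iff a larger
    res = sps.mannwhitneyu(y, x, alternative="two-sided", method=method)
    u_b = float(res.statistic)
    r = rank_biserial(u_b, n_a, n_b)
    iqr_a = float(np.percentile(x, 75) - np.percentile(x, 25))
    iqr_b = float(np.percentile(y, 75) - np.percentile(y, 25))
    return ComparisonResult(
        test=ComparisonTest.MANN_WHITNEY,
        statistic=u_b,
        p_value=float(res.pvalue),
        effect_size=r,
        effect_name="rank_biserial",
        summary_a=(float(np.median(x)), iqr_a),
        summary_b=(float(np.median(y)), iqr_b),
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Two-sided by the usual convention: sum of hypergeometric probabilities of
    tables no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    _, p = sps.fisher_exact(np.round(t).astype(int), alternative="two-sided")
    return float(p)


def tlx_raw(subscales: Sequence[float]) -> float:
    """Raw NASA-TLX: unweighted mean of the six subscale ratings."""
    x = list(subscales)
    if len(x) != 6:
        raise ValueError(f"NASA-TLX has exactly 6 subscales, got {len(x)}")
    return float(sum(x) / 6.0)


def sample_size_two_group(d: float, alpha: float = 0.05, power: float = 0.9) -> int:
    """A priori per-group n for a two-sided two-sample comparison.

    Normal approximation: ceil(2 (z_{1-alpha/2} + z_{power})^2 / d^2).
    At d = 0.8, alpha 0.05: 33/group for power 0.9, 25/group for power 0.8.
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    return max(1, math.ceil(2.0 * z * z / (d * d)))
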