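"""Classical test statistics for the questionnaire arm of the analysis.

Covers the general-linear-model toolkit such a longitudinal cohort study
uses before any network modelling: one-sample Kolmogorov-Smirnov normality
screening, one-way repeated-measures ANOVA over the three assessments with
Tukey HSD post hocs, between-group one-way ANOVA, an a priori power analysis
for the bivariate correlation test, and classification of sample means
against a published control norm (mean +- 1 SD band).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class TestResult:
    """A single test statistic with its degrees of freedom and p-value."""

    statistic: float
    p_value: float
    label: str
    df: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class PowerQuery:
    n: int
    alpha: float = 0.05
    power: float = 0.8
    sides: str = "two"  # "one" | "two"

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("correlation power analysis requires n >= 4")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.sides not in ("one", "two"):
            raise ValueError("sides must be 'one' or 'two'")


@dataclass(frozen=True)
class ReferenceNorm:
    """Published control-sample mean and SD for one subscale."""

    subscale: str
    control_mean: float
    control_sd: float

    def __post_init__(self) -> None:
        if self.control_sd <= 0:
            raise ValueError("control_sd must be positive")


class NormBand(str, enum.Enum):
    below = "below"
    within_1sd = "within_1sd"
    above_1sd = "above_1sd"


class DegenerateDataError(ValueError):
    pass


def ks_normality(
    sample: np.ndarray, mean: float | None = None, sd: float | None = None
) -> TestResult:
    """One-sample K-S test against a normal reference.

    With ``mean``/``sd`` omitted the reference is fitted from the sample
    (Lilliefors situation: the asymptotic p-value is then conservative,
    which is the common practice this mirrors).  D is the sup-distance
    between the empirical CDF and the reference CDF; p comes from the
    asymptotic Kolmogorov distribution.
    """
    x = np.asarray(sample, float)
    if x.size < 1:
        raise ValueError("sample must be non-empty")
    if mean is None or sd is None:
        if x.size < 2 or np.std(x, ddof=1) == 0:
            raise DegenerateDataError("zero-variance sample: cannot fit normal reference")
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
    res = stats.kstest(x, "norm", args=(mean, sd), mode="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        label="ks_normality",
        df=None,
    )


def rm_anova(scores: np.ndarray) -> TestResult:
    """One-way within-subject (repeated-measures) ANOVA.

    ``scores`` is a complete subjects x time matrix.  Decomposition:
    F = MS_time / MS_(time x subject), df = (t-1, (t-1)(n-1)).  No
    sphericity correction is applied by default (see greenhouse_geisser).
    """
    y = np.asarray(scores, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("scores must be an (n >= 2) x (t >= 2) matrix")
    if np.isnan(y).any():
        raise ValueError("scores matrix must be complete")
    n, t = y.shape
    grand = y.mean()
    ss_time = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_subj = t * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_time - ss_subj
    df_time = t - 1
    df_err = (t - 1) * (n - 1)
    ms_err = ss_err / df_err
    if ms_err <= 0 or np.isclose(ms_err, 0, atol=1e-14):
        if ss_time <= 1e-14:
            # no time effect and no error: F defined as 0 only if effect is 0
            raise DegenerateDataError("zero residual mean square in RM-ANOVA")
        raise DegenerateDataError("zero residual mean square in RM-ANOVA")
    F = (ss_time / df_time) / ms_err
    p = float(stats.f.sf(F, df_time, df_err))
    return TestResult(statistic=float(F), p_value=p, label="rm_anova", df=(df_time, df_err))


def greenhouse_geisser_epsilon(scores: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor (optional adjunct)."""
    y = np.asarray(scores, float)
    S = np.cov(y, rowvar=False, ddof=1)
    t = S.shape[0]
    sbar = S.mean()
    row = S.mean(axis=1)
    num = (t * (np.trace(S) / t - sbar)) ** 2
    den = (t - 1) * (np.sum(S**2) - 2 * t * np.sum(row**2) + t**2 * sbar**2)
    return float(num / den)


def tukey_hsd(
    group_means: np.ndarray,
    ms_error: float,
    n_per_group: int,
    df_error: float,
    labels: list[str] | None = None,
) -> list[TestResult]:
    """Tukey HSD pairwise comparisons from summary statistics.

    q_ij = |mean_i - mean_j| / sqrt(ms_error / n); p from the studentized
    range distribution with k groups and ``df_error`` error df.
    """
    means = np.asarray(group_means, float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    labels = labels or [f"g{i}" for i in range(k)]
    se = math.sqrt(ms_error / n_per_group)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_error))
            out.append(
                TestResult(
                    statistic=float(q),
                    p_value=min(1.0, p),
                    label=f"tukey:{labels[i]}-{labels[j]}",
                    df=(float(k), float(df_error)),
                )
            )
    return out


def one_way_anova(groups: list[np.ndarray]) -> TestResult:
    """Classical between/within one-way ANOVA over independent groups."""
    gs = [np.asarray(g, float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.var(g, ddof=1) == 0 for g in gs):
        raise DegenerateDataError("zero within-group variance in every group")
    F, p = stats.f_oneway(*gs)
    df1 = len(gs) - 1
    df2 = sum(g.size for g in gs) - len(gs)
    return TestResult(
        statistic=float(F), p_value=float(p), label="one_way_anova", df=(df1, df2)
    )


def _critical_r(n: int, alpha: float, sides: str) -> float:
    """Null critical sample correlation from the t distribution."""
    df = n - 2
    tail = alpha / 2 if sides == "two" else alpha
    tcrit = stats.t.ppf(1 - tail, df)
    return float(tcrit / math.sqrt(df + tcrit**2))


def correlation_power(r: float, query: PowerQuery) -> float:
    """Power of the correlation test at true effect ``r``.

    Fisher-z approximation with the standard bias correction
    ``atanh(r) + r / (2(n-1))`` for the mean and SE ``1/sqrt(n-3)``; the
    rejection region comes from the t-based critical correlation.
    """
    n = query.n
    rcrit = _critical_r(n, query.alpha, query.sides)
    se = 1.0 / math.sqrt(n - 3)
    mu = math.atanh(r) + r / (2 * (n - 1))
    zhi = math.atanh(rcrit)
    power = stats.norm.sf((zhi - mu) / se)
    if query.sides == "two":
        power += stats.norm.cdf((math.atanh(-rcrit) - mu) / se)
    return float(power)


def power_min_r(query: PowerQuery) -> float:
    """Minimal detectable correlation for the requested power.

    Numerically inverts :func:`correlation_power` in r; monotone decreasing
    in n.  As power approaches alpha the solution approaches 0.
    """
    if query.power <= query.alpha:
        raise ValueError("requested power must exceed alpha")
    f = lambda r: correlation_power(r, query) - query.power
    return float(optimize.brentq(f, 1e-12, 1 - 1e-12, xtol=1e-6))


def compare_to_reference(sample_mean: float, norm: ReferenceNorm) -> NormBand:
    """Classify a sample mean against the control mean +- 1 SD band."""
    lo = norm.control_mean - norm.control_sd
    hi = norm.control_mean + norm.control_sd
    if sample_mean < lo:
        return NormBand.below
    if sample_mean > hi:
        return NormBand.above_1sd
    return NormBand.within_1sd
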