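"""Cohort statistics: correlations, inter-rater reliability, sample sizes.

Pearson r (with the GLM slope t-test p-value), Spearman rank correlation for
ordinal manual ratings, two-way random-effects intraclass correlation for
rater agreement, and the two design-stage sample-size calculators used when
planning a correlation study or a two-arm trial.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "ReliabilityResult",
    "pearson",
    "spearman",
    "correlation_from_r",
    "interrater_reliability",
    "sample_size_correlation",
    "sample_size_ttest",
    "power_ttest",
]


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """Correlation coefficient with its squared value and two-sided p."""

    r: float
    r2: float
    p: float
    n: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"r out of [-1, 1]: {self.r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of [0, 1]: {self.p}")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclasses.dataclass(frozen=True)
class ReliabilityResult:
    """Intraclass correlation with its F-test p-value."""

    icc: float
    p: float
    f: float
    raters: int
    subjects: int
    model: str = "ICC(2,1): two-way random effects, absolute agreement, single measure"


def _validate_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    return x, y


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the GLM slope t-test p.

    The two-sided p-value is that of ``t = r*sqrt(n-2)/sqrt(1-r^2)`` on
    ``n - 2`` degrees of freedom, identical to the t-test of the slope in the
    simple linear (general linear model) regression of y on x.
    """
    x, y = _validate_pair(x, y)
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue), n=x.size, method="pearson")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank-order correlation (tie-corrected mid-ranks)."""
    x, y = _validate_pair(x, y)
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, p=float(res.pvalue), n=x.size, method="spearman")


def correlation_from_r(r: float, n: int, method: str = "pearson") -> CorrelationResult:
    """Result object for a published correlation coefficient and sample size.

    Recomputes the two-sided t-based p-value from ``r`` and ``n`` alone;
    useful for re-deriving r² and significance from summary tables.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not -1.0 < r < 1.0:
        raise ValueError("r must be strictly inside (-1, 1) for a finite t")
    t = abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(sps.t.sf(t, n - 2))
    return CorrelationResult(r=float(r), r2=r * r, p=p, n=int(n), method=method)


def interrater_reliability(ratings) -> ReliabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a complete raters x subjects table (each of k raters rates
    all n subjects).  From the two-way ANOVA mean squares — between-subject
    MSR, between-rater MSC and residual MSE —

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the subject-effect F-test ``F = MSR/MSE`` on (n-1, (n-1)(k-1))
    degrees of freedom for the p-value.  Chosen over the one-way and
    consistency variants because a fixed panel of trained raters rated every
    animal and systematic rater offsets should count as disagreement.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2:
        raise ValueError("ratings must be a 2D raters x subjects table")
    if not np.all(np.isfinite(y)):
        raise ValueError("ratings table is incomplete (non-finite entries)")
    k, n = y.shape
    if k < 2 or n < 3:
        raise ValueError("need at least 2 raters and 3 subjects")

    grand = y.mean()
    subject_means = y.mean(axis=0)
    rater_means = y.mean(axis=1)
    ss_subjects = k * float(((subject_means - grand) ** 2).sum())
    ss_raters = n * float(((rater_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_raters

    msr = ss_subjects / (n - 1)
    msc = ss_raters / (k - 1)
    mse = max(ss_error / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        raise ValueError("no variance in ratings; ICC undefined")
    icc = (msr - mse) / denom
    if mse == 0.0:
        f = math.inf
        p = 0.0
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ReliabilityResult(icc=float(icc), p=p, f=float(f), raters=k, subjects=n)


def sample_size_correlation(
    r2: float,
    alpha: float = 0.05,
    power: float = 0.8,
    sides: int = 2,
) -> int:
    """Smallest n detecting a correlation of effect size r² (Fisher-z).

    Interprets the effect size as ``r = sqrt(r2)`` and uses the Fisher
    z-approximation: ``n = ceil(((z_{1-alpha/sides} + z_{power}) /
    atanh(r))^2 + 3)``.
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError(f"r2 must be strictly inside (0, 1), got {r2}")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    za = sps.norm.ppf(1.0 - alpha / sides)
    zb = sps.norm.ppf(power)
    c = math.atanh(math.sqrt(r2))
    return int(math.ceil(((za + zb) / c) ** 2 + 3.0))


def power_ttest(n_per_group: int, d: float, alpha: float = 0.05, sides: int = 1) -> float:
    """Power of the two-sample equal-n t-test via the noncentral t.

    Noncentrality ``d*sqrt(n/2)`` on ``2n - 2`` degrees of freedom; the
    two-sided version adds the (negligible for d > 0) lower tail.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 per group")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1.0 - alpha / sides, df)
    power = float(sps.nct.sf(tcrit, df, nc))
    if sides == 2:
        power += float(sps.nct.cdf(-tcrit, df, nc))
    return power


def sample_size_ttest(
    d: float,
    alpha: float = 0.05,
    power: float = 0.8,
    sides: int = 1,
    max_n: int = 100_000,
) -> int:
    """Smallest per-group n with two-sample t-test power >= target.

    Defaults to one-sided, the convention under which d = 1, alpha = 0.05 and
    power 0.8 give 14 animals per group.  Searches n upward using the exact
    noncentral-t power function.
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0")
    if not (0 < power < 1):
        raise ValueError("power must be in (0, 1)")
    for n in range(2, max_n + 1):
        if power_ttest(n, d, alpha=alpha, sides=sides) >= power:
            return n
    raise ValueError(f"power {power} not attainable with n <= {max_n}")
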