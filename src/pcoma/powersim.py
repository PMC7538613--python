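"""ANOVA-vs-ANCOVA power simulation for a two-arm preclinical trial.

A hypothetical treatment trial with a standardized effect of d within-group
SDs is simulated together with a normally distributed covariate (think:
collateral-vessel patency score) that explains a fraction r² of the outcome
variance within each group.  Each simulated experiment is analyzed once
ignoring the covariate (one-way ANOVA) and once adjusting for it (ANCOVA);
the fraction of significant experiments estimates the power of each analysis.
A closed-form noncentral-t oracle (`analytic_power`) provides the exact
power for verification.

Data-generating process per subject (group g ∈ {0, 1})::

    X ~ N(0, 1)
    Y = d*g + sqrt(r2)*X + sqrt(1 - r2)*E,   E ~ N(0, 1)

so the within-group outcome variance is exactly 1, the within-group
covariate-outcome squared correlation is exactly r², and the standardized
group effect is exactly d.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PAPER_R2_GRID",
    "TrialConfig",
    "SimResult",
    "simulate_trial",
    "analyze_trial",
    "estimate_power",
    "power_grid",
    "analytic_power",
]

#: Grid of covariate-outcome squared correlations simulated in the study.
PAPER_R2_GRID: tuple[float, ...] = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.29, 0.36, 0.49, 0.64)

_METHOD_CODE = {"anova": 11, "ancova": 13}  # fixed tags for substream seeding


@dataclasses.dataclass(frozen=True)
class TrialConfig:
    """Design of the simulated two-arm trial.

    d: standardized effect size in within-group SD units (1.0 is typical for
    preclinical stroke research); n_per_group animals per arm; alpha the
    significance level; r2 the within-group squared correlation between the
    covariate and the outcome; sides 1 or 2.
    """

    d: float = 1.0
    n_per_group: int = 14
    alpha: float = 0.05
    r2: float = 0.0
    sides: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 <= self.r2 < 1.0:
            raise ValueError("r2 must be in [0, 1)")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")

    def with_(self, **kwargs) -> "TrialConfig":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass(frozen=True)
class SimResult:
    """Monte-Carlo power estimate with its binomial standard error."""

    method: str
    reps: int
    power: float
    mc_se: float


def _draw(d: float, n: int, r2: float, reps: int, rng: np.random.Generator):
    """Simulate `reps` trials at once; returns (group, X, Y) arrays."""
    group = np.concatenate([np.zeros(n), np.ones(n)])
    x = rng.standard_normal((reps, 2 * n))
    eps = rng.standard_normal((reps, 2 * n))
    y = d * group[None, :] + math.sqrt(r2) * x + math.sqrt(1.0 - r2) * eps
    return group, x, y


def simulate_trial(config: TrialConfig) -> pd.DataFrame:
    """One simulated experiment as a tidy table (group, covariate, outcome)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7]))
    group, x, y = _draw(config.d, config.n_per_group, config.r2, 1, rng)
    return pd.DataFrame({"group": group.astype(int), "covariate": x[0], "outcome": y[0]})


def _group_tstats(group: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized two-sample t statistic of group 1 minus group 0 per row."""
    g1 = group == 1
    n1, n0 = int(g1.sum()), int((~g1).sum())
    m1 = y[:, g1].mean(axis=1)
    m0 = y[:, ~g1].mean(axis=1)
    ss1 = ((y[:, g1] - m1[:, None]) ** 2).sum(axis=1)
    ss0 = ((y[:, ~g1] - m0[:, None]) ** 2).sum(axis=1)
    df = n1 + n0 - 2
    sp2 = (ss1 + ss0) / df
    t = (m1 - m0) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
    return t, df


def _ancova_tstats(group: np.ndarray, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorized t statistic of the group coefficient in Y ~ 1 + group + X.

    Frisch-Waugh-Lovell: residualize the group indicator and the outcome on
    [1, X] per replicate, then regress residual on residual.
    """
    n = group.size
    gc = group - group.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    gx = gc[None, :] - ((gc[None, :] * xc).sum(axis=1) / sxx)[:, None] * xc
    yx = yc - ((yc * xc).sum(axis=1) / sxx)[:, None] * xc
    sgg = (gx * gx).sum(axis=1)
    beta = (gx * yx).sum(axis=1) / sgg
    rss = (yx * yx).sum(axis=1) - beta**2 * sgg
    df = n - 3
    se = np.sqrt(rss / df / sgg)
    return beta / se, df


def _pvalues(t: np.ndarray, df: int, sides: int) -> np.ndarray:
    if sides == 2:
        return 2.0 * sps.t.sf(np.abs(t), df)
    return sps.t.sf(t, df)  # one-sided: treatment effect in the positive direction


def analyze_trial(
    data: pd.DataFrame,
    method: str = "ancova",
    alpha: float = 0.05,
    sides: int = 2,
) -> tuple[float, bool]:
    """Test the group effect in one experiment; returns (p, significant).

    ``method="anova"`` fits ``outcome ~ group`` (for two groups the F test is
    the squared two-sample t test); ``method="ancova"`` fits ``outcome ~
    group + covariate`` and tests the group coefficient.  Model fitting is
    delegated to statsmodels OLS.
    """
    import statsmodels.api as sm

    if method not in ("anova", "ancova"):
        raise ValueError(f"method must be 'anova' or 'ancova', got {method!r}")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    group = np.asarray(data["group"], dtype=float)
    if not (np.any(group == 0) and np.any(group == 1)):
        raise ValueError("both groups must be non-empty")
    cols = [group]
    if method == "ancova":
        cov = np.asarray(data["covariate"], dtype=float)
        if np.std(cov) == 0:
            raise ValueError("covariate is constant; ANCOVA is degenerate")
        cols.append(cov)
    design = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(np.asarray(data["outcome"], dtype=float), design).fit()
    tval = float(fit.tvalues[1])
    if sides == 2:
        p = float(fit.pvalues[1])
    else:
        p = float(sps.t.sf(tval, fit.df_resid))
    return p, bool(p < alpha)


def estimate_power(config: TrialConfig, reps: int = 1000, method: str = "ancova") -> SimResult:
    """Monte-Carlo power of one analysis method under ``config``.

    Uses a vectorized closed-form least-squares engine (validated against
    `analyze_trial` and `analytic_power` in the test-suite) so that 10,000
    replicates complete in well under a second.  The RNG substream is derived
    from (seed, method), independent of ``reps``-batching.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful power estimate")
    if method not in _METHOD_CODE:
        raise ValueError(f"method must be 'anova' or 'ancova', got {method!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _METHOD_CODE[method]]))
    group, x, y = _draw(config.d, config.n_per_group, config.r2, reps, rng)
    if method == "anova":
        t, df = _group_tstats(group, y)
    else:
        t, df = _ancova_tstats(group, x, y)
    p = _pvalues(t, df, config.sides)
    power = float(np.mean(p < config.alpha))
    mc_se = math.sqrt(power * (1.0 - power) / reps)
    return SimResult(method=method, reps=reps, power=power, mc_se=mc_se)


def power_grid(
    base: TrialConfig,
    r2_values: Sequence[float] = PAPER_R2_GRID,
    reps: int = 1000,
) -> pd.DataFrame:
    """Estimate ANOVA and ANCOVA power over a grid of covariate correlations.

    Returns one row per r² with both power estimates, the difference in
    percentage points (``delta_percentage_points = 100*(ancova - anova)``)
    and Monte-Carlo standard errors (``mc_se_delta`` pools both methods).
    Each (r², method) pair runs on an independent RNG substream derived from
    the master seed, so the grid is reproducible and order-independent.
    """
    rows = []
    for i, r2 in enumerate(r2_values):
        if not 0.0 <= r2 < 1.0:
            raise ValueError(f"grid r2 values must be in [0, 1), got {r2}")
        results = {}
        for method in ("anova", "ancova"):
            cfg = base.with_(r2=float(r2))
            rng_seed = np.random.SeedSequence([int(base.seed), i, _METHOD_CODE[method]])
            rng = np.random.default_rng(rng_seed)
            group, x, y = _draw(cfg.d, cfg.n_per_group, cfg.r2, reps, rng)
            t, df = _group_tstats(group, y) if method == "anova" else _ancova_tstats(group, x, y)
            p = _pvalues(t, df, cfg.sides)
            power = float(np.mean(p < cfg.alpha))
            results[method] = SimResult(method, reps, power, math.sqrt(power * (1 - power) / reps))
        anova, ancova = results["anova"], results["ancova"]
        rows.append(
            {
                "r2": float(r2),
                "power_anova": anova.power,
                "power_ancova": ancova.power,
                "delta_percentage_points": 100.0 * (ancova.power - anova.power),
                "mc_se_anova": anova.mc_se,
                "mc_se_ancova": ancova.mc_se,
                "mc_se_delta": 100.0 * math.hypot(anova.mc_se, ancova.mc_se),
            }
        )
    return pd.DataFrame(rows)


def _nct_tail(tcrit: float, df: int, nc, sides: int):
    power = sps.nct.sf(tcrit, df, nc)
    if sides == 2:
        power = power + sps.nct.cdf(-tcrit, df, nc)
    return power


def analytic_power(
    d: float,
    n_per_group: int,
    r2: float = 0.0,
    alpha: float = 0.05,
    sides: int = 2,
    method: str = "anova",
    covariate: str = "random",
) -> float:
    """Noncentral-t power of either analysis under the simulation DGP.

    Adjusting for a covariate that explains r² of the outcome variance
    shrinks the residual SD by sqrt(1 - r²), inflating the noncentrality to
    ``d*sqrt(n/2)/sqrt(1-r2)`` at the cost of one residual degree of freedom
    (df = 2n - 3 instead of 2n - 2).

    Because the covariate is balanced by randomization only, its sample
    imbalance between the arms inflates the standard error of the adjusted
    group effect: conditional on the data, the ANCOVA noncentrality is
    ``d*sqrt(n/2)*sqrt(1-B)/sqrt(1-r2)`` where ``B``, the squared sample
    correlation between the group indicator and the covariate, follows a
    Beta(1/2, (2n-2)/2) distribution.  ``covariate="random"`` (default)
    integrates the noncentral-t tail over that distribution and is exact for
    the simulation; ``covariate="fixed"`` sets B = 0, the classical
    conditional formula, which overstates ANCOVA power by ~1.5 percentage
    points at n = 14.  The ANOVA power is unaffected.
    """
    if method not in ("anova", "ancova"):
        raise ValueError(f"method must be 'anova' or 'ancova', got {method!r}")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if covariate not in ("random", "fixed"):
        raise ValueError(f"covariate must be 'random' or 'fixed', got {covariate!r}")
    if method == "anova":
        df = 2 * n_per_group - 2
        nc = d * math.sqrt(n_per_group / 2.0)
        tcrit = sps.t.ppf(1.0 - alpha / sides, df)
        return float(_nct_tail(tcrit, df, nc, sides))

    if not 0.0 <= r2 < 1.0:
        raise ValueError("ancova requires r2 in [0, 1)")
    df = 2 * n_per_group - 3
    nc0 = d * math.sqrt(n_per_group / 2.0) / math.sqrt(1.0 - r2)
    tcrit = sps.t.ppf(1.0 - alpha / sides, df)
    if covariate == "fixed" or d == 0.0:
        return float(_nct_tail(tcrit, df, nc0, sides))
    # Gauss-Legendre in the probability domain of B ~ Beta(1/2, n-1)
    nodes, weights = np.polynomial.legendre.leggauss(64)
    u = 0.5 * (nodes + 1.0)
    b = sps.beta.ppf(u, 0.5, n_per_group - 1.0)
    tails = _nct_tail(tcrit, df, nc0 * np.sqrt(1.0 - b), sides)
    return float(np.sum(0.5 * weights * tails))
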