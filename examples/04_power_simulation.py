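"""ANOVA vs ANCOVA power for a two-arm trial with a prognostic covariate.

Simulates the standard preclinical stroke design (d = 1, 14 animals per
group, alpha 0.05 two-sided) over ten covariate strengths and compares the
Monte-Carlo power estimates with the exact noncentral-t oracle.  The delta
column is the power gained (percentage points) by adjusting for the
covariate in the analysis.
"""

import pcoma as pc

grid = pc.power_grid(pc.TrialConfig(d=1.0, n_per_group=14, seed=7), reps=10000)
print(f"{'r2':>5} {'anova':>7} {'ancova':>7} {'delta(pp)':>9} {'oracle delta':>12}")
anova_exact = pc.analytic_power(1.0, 14, method="anova")
for _, row in grid.iterrows():
    oracle = 100 * (pc.analytic_power(1.0, 14, row.r2, method="ancova") - anova_exact)
    print(f"{row.r2:5.2f} {row.power_anova:7.3f} {row.power_ancova:7.3f} "
          f"{row.delta_percentage_points:9.2f} {oracle:12.2f}")

# The gain grows with the covariate-outcome correlation: worthless covariates
# cost ~2 points (one df plus chance imbalance), while a covariate explaining
# 64% of the outcome variance buys ~26 points of power at this sample size.
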