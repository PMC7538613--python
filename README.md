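# pcoma

Tools for a recurring problem in experimental stroke research: lesion sizes
after filament middle cerebral artery occlusion (fMCAo) in C57BL/6 mice vary
enormously, and a major driver is whether each animal's posterior
communicating artery (PcomA) — the collateral connecting the superior
cerebellar artery (SCA) and the posterior cerebral artery (PCA) — carries
flow. `pcoma` implements:

- **a semiquantitative PcomA patency score** from atlas-registered
  time-of-flight (TOF) MR angiograms,
- **edema-corrected lesion volumetry** (lesion as % of hemisphere in atlas
  space),
- **cohort statistics** (Pearson/Spearman correlation, ICC(2,1) rater
  agreement, sample-size calculators),
- **an ANOVA-vs-ANCOVA power simulation** quantifying how much statistical
  power is gained by including the patency score as a covariate in the
  outcome analysis, with an exact noncentral-t oracle,
- **a seeded phantom generator** (vessel cylinders with partial-volume
  rasterization plus Rician noise, lesion blobs, cohorts with planted
  correlations) so every component is testable against known ground truth.

It is aimed at preclinical imaging groups who already register their mouse
MRI to an atlas and want a reproducible, scriptable patency readout plus the
design-stage numbers for covariate-adjusted analyses.

## The score

For a magnitude TOF volume, the Gaussian channel noise is estimated from a
signal-free background region as `sigma = SD(background) / sqrt(2 - pi/2)`
(the background of a magnitude image is Rayleigh distributed;
`sqrt(2 - pi/2) ≈ 0.6551`). The volume is converted to a voxelwise SNR map,
everything below 1/10 of the dataset maximum is set to NaN, and the score is

```
score = max SNR inside (SCA–PCA corridor ∩ 10-slice slab)
```

— a dimensionless correlate of PcomA flow, invariant under rescaling of the
image intensities. Higher flow → higher score; an absent vessel leaves only
the background ceiling.

For the trial simulation, each subject in a two-arm design has covariate
`X ~ N(0,1)` and outcome `Y = d·group + sqrt(r²)·X + sqrt(1−r²)·ε`, so the
within-group variance is 1, the within-group covariate–outcome squared
correlation is exactly `r²`, and the standardized effect is exactly `d`.
Each simulated experiment is analyzed by one-way ANOVA (`Y ~ group`) and by
ANCOVA (`Y ~ group + X`); power is the fraction of significant replicates.

## Worked example

`python examples/01_score_patency.py` renders a circle-of-Willis phantom
with a patent left PcomA (planted flow SNR 12) and an absent right PcomA,
then scores both sides:

```
noise sigma: 1.990 a.u. (true 2.000)
threshold cutoff: 1.46 (SNR units)
left  PcomA score: 11.34  (planted flow SNR 12)
right PcomA score:  3.89  (planted flow SNR 0)
```

The left score recovers the planted flow SNR (partial-volume losses of the
0.12 mm vessel on the 0.1 mm grid pull it slightly below 12); the right
corridor contains only noise, so its score is the background ceiling.

`python examples/04_power_simulation.py` reproduces the covariate-adjustment
power curve at d = 1, n = 14 per group, two-sided α = 0.05 (10,000
replicates per cell, against the exact oracle):

```
   r2   anova  ancova delta(pp) oracle delta
 0.00   0.723   0.698     -2.52        -1.82
 0.25   0.721   0.820      9.93         9.91
 0.36   0.720   0.876     15.60        15.42
 0.64   0.719   0.985     26.61        26.39
```

A worthless covariate costs ~2 points of power (one degree of freedom plus
its chance imbalance between arms); a covariate explaining 64% of the
outcome variance buys ~26 points. Other examples cover lesion volumetry,
cohort statistics and the end-to-end pipeline; the `pcoma` console command
exposes the same steps (`pcoma score`, `pcoma lesion`, `pcoma power`,
`pcoma run`, …) for shell use.

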