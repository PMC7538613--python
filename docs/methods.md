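# Methods

## The patency score

TOF angiography renders flowing blood bright without contrast agent, so the
flow through a collateral can be read off a magnitude volume as its maximal
flow-related SNR. The implemented chain is:

1. **Noise estimation.** Magnitude background noise is Rayleigh distributed
   with SD `sigma·sqrt(2 − π/2)`, where `sigma` is the per-channel Gaussian
   noise. `estimate_noise` divides the background SD by `0.6551` to recover
   `sigma`. The correction factor is a config key (`noise_correction`)
   because multi-channel coil combinations follow higher-order chi
   distributions with different factors. The background region is
   user-supplied; the fallback is the 8 corner sub-cubes of the volume
   (1/8 of each axis), which contain air in the scout geometry assumed here.
   The corner estimator is unbiased on pure noise (checked in the tests).
2. **SNR map.** Voxel intensity divided by `sigma`. No threshold yet.
3. **Thresholding.** Voxels below `fraction × max(map)` become NaN;
   `fraction` defaults to 1/10. The maximum is taken over the whole volume,
   not the ROI — ROI-local thresholding would make an absent vessel
   unscorable, because the cutoff would collapse to the local noise ceiling.
   The operation is idempotent.
4. **Score.** Maximum non-NaN SNR inside the SCA–PCA corridor intersected
   with a 10-slice slab (inclusive 0-based indices; volumes are assumed
   atlas-registered, so the slab is fixed across animals). If every corridor
   voxel fell below the cutoff the score is 0 with a `no_signal` flag — the
   natural floor, keeping the score usable as a covariate. An empty
   corridor∩slab *before* thresholding is a geometry error instead.

The score is invariant under global intensity rescaling (both the SNR
normalization and the fractional threshold are scale-free), which the test
suite asserts end to end.

Two readings of "maximum of the dataset" were possible for the threshold
(whole volume vs the 10-slice slab); the whole volume is used. Only the
side ipsilateral to the lesion is scored by default (left, matching a
left-sided occlusion), with the side configurable. Patency calls for
phenotype classification default to `score > 0` and can be overridden by
manual calls; cohort phenotypes are *complete* (both PcomAs patent),
*unilateral*, or *absent*, with integer-rounded percentages.

Manual-measurement support: `mip` computes maximum intensity projections;
`vessel_diameter` measures a full-width-at-half-maximum diameter along a
profile perpendicular to the vessel, with the half-maximum referenced to
(peak − local background), sub-pixel crossings by linear interpolation, and
a `no vessel` error when the peak does not exceed background by 5 background
SDs (the default margin). `diameter_percent_basilar` expresses a PcomA
diameter relative to the basilar artery, the convention for reporting
collateral caliber.

## Lesion volumetry

Edema-corrected lesion volume is `100 × lesion voxels / hemisphere voxels`
with both masks on the same atlas grid, making the ratio independent of
voxel size (absolute mm³ is offered separately). The denominator is the
ipsilesional hemisphere by default — the natural normalization when the
lesion mask is required to lie inside it — and is configurable. Lesion
voxels outside the hemisphere raise an error carrying their count; they
indicate registration or delineation faults that a silent ratio would hide.

## Phantoms

`make_angiophantom` renders vessels as cylinders around polyline
centerlines. Coverage per voxel is computed by 3×3×3 supersampling, so
sub-voxel diameters yield graded partial-volume intensities — important
because recruited mouse PcomAs (0.08–0.15 mm) sit at the 0.1 mm voxel
scale. The magnitude image is `|signal + n₁ + i·n₂|` with independent
Gaussian channels of SD `noise_sigma` (default 2.0 a.u.): Rician over
vessels, Rayleigh background. The default geometry is a stylized posterior
circle of Willis on an 8.0 × 8.0 × 4.8 mm grid (0.1 mm voxels): basilar
artery (0.26 mm) splitting into SCAs, PCAs above, and one PcomA per side
(default 0.12 mm, i.e. ~46% of the basilar caliber) bridging them through a
box-shaped SCA–PCA corridor that contains no other vessel. Default planted
flow SNR is 12, comfortably above the 1/10 threshold but realistic for
small vessels.

A note on recovery accuracy: the score is a *maximum* over many voxels, so
for a thick vessel at planted SNR `s` it concentrates around `s` plus an
order-statistics excess of ~1.5–2 (the maximum of dozens of ≈N(s, 1)
draws). For the default sub-voxel PcomA the partial-volume loss offsets
this excess, and the recovered score lies within ±10% of the planted SNR
on average (the recovery tests therefore compare the mean over several
phantom seeds, and thick-vessel recovery against an order-statistics-aware
rendering oracle rather than the naive `≈ s` expectation).

`make_lesion_phantom` grows a connected blob from a deep seed point inside
the ipsilateral half of an ellipsoidal brain, in roughly concentric order
with seeded jitter, stopping at the requested fraction of hemisphere voxels
(exact to one voxel). `make_cohort` draws scores `N(8, 4²)` and lesions
`a + b·score + ε` with `b = −sqrt(r²)·σ_lesion/σ_score`, so the population
squared correlation and the slope sign are exact; lesion percentages are
clipped to [0, 100] last and the clip count is reported. Cohort defaults
(43 animals, r² = 0.34, negative slope, lesions 20 ± 8%) describe a pooled
fMCAo control cohort. All generators take a single seed and are
bit-reproducible; no global RNG state is touched.

What the phantoms do **not** emulate: flow saturation and inflow dynamics,
k-space acquisition and zero-filling, coil sensitivity profiles, motion,
registration error, and real vascular tortuosity. Passing tests therefore
demonstrate that the *measurement chain* is correct and calibrated, not
that it is robust to every artifact of in vivo data.

## Cohort statistics

`pearson` reports r, r², and the two-sided p of the slope t-test in the
simple linear model (t = r·√(n−2)/√(1−r²) on n−2 df); `spearman` uses
tie-corrected mid-ranks. `correlation_from_r` recomputes r² and p from a
published (r, n) pair. `interrater_reliability` implements ICC(2,1) —
two-way random effects, absolute agreement, single measure — from the
ANOVA mean squares, with the subject-effect F-test for the p-value. This
flavor is the standard choice when a fixed panel of trained raters rates
every subject and systematic rater offsets should count as disagreement;
the variant is recorded in the result's `model` label. With zero residual
mean square the ICC is 1 and p is 0 by convention.

Sample-size calculators: the correlation design uses the Fisher-z
approximation `n = ceil(((z₁₋α/sides + z_power)/atanh(r))² + 3)` with
`r = sqrt(r²)` (effect sizes quoted as r² are interpreted as the squared
correlation); the two-sample design searches the exact noncentral-t power
function (noncentrality `d·√(n/2)`, df `2n−2`) upward for the smallest n
reaching the target. The t-test calculator defaults to **one-sided**
because that convention yields the canonical n = 14 per group at d = 1,
α = 0.05, power 0.8 (two-sided gives 17); sidedness is always explicit.

## Power simulation

`simulate_trial` draws the DGP described in the README; within-group
variance is normalized to 1 so that `d` and `r²` are simultaneously exact
(the variance convention is otherwise arbitrary). The covariate is balanced
by randomization only — no stratification — so its sample imbalance between
arms is part of the simulated truth. `analyze_trial` delegates single-
dataset fits to statsmodels OLS; `estimate_power` uses a vectorized
closed-form least-squares engine (Frisch–Waugh–Lovell residualization for
the ANCOVA t) that the tests verify against statsmodels to machine
precision, making 10,000 replicates sub-second. Each (r², method) cell of
`power_grid` runs on an independent substream derived from the master seed
via `SeedSequence`, so results are reproducible and order-independent.
Significance tests are two-sided by default (F-tests of the linear model,
standard ANOVA/ANCOVA practice); the one-sided option uses the signed t.
The asymmetry with the one-sided design-stage sample size is deliberate and
documented rather than hidden.

`analytic_power` is the verification oracle. For ANOVA it is the plain
noncentral-t tail. For ANCOVA, conditioning on the data makes the t
noncentral with parameter `d·√(n/2)·√(1−B)/√(1−r²)` on `2n−3` df, where
`B` — the squared sample correlation between the group indicator and the
covariate — follows Beta(1/2, n−1) under randomization. The default
(`covariate="random"`) integrates the tail over that distribution by
64-node Gauss–Legendre quadrature in the probability domain and is exact
for the simulation; `covariate="fixed"` sets B = 0, the classical formula,
which overstates ANCOVA power by ~1.5 percentage points at n = 14. A
consequence worth knowing at typical preclinical sample sizes: covariate
adjustment only pays off once r² exceeds ≈ 0.05 — below that, the lost
degree of freedom and the chance imbalance cost more than the variance
reduction (at r² = 0 the exact cost is 1.8 points at n = 14).

## Pipeline and problem sizes

`run_pipeline` chains cohort generation → phantom rendering → scoring →
volumetry → correlation report → power curve, writing five CSV artifacts
whose header comments carry the package version, a 12-hex config hash and
the seed; the log (stderr + `pipeline.log`) holds the timestamps so the
CSVs are byte-reproducible. Config is a flat YAML key-value document with
every key defaulted (threshold fraction 0.1, slab 16–25, correction 0.6551,
α 0.05, 1000 reps) and unknown keys rejected by name.

Default problem sizes were chosen so the full validation suite runs in
seconds on one CPU while keeping Monte-Carlo error well below the effects
of interest: 80×80×48 phantom grids (0.1 mm), 8-animal pipeline demos,
10,000 replicates per cell for power properties (MC SE ≤ 0.5 points), and
20,000–50,000 replicates in the acceptance script (SE ≤ 0.3 points).

## Known limitations

- The SCA–PCA corridor is a fixed atlas-space box matched to the phantom
  geometry; real studies delineate it manually, and automated corridor
  detection is out of scope.
- The score saturates at the planted flow intensity and cannot separate
  vessels whose peak SNR exceeds the corridor's brightest competing
  structure; it is a patency correlate, not a flow measurement.
- An absent vessel scores at the background ceiling (≈4 SNR units under
  default settings), not 0, unless a bright structure elsewhere pushes the
  1/10 cutoff above the corridor background — matching the observation that
  the maximum SNR in the corridor "depends on background intensity and on
  the flow signal present". Dichotomous patency calls should therefore use
  manual ratings or a cohort-specific cutoff rather than `score > 0` when
  absolute absence matters.
- Registration, lesion segmentation and brain extraction are upstream of
  this package and assumed done.
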