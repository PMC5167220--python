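# Methods

## Model and procedure

The pipeline treats a subject's white matter as a set of named bundles, each
a collection of streamlines with point-wise correspondence across subjects.
Correspondence is established positionally: every fiber is resampled to
K equidistant points (default 15) along its arc length, oriented against its
nearest atlas prototype (forward or reversed, whichever minimizes the mean
point-to-point distance, ties keeping the original order), and point index
*i* of fiber slot *j* then corresponds across subjects through the atlas.

**Tensor stage.** The diffusion tensor is fitted per voxel by ordinary
(unweighted) log-linear least squares on `log(S/S₀) = −b gᵀDg`, with S₀ the
mean of the b = 0 volumes. No weighting or robust reweighting (WLS/RESTORE)
is applied: the scalar metrics downstream are the object of interest and the
plain fit is the simplest faithful estimator. Negative eigenvalues from noisy
fits are *not* clipped — clipping silently biases FA — but are reported
through the warnings channel.

**Radial diffusivity convention.** RD is the average of the two minor
eigenvalues, `(λ2+λ3)/2`. Some published formula listings print a `/3`
denominator for this quantity; `compute_scalars(..., rd_denominator=3)`
reproduces that variant, but the operative definition ("the average of λ2 and
λ3") is the default.

**Bundle matching.** Streamline-to-template distance defaults to the
symmetric Hausdorff distance over the resampled vertex sets; directed
Hausdorff and symmetrized mean-closest-point are available for sensitivity
checks. Multi-atlas fusion defaults to the union rule — a fiber joins a
bundle if any atlas subject has a prototype within the acceptance threshold,
recording the minimal distance and winning atlas — with majority voting
behind a flag. The acceptance threshold has no canonical published value; it
defaults to 4 mm and is configuration-exposed. A fiber within threshold of
several bundles goes to the closest one; exact ties break by registry order,
for determinism. Fibers matched through a non-primary atlas are re-anchored
to the nearest slot of the slot-defining (first) atlas when profiles are
built.

**Map fallback.** Atrophy-related low anisotropy can prevent tracking, so
tract statistics must not require complete fiber detection. For every atlas
fiber slot without a matched subject fiber, the four metric volumes are
sampled by trilinear interpolation at the prototype's own point locations in
the subject's (registered) maps, with a provenance flag. Points outside the
field of view take the nearest in-volume voxel value and are flagged.

**Statistics.** At each pooled point the metric is regressed by OLS on
[intercept, disease indicator, age, sex (M = 1), brain volume]; positive t
means higher values in the disease group. Because every point shares the
design matrix, the 87,885 fits per metric reduce to two matrix products.
P-values are two-sided from the t distribution with the residual degrees of
freedom (n − 5 with covariates); the effect-size transform r = √(t²/(t²+df))
deliberately uses df = n − 2, the convention of the summary tables this
package mirrors. These two df conventions coexist by design: one governs
inference, the other the reported effect scale.

Benjamini–Hochberg correction is applied over the *full* pooled vector of a
metric/comparison (all bundles, slots, points — not per bundle), at
q = 0.05. The per-bundle "% tract affected" counts points that are both
FDR-significant and in the hypothesized direction (FA decrease, diffusivity
increases for disease vs control), applied as a direction mask on two-sided
tests rather than as one-sided tests. Whether published percentages count
points or whole fibers is ambiguous; the default counts points, and a
fiber-unit variant (a fiber is affected when ≥ 50% of its points qualify) is
available via `unit="fibers"`. Bundle-level r defaults to the mean of
point-wise r, with an `r(mean t)` alternative behind a flag. The MMSE
association keeps the age/sex/brain-volume covariates by default
(`include_covariates=False` drops them).

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical* structure the analysis assumes:
the 21-bundle registry with its template fiber counts (5859 fibers), group
sizes 33/20/23, group age distributions (59.4 ± 9.6, 60.7 ± 10.7,
59.0 ± 5.0 years), sex ratios (14M/19F, 8M/12F, 10M/13F), MMSE distributions
(29.1 ± 0.9, 24.1 ± 4.7, 23.4 ± 4.2) and a brain-volume covariate
(1.10 ± 0.10 × 10⁶ mm³). Scalar baselines are plausible defaults, not fitted
values: per-bundle FA in [0.30, 0.70], MD in [0.70, 0.80] × 10⁻³ mm²/s, RD in
[0.45, 0.60] × 10⁻³, AX in [1.05, 1.30] × 10⁻³, each with a smooth
low-amplitude along-tract modulation. Point-level noise is independent
Gaussian (FA 0.04; MD/RD 6 × 10⁻⁵; AX 8 × 10⁻⁵ mm²/s); real along-tract
profiles are spatially autocorrelated, which the default does not model (a
correlated-noise mode is a natural extension), so passing recovery tests
demonstrate correctness of the machinery, not field-realistic power.
Covariate slopes default to a mild age-related FA decline (−0.001/yr) and
diffusivity increase (+1.5 × 10⁻⁶/yr), small sex offsets and a zero
brain-volume slope. Effects are additive on the scalars directly — exact
control of standardized effect sizes for recovery experiments — rather than
simulated through tensors; tensor-level simulation is exercised separately by
the forward-model round-trip tests. Bundle geometry (spline centerlines on a
100 mm grid with 1.5 mm fiber spread) makes extraction unambiguous by
construction; registration error is not simulated. MMSE is coupled to each
subject's global mean MD (1 point per cohort SD by default) so the cognition
association has a recoverable planted signal.

## Numerical choices

- Resampling interpolates linearly in cumulative arc length; endpoints are
  preserved exactly.
- A regression point whose response is numerically constant (coefficient and
  SE both at rounding level relative to the response RMS) reports t = 0,
  p = 1 instead of a noise ratio.
- BH-FDR delegates to `statsmodels.stats.multitest.multipletests` and derives
  the critical P as the largest rejected p-value (0 when none); tests verify
  exact agreement with a literal step-up implementation.
- Collinear designs and n ≤ p are rejected with the offending columns named.
- All generators draw from seeded PCG64 streams keyed by (seed, stage,
  bundle index); no iteration-order or time dependence.

## Problem sizes used in validation

Planted-effect recovery runs at the full registry scale (5859 fibers, 87,885
points per metric, 33 vs 20 subjects, d = 1.2 in points 5–10 of one bundle).
The global-null false-discovery simulation uses 200 replicate cohorts at 10%
of the registry's fiber counts (587 slots, 8805 points per metric) with the
full 76-subject design — FDR control does not depend on the number of tests,
so the reduced width is a pure efficiency choice; the acceptance bound allows
three Monte-Carlo standard errors above q.

## Known limitations

- No tractography and no registration: subjects are assumed in a common
  space (the generator guarantees this; real data must be pre-registered).
- Independent-noise defaults understate the multiplicity burden's effective
  correlation in real data.
- OLS only — no mixed-effects, permutation or cluster-level inference.
- The fiber-vs-point ambiguity of "% tract affected" is resolved by
  configuration, not by assumption.
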