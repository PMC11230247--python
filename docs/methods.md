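# Methods

`fetalfold` implements a surface-based analysis of how the microstructure
of the transient fetal brain compartments — the cortical plate (CP) and
the subplate (SP) — couples with the emergence of cortical folds across
gestational weeks 24–36, together with a synthetic cohort generator that
supplies ground truth for every stage. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
tests do and do not establish about real data.

## Surface model and sulcal depth

Surfaces are closed, consistently wound triangle meshes with template
vertex correspondence. The template is a recursively subdivided
icosahedron re-projected to the unit sphere; level 6 gives the
standard-format surface of 40,962 vertices and 81,920 triangles used for
template-resolution checks, while analyses at desk scale run on level 3
(642 vertices) or level 4 (2,562 vertices). Subdivision level, not vertex
count, is the configuration parameter.

Geometric noise is removed with Taubin lambda/mu smoothing (defaults
`lambda_shrink = 0.33`, `mu_inflate = -0.34`, 10 iterations — the classic
low-shrinkage setting). The alternating inflate step keeps the enclosed
volume within a fraction of a percent on noisy spheres where matched pure
Laplacian smoothing shrinks by several percent; both behaviours are
asserted in the tests.

**Sulcal depth** is defined here as the Euclidean distance (mm) of each
vertex from the outer convex hull of the surface. For a point inside a
convex polytope, the distance to the boundary equals the minimum
perpendicular distance over the facet planes, so the computation is exact
and fully vectorised (no nearest-triangle search). This hull-distance
definition is a deliberate simplification of volumetric distance-transform
depth measures: it is exact for convex (unfolded) brains, well behaved for
the single-scale synthetic folds used here, and translation/rotation
invariant with linear scaling (tested). It under-reports depth for wide,
shallow invaginations, where the hull "lid" dips towards the surface; the
narrow-pit construction used in the ground-truth tests keeps this bias
below 10 % of the programmed displacement, which is the tolerance the
tests assert. The interface returns a per-vertex metric, leaving room for
a volumetric/geodesic variant without changing callers.

**Neighbourhoods.** Patches are k-ring sets on the edge graph (breadth
first, centre included), `k = 5` by default, giving 91 vertices around a
regular (degree-6) centre; the 12 icosahedral degree-5 vertices simply
yield slightly smaller rings, with no special-casing. Patches with fewer
than `min_valid_vertices = 10` usable vertices are treated as missing —
Pearson estimates on fewer points are too unstable to interpret.

## Two-compartment diffusion decomposition

The multi-shell signal (defaults b = 0, 400, 1000 s/mm² with 15/46/80
volumes) is reduced to per-shell spherical means and decomposed per voxel
into a "tissue" (anisotropic, slowly attenuating) and a "fluid"
(free-water) component by non-negative least squares against two
per-shell response functions, each normalised to unit b = 0 amplitude.
This is the l = 0 special case of multi-shell multi-tissue deconvolution:
it determines exactly the tissue/fluid *fractions* analysed downstream,
without the spherical-harmonic machinery needed for fibre orientations,
which this analysis does not use.

With two compartments the NNLS optimum is either the unconstrained 2×2
solution (when both weights are non-negative) or the better of the two
single-compartment boundary solutions; the fit is therefore computed in
closed form, vectorised over voxels, and is verified in the tests against
`scipy.optimize.nnls` voxel by voxel. Fractions are the weights divided
by their sum, so tissue + fluid = 1 at every valid voxel; all-zero voxels
are masked invalid rather than raising. Negative shell means (possible
after noise) are clipped to zero before fitting. If the two responses are
proportional the per-voxel weights are not identifiable and the fit
refuses with a dedicated error rather than returning arbitrary numbers.

Defaults for synthetic work: tissue response (1, 0.80, 0.55) —
moderately attenuated anisotropic tissue — and fluid response
`exp(-b * 3.0e-3 mm²/s)` ≈ (1, 0.301, 0.050), the free-water diffusivity
at body temperature. Response estimation from reference masks (mature
white matter for tissue, ventricles for fluid) is implemented and tested;
the synthetic pipeline uses the known generating responses directly.

Noise is Rician (magnitude MR): the magnitude of the complex signal after
independent Gaussian corruption of both channels, parameterised by SNR at
b = 0 (where the noiseless fraction-weighted signal is 1). At the default
SNR 20 the shell-mean averaging over 141 volumes keeps the mean absolute
tissue-fraction error below 0.05 (asserted over 1,000 voxels).

## Ribbon sampling

Vertex metrics are read from volumes by walking ±2 mm along the outward
unit vertex normal (angle-weighted average of incident face normals):
inward for the SP, outward for the CP. The 2 mm default matches the
diffusion resolution of the emulated acquisition. Five sample points
evenly spaced in (0, 2] mm (0.4 mm spacing, matched to a 0.8 mm
reconstruction grid) are trilinearly interpolated and averaged; the
point-sample-along-the-normal reading was chosen over a dilated voxel
ribbon, and the arithmetic mean over the segment is the aggregation.
Vertices whose segment leaves the field of view or touches invalid (NaN)
voxels are masked missing and stay missing through all downstream
statistics — never zero-filled. Voxel indices are 0-based; world
coordinates go through the NIfTI affine; interpolation happens in
continuous voxel space.

## Coupling statistics

Within each subject, the coupling at a centre vertex is the Pearson r
between the microstructural metric and sulcal depth over the valid
members of its k-ring patch, with the exact two-sided p from the
t distribution on n − 2 degrees of freedom. A vertex missing in either
input drops out of that patch only. Patches below the valid-vertex
minimum, or with zero variance in either variable (guarded with a
relative floor so rounding residue on constant inputs does not count as
variance), are missing.

Subjects enter half-open bi-weekly gestational-age bins [c − 1, c + 1)
centred on odd weeks 25–35; each subject lands in exactly one bin, and
out-of-range subjects are excluded with a warning. At each vertex a
one-sample two-sided t-test of the per-subject r values against zero is
computed on the **raw r scale** (a Fisher-z option exists but is off by
default, matching the reference procedure). Vertices with fewer than
`min_subjects_per_bin = 2` defined values are missing. Benjamini–Hochberg
step-up FDR at q = 0.05 runs across all non-missing vertices of one
hemisphere/metric/bin analysis; the selection is delegated to
`statsmodels` and verified in the tests against a direct implementation
of the step-up definition. Mean r is only displayed where the FDR mask is
true.

The **age-mismatched** ("back-projection") analysis replaces each young
subject's own depth with the group-mean sulcal depth of the oldest bin,
carried across subjects by template vertex correspondence; everything
downstream (binning, t-tests, FDR) is reused unchanged.

No spatially aware null models (spin tests, variogram-matched surrogates)
are implemented; the type-I guarantees below are for spatially
independent noise.

## Growth models

Sulcal-depth trajectories are fitted with a 4-parameter logistic
`y = L + (U − L) / (1 + exp(−k (ga − g₀)))` by bounded nonlinear least
squares. Initialisation is deterministic from data quantiles (L = min,
U = max, g₀ = GA at the half-range crossing, k = 4/GA span); bounds keep
the asymptotes within the data range ± 50 % and k ∈ (0, 5]. Constant
input is flagged degenerate instead of fitted; non-convergence raises
with solver diagnostics. The fit is bit-for-bit reproducible given the
data and equivariant to affine rescaling of y. Fraction trends use
ordinary least squares on the (1, ga, ga²) basis, refusing rank-deficient
designs (< 3 distinct ages).

## Synthetic cohort

Each phantom is a radially displaced icosphere (radius 30 mm): folds are
Gaussian angular bumps whose pit displacement grows logistically with GA
(the generative inverse of the sigmoidal depth-growth observation). The
default three modes have widths 0.22–0.28 rad, amplitudes 6.5–8 mm and
onsets at 28–31 weeks, so cohorts spanning 24–36 weeks range from
essentially spherical to clearly folded. Displacement is radial only, so
template correspondence is exact by construction and no surface
registration is needed.

Microstructure is planted as
`tissue = base(ga) + beta * future_depth + eps`, where `future_depth` is
the measured sulcal depth of the fully folded (36-week) surface and
`base(ga)` rises linearly from 0.35 to 0.55 in the CP, with the SP 0.05
lower until 30 weeks and on a doubled slope afterwards — a qualitative
emulation of the late subplate maturation spurt, not a fit to empirical
values. `beta < 0` plants the anticipatory tissue-fraction deficit in
fold-destined cortex.

Three observation routes trade realism against analytic control:

* **vertex** — metrics planted directly on the template. With
  homoscedastic noise the within-patch population correlation is exactly
  `rho = beta·sd(depth) / sqrt(beta²·var(depth) + sigma²)` per patch
  (`planted_rho`), and `calibrate_noise_sd` inverts the patch-*mean* of
  this map by bisection, so coupling-recovery tests compare the measured
  bin-mean r against an exact analytic target. A per-patch heteroscedastic
  inversion (`matched_noise_sd`) exists but is only exact where the depth
  spread varies slowly — the calibration assumes the noise level is
  locally constant across a patch, which a per-vertex profile violates in
  fold/flat transition zones; the scalar calibration is therefore the one
  used for quantitative targets.
* **volume** — fractions painted into an isotropic voxel grid (default
  1.5 mm) by nearest-vertex lookup around the subject's surface: voxels
  within ±2 mm of the boundary along the local normal form the SP/CP
  shells, deep interior voxels take the SP baseline, the exterior is
  fluid-dominated. Reading the volume back through ribbon sampling adds
  the interpolation smoothing a real pipeline would have.
* **dwi** — a further forward multi-shell signal with Rician noise, to be
  decomposed before sampling.

All randomness derives from one master seed through
`numpy.random.SeedSequence` streams keyed by (master seed, subject
index), so cohorts regenerate bit-identically and per-subject streams are
independent of cohort size.

### What the phantoms do not emulate

Realistic cortical geometry (secondary/tertiary folds, hemispheric
asymmetry, non-star-shaped surfaces), registration error, motion and
distortion artefacts, partial-volume mixtures at tissue boundaries,
spatially correlated physiological noise, and between-subject variation
in fold placement. Passing tests therefore establish the *statistical
machinery* — calibration, error control, spatial specificity at patch
resolution — under the stated noise model, not performance on real fetal
MRI.

## Study-scale choices in the tests

Quantitative checks run at desk scale, chosen once as part of the study
design: coupling recovery uses 40 phantoms on the level-4 template (2,562
vertices, ~91-vertex patches) against the calibrated target
rho = −0.7 ± 0.05; type-I error uses 20 replicate 8-subject null cohorts
(beta = 0) on the level-3 template, asserting the mean FDR-selected
fraction ≤ q + 3 Monte-Carlo standard errors; the age-mismatched
experiment uses 10 unfolded 26-week subjects through the full volume
route against the mean depth of six 34–36-week subjects. In that
experiment a selected centre counts as a true positive when its k-ring
reaches cortex with planted |rho| ≥ 0.5: the coupling statistic is a
patch property, so spatial specificity is assessed at patch resolution;
measured precision must exceed 0.8. Growth recovery demands the logistic
parameters to 1e-3 noiseless and the inflection age within ±0.5 weeks at
noise sd 0.5 with 100 subjects over 50 replicates.

## Known limitations

* Hull-based sulcal depth underestimates wide shallow folds and reports
  zero across the hull "lid", producing exact-zero plateaus that the
  zero-variance patch guard must handle (it does, by design).
* The nearest-vertex volume painting quantises the planted depth field at
  vertex resolution; with voxels finer than the vertex spacing this is
  invisible to ribbon sampling, but very coarse meshes would alias.
* Binning is fixed to the configured centres; subjects outside them are
  excluded rather than assigned to an open-ended bin.
* The t-test on raw r is exact only under the null; for strong planted
  effects its confidence statements are conservative relative to a
  Fisher-z analysis (available via configuration).
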