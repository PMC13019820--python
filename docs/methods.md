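# Methods

This note documents the models and procedures implemented in
`psychocortex`, their assumptions, the parameters that matter, and the
design decisions taken where more than one reasonable choice existed.

## Synthetic cohort

The generator emulates a forensic morphometry study at the level of
statistical structure, not biology. One global seed is expanded into fixed
per-stage child seeds, so every artifact is bit-reproducible.

**Atlas.** Parcels are placed by a golden-angle spiral on two unit spheres
— one per hemisphere, mirror-images in *x* — mimicking surface-based
spherical registration (each hemisphere owns a full registration sphere;
this matters for the spin test below). The anterior-posterior position
`ap_axis` is the *y* coordinate rescaled to [−1, 1]. Mesulam classes
(paralimbic 12%, heteromodal 40%, unimodal 36%, idiotypic 12%) and Yeo-7
networks are assigned in contiguous ap bands, so the partitions are
spatially coherent and all categories are represented.

**Covariance model.** The parcel correlation matrix is a squared-
exponential kernel in ap distance, K_ij = exp(−2 (g·d_ij)²), with
`gradient_strength` g (default 1). This is positive semi-definite by
construction and puts the leading non-trivial eigenvector along the ap
axis, which is what the gradient analysis must recover. Group-specific
*compression* blends the off-diagonal structure toward its constant mean,
K_c = (1−c)·K + c·K̄ with the unit diagonal fixed — one parameter (c,
default 0; the high-psychopathy group uses the configured value) that
directly produces "pulled toward the center" loadings.

**Morphometry.** Subject rows are multivariate normal draws from the
group's covariance plus linear covariate effects on the standardized scale
(defaults: CT age −0.25, IQ 0.05; SA age −0.10, IQ 0.10, TIV 0.55 SD per
covariate SD), a per-parcel standardized group shift for the high group
(default +0.4 SD in paralimbic ∪ somatomotor parcels, SA only), and iid
measurement noise (`noise_sd` 0.3 relative to unit latent SD — small
relative to between-subject variance, as for surface-based morphometry).
Units: CT = 2.5 + 0.15·signal mm; SA uses a smoothly varying per-parcel
baseline (≈ 700 mm², one order of magnitude across parcels) with a 12%
coefficient of variation. Values are floored at a tiny positive number;
with these scales the floor is never active in practice.

**Behavior.** Latent factors (F1, F2) are bivariate normal with Pearson
r = 2·sin(π·0.5/6) ≈ 0.52, targeting Spearman ρ ≈ 0.5. Items are
thresholded latents (loading √0.5): 20 PCL-R items scored 0–2 (8 on F1, 10
on F2, 2 on neither), 7+7 IRI items scored 0–4. `behavior_effects` set the
signed latent regressions F1 → IRI-EC and F2 → IRI-PT (defaults −0.4).
Designated group membership is realized by rejection sampling: latents are
shifted per group (−0.9 low, +0.55 moderate, +1.9 high) and subjects are
redrawn until the prorated PCL-R total lands in the group's band (≤ 20,
21–29, ≥ 30).

**What the generator does not emulate:** spatial autocorrelation beyond
the single ap kernel, site/scanner effects, non-Gaussian morphometry,
missing covariates, or any vertex-level structure. Passing tests therefore
demonstrate that the *pipeline* behaves correctly under its assumed data
model, not that the effects exist in real cohorts.

## Psychometrics

Prorating multiplies a scale's observed sum by (scale items / scored
items) — equivalent to mean-imputing omitted items — and is the identity
on complete data. Omission caps default to 5 (total) and 2 (per factor)
following common practice with this instrument; they are configurable
because no single convention is universal. The IRI is never prorated; a
missing item is an error. Group cutoffs are closed: 20 is low, 30 is high.
Spearman matrices use average ranks and the t approximation, pairwise
complete cases, and a Bonferroni flag p·m < .05 with m defaulting to the
number of off-diagonal pairs (28 for the 8 standard variables).

## Robust brain-behavior maps

`robust_fit` is IRLS with Tukey's bisquare (c = 4.685, ≈ 95% Gaussian
efficiency), MAD/0.6745 scale recomputed per iteration, maximum 50
iterations, tolerance 1e−8 on coefficients; statsmodels' RLM provides the
solver. p-values are asymptotic normal on the robust covariance.
Standardized betas come from a refit on z-scored response and predictors
(not post-hoc rescaling), so β_Z is well-defined with covariates present.
A constant response returns zero slopes with p = 1 rather than an error.
Non-convergence is flagged, never raised. The adjusted R² reported for
global fits uses the robust fitted values; it is a pseudo-R², adequate for
description.

FDR is Benjamini–Hochberg applied across the 360 parcels of each map
separately (per index × predictor), matching per-map reporting. Partition
contrasts treat parcels as exchangeable units in rank-sum tests with
Bonferroni factors 6 (4 classes) and 21 (7 networks); spatial
autocorrelation is not modeled here, a deliberate replication of the
field's practice — the spin test exists for the map-level questions where
it matters.

## Out-of-sample prediction

Order of operations: split once (test size = round(n·fraction); simple
random, no stratification) → residualize every parcel column on intercept
+ covariates *within each set independently* → standardize columns by the
training-set SD → select λ from a log-spaced grid (1e−3…1e5, 25 points)
by 10-fold CV MSE on training only → refit on all of training → score the
test set. Nothing from the test rows ever reaches selection (a test
corrupts test rows after fitting and verifies identical coefficients).

The ridge solve uses an SVD of the fixed design shared across the grid and
across permutations; it equals the closed form (XᵀX + λI)⁻¹Xᵀy to
floating-point accuracy. The target is centered on the (fold-)training
mean; the intercept is that mean. Out-of-sample R² uses the test-set mean
in SS_tot (the training-mean convention is available via
`ss_tot_center="train"`); the normalized MSE divides by the instrument's
maximum score (16 for PCL-R F1, 20 for F2, 28 for IRI subscales).

The permutation null permutes the *training* target and re-runs the whole
selection-plus-refit pipeline, preserving selection optimism under the
null; p = (1 + #{null MSE ≤ observed}) / (1 + N_perm). Under an
independent target this p is uniform (verified by KS over 100 outer
seeds at N_perm = 200).

A planted-signal note: a recoverable multivariate signal at n ≈ 800 and
p = 360 must live in the data's dominant covariance directions. The
recovery suite plants a smooth ap-patterned weight vector on standardized
SA explaining 10% of target variance; an isotropic dense weight vector of
the same strength is essentially unlearnable by ridge at this n/p, which
is a property of the estimator, not a bug.

## Structural-covariance gradients

Pipeline: residualize the index on its covariates (group-specific
residualization for group matrices, matching sample-specific covariance
construction) → Pearson correlation across subjects (≥ 30 required;
zero-variance parcels keep a unit diagonal and zero off-diagonals) →
row-sparsify at 90% (top 36 of 360 entries per row, negatives dropped) →
normalized-angle similarity 1 − arccos(cos)/π → diffusion embedding with
density normalization α = 0.5, diffusion time 0, dense symmetric
eigendecomposition (trivial at p = 360). Loadings are eigenvectors scaled
by their eigenvalues; variance explained is the normalized eigenvalue
magnitudes over the 10 retained components. Sign is fixed
deterministically (positive correlation with the ap axis for the template,
with the template's first gradient for group embeddings, falling back to a
largest-|loading|-positive rule).

**Alignment.** Group gradients are aligned to the total-sample template by
orthogonal Procrustes (column centering, SVD of the cross-product, no
scaling; the template's column means are restored, so self-alignment is
the identity). The subspace entering alignment is capped at `n_align`
(default 1 — the primary gradient under comparison, reducing the transform
to sign/offset matching). Rationale: the affinity spectra here are nearly
degenerate beyond the leading component, and an orthogonal fit over many
near-degenerate components can rotate other components into the primary
axis, absorbing exactly the group difference (compression) one is testing
for; this leakage was directly observed in simulation. `n_align` is
configurable for users who prefer full-subspace alignment.

**Compression.** Globally: two-sample KS on the aligned primary-gradient
loadings (360 per group, asymptotic p) plus the loading range ratio
high/low. Locally: per class/network, a paired signed-rank test on
(high − low) loadings, Bonferroni factors 4 and 7, and a
compression-oriented flag — the high-group label median lies strictly
closer to its group's center (median of label medians) than the low-group
median does to its own; labels with < 5 parcels are excluded as unstable.

## Spin permutation

A uniform SO(3) rotation is applied to the left hemisphere's registration
sphere and its x-mirrored counterpart to the right, preserving left/right
correspondence; each parcel then takes the value of the nearest rotated
centroid within its hemisphere (with replacement — the simplest standard
variant; the identity rotation reproduces the map exactly). p_spin is
two-sided: (1 + #{|null r| ≥ |observed r|}) / (1 + N_perm).

Calibration subtlety: with mirrored rotations, a map with no bilateral
organisation yields hemisphere contributions that are coherent in the
observed correlation but decorrelated in the null, making p_spin
anti-conservative; a map made symmetric by folding coordinates (|x|)
breaks rotational isotropy instead. The calibration suite therefore uses
isotropic smooth fields evaluated in each hemisphere's own registration
frame (exact mirror yoking — the idealization of the strong bilateral
symmetry of real cortical maps), under which the null is exchangeable and
p_spin is uniform. `smooth_random_map` implements this construction.

## Pipeline

`run_pipeline` executes simulate → Q1 (psychometrics) → Q2 (maps) → Q3
(prediction) → Q4 (group maps + mask overlap) → Q5 (gradients +
compression + spin consistency against a second, reference synthetic
cohort on the same atlas), writing every stage artifact and a
`report.json` that embeds the fully resolved configuration. Timings go to
the log only, so reruns are byte-identical. The Q4 overlap masks are
synthetic stand-ins built from the atlas partitions ("affective" =
paralimbic ∪ somatomotor ∪ limbic; "cognitive" = default-mode ∪
frontoparietal; baseline/preferential/unique variants by set arithmetic);
real meta-analytic masks can be supplied through the same interface.

## Problem sizes and tolerances

Default suites run at the sizes the analyses are specified for: 360
parcels; n = 400 (gradient recovery), 300/group (compression), 800
(prediction recovery), 289/337/178 (cohort emulation). Monte-Carlo suites
use 20 seeds for recovery rates and 100 outer seeds for null-calibration
KS checks at 200 permutations. Numerical tolerances: PSD jitter 1e−10;
IRLS tolerance 1e−8; Procrustes/linear-algebra assertions at 1e−10;
KS/signed-rank tests use asymptotic p-values throughout.

## Known limitations

- The generator's single-kernel covariance understates the spatial
  complexity of real structural covariance; compression detection rates
  measured here need not transfer to real cohorts.
- Partition-level rank-sum and signed-rank tests ignore spatial
  autocorrelation among parcels (by design, replicating common practice).
- The robust-fit p-values are asymptotic; at parcel-level n in the
  hundreds this is adequate but not exact.
- Spin reassignment with replacement slightly perturbs the value multiset
  of spun maps; the one-to-one assignment variant is not implemented.
- No vertex-level analysis, surface meshes, or real atlas geometry.
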