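# Methods

This note documents the statistical model and the numerical choices behind
`craniomap`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, which
knobs matter, and what the synthetic test bench does and does not show.

## Superimposition

**Centroid size.** CS(X) = √Σᵢ‖xᵢ − x̄‖², the standard geometric-
morphometric size measure (mm).

**OPA.** Ordinary Procrustes alignment of a configuration A onto a fixed
reference B: translation to B's centroid frame, optional scaling, and the
rotation minimizing ‖A′ − B‖². The rotation comes from the SVD of the
cross-covariance A′ᵀB with the standard sign correction on the smallest
singular value, so the fit is always a *proper* rotation (det = +1): a
mirrored configuration keeps a positive residual instead of being silently
reflected. Degenerate (rank < 2) configurations are rejected.

**GPA.** All specimens are centered, optionally scaled to unit centroid
size, and iteratively rotated to the running consensus; the consensus is
re-averaged (and, when scaling, re-normalized to unit size) each sweep.
Convergence is the RMS change of the consensus, tolerance 1e-10, max 100
iterations (a warning carries the final change if the cap is hit; in
practice convergence takes 3–6 sweeps). Original centroid sizes are stored
regardless of scaling. Tangent-space projection is **not** applied before
PCA — coordinates are used as aligned; at the small shape variances of the
intended data the difference is negligible, and keeping coordinates raw
makes the per-neighborhood pipeline self-contained.

**Symmetrization.** The reflected, pair-relabeled copy of each specimen is
OPA-aligned (no scaling) to the original and the two are averaged. No
explicit symmetry plane needs to be estimated: reflecting about *any*
plane and letting the OPA rotation absorb the choice gives the same
optimum, because the cross-covariance of the mirrored copy with the
original is F·S with S symmetric (F = diag(−1,1,1)), which forces the
optimal rotation R to satisfy FRᵀF = R; that identity makes the average
exactly invariant under reflect-and-relabel (machine precision; tested at
1e-8 mm). The operation is idempotent.

**TPS and area-change maps.** 3D thin-plate-spline warping uses the
biharmonic kernel U(r) = r plus an affine term (scipy's RBF machinery;
exact interpolation on the source points). Surface "expansion/contraction"
maps divide per-vertex areas (one third of the incident triangle areas) of
a target shape by those of a reference; 1 = unchanged, > 1 expanded.

## Feature spaces and classification

Shape space: flattened GPA coordinates (unit size). Form space: shape
coordinates plus one column of ln CS, so size differences re-enter an
otherwise size-free analysis on a scale commensurate with shape variance.
Size-only: ln CS alone.

PCA is a centered SVD with a deterministic sign convention (largest-
magnitude loading of each axis positive); eigenvalues are score variances
(ddof = 1). Downstream analyses retain the leading components up to a
cumulative-variance threshold, default **0.90**.

The classifier is the two-class linear discriminant with pooled
within-class covariance. Priors default to training class frequencies (an
`priors="equal"` switch exists; with the balanced designs used throughout,
the two coincide). If the pooled covariance of the retained PC scores is
singular, a ridge of 1e-8 × trace/k is added to the diagonal. Accuracy is
estimated by repeated stratified splits: per class, a random
`train_fraction` (default 0.7) of specimens trains; PCA and the
discriminant are fitted on training data only, and test specimens are
projected through the *training* mean and axes — never refit — so no
information leaks from the test set. Totals and per-class (F/M) accuracies
are averaged over `n_perm` splits.

Note on null behavior: cross-validated accuracy under a true null is not
exactly 0.5 for a *given* finite sample. Split-to-split Monte Carlo error
shrinks as 1/√n_perm, but the realized separability of one noise sample
does not average away; at n = 120 specimens with ~15 retained PCs the
per-point null accuracy has a standard deviation of roughly 0.03–0.04.
Interpreting maps therefore requires comparing against this null spread,
not against 0.5 exactly (the acceptance script reports the null map's
worst-case deviation for its own conditions).

## The accuracy map

Neighborhoods are built **once** from the full-sample GPA consensus: each
point's neighborhood is itself plus its k − 1 nearest neighbors (Euclidean
distance on the consensus, ties broken toward lower index; default k = 10,
counting the focal point — a `k_excludes_focal` switch implements the
k + 1 reading). Fixing neighborhoods keeps every permutation's spatial
support identical. Per neighborhood and permutation the full pipeline runs
independently — stratified split, training-only GPA of the neighborhood's
points, OPA projection of test specimens (with scaling in shape/form
space; the size feature uses the raw neighborhood ln CS), PCA truncation,
LDA — which is what makes neighborhoods statistically independent units.
At full scale this is n_points × n_perm discriminant analyses per map
(e.g. 1050 × 100 = 105 000).

Reproducibility and order independence: the split at (point, permutation)
is derived by hashing (seed, point index, permutation index, specimen id)
through a splitmix64 mixer, and the training subset is processed in a
canonical order. Maps are therefore bit-identical across runs, independent
of specimen storage order, and trivially parallelizable. Permutations
whose training neighborhood is geometrically degenerate are skipped; a
point with more than half of its permutations skipped is reported missing
(NaN) rather than silently averaged.

Module-level accuracy (`combined_module_accuracy`) applies the same
pipeline once to the union of named point sets, with a module-level
default of 1000 permutations. `extract_top_modules` thresholds a map (by
cutoff or quantile) and splits the selection into connected components of
the neighborhood graph, ordered by peak accuracy — a reproducible stand-in
for selecting named anatomical regions by inspection. Map agreement is
quantified by the Pearson correlation of per-point accuracies, optionally
recomputed above a quantile of the first map (linear-interpolation
quantile, threshold taken from map A).

## Morphometric statistics

**Procrustes linear model.** Sequential (order-of-entry) multivariate
regression of the flattened shape variables on model terms (default order
size, sex, size × sex; two-level factors coded ±1). Each term's variance
fraction is its sequential sum of squares over the total (summed across
variables). p-values use residual randomization of the reduced model
(RRPP): the residuals of the model *before* the term are permuted, the
term's F-ratio recomputed, and p = (exceedances + 1)/(n_perm + 1) — the
+1 estimator avoids p = 0. Fractions over all terms plus residual sum to 1.

**Repeatability.** One-way Procrustes ANOVA on jointly superimposed
replicated digitizations (balanced designs only, r ≥ 2 replicates each):
R = (MS_among − MS_within)/(MS_among + (r − 1)·MS_within), mean squares
summed over coordinates, reported ×100 and clamped to [0, 100].

**Allometry.** Per group, each shape variable is regressed (OLS) on
centroid size — untransformed by default, natural log via a switch; both
conventions are common and the choice is recorded in the result. The
stacked slope vector is the group's allometric trajectory; R² pools
regression over total sums of squares across variables; predicted shapes
are evaluated at the group's observed size extremes. The divergence
between two trajectories is the angle between unit-normalized coefficient
vectors, in degrees; its significance comes from shuffling group labels
(sizes preserved) and recomputing, p = (count ≥ observed + 1)/(n_perm+1).
Caveat: estimated angles are biased upward when trajectories are weakly
determined (low R²), because independent estimation noise in the two
coefficient vectors pushes their angle toward 90°; the permutation test,
not the raw angle, is the calibrated quantity.

## Synthetic data generator

The generator emulates the statistical structure of a two-group cranial
landmark study. Base shape: a quasi-uniform spiral lattice on the x > 0
half of an ellipsoid (default semi-axes 60 × 75 × 55 mm, skull-like
proportions), mirrored across x = 0 and closed with an evenly spaced
midline ring, so bilateral pairing and reflect-relabel symmetry hold
*exactly*; faces come from the convex hull; the centroid is placed at the
origin by alternating recentering with radial reprojection (preserving the
mirror pairing).

Per specimen: group-M points in a chosen index set are displaced by
`effect_size` × (mean nearest-neighbor spacing) along outward vertex
normals (or a fixed vector); ln CS is drawn normally per group (log-normal
sizes; defaults 760 vs 800 mm with 30 mm sd ≈ 5% dimorphism, the realistic
cranial regime); an allometric displacement `strength × (ln CS − mean) ×
group vector` is added; the shape is scaled to its drawn size, rigidly
moved at random, and isotropic digitization noise (default 0.3 mm) is
added last so measurement error is frame-independent. Optionally each
individual carries its own anatomical deviation (`individual_sd`, default
0 mm, shared by its replicates) — without it, same-group individuals
differ only by noise, which is the cleanest regime for calibration tests
but makes repeatability designs degenerate; repeatability simulations use
individual_sd = 2 mm against 0.3 mm digitization noise (variance ratio
≈ 44:1, i.e. the ~98% repeatability regime typical of careful cranial
digitization).

Planted allometry vectors are projected orthogonal to the 7-dimensional
similarity tangent space (translations, rotations, scaling) of the base
shape before use; GPA quotients out exactly those directions, so planted
trajectory directions and mutual angles survive superimposition —
otherwise a planted 40° angle would be distorted by the fit.

What passing tests on this generator do **not** show about real data: the
base shape is convex and smooth (no foramina, ridges or concavities), the
noise is isotropic and homoscedastic, semilandmarks are fixed rather than
slid, populations are homogeneous, and within-group shape variation is
isotropic. Results on real crania additionally depend on digitization
protocol and sample composition.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| k | 10 | neighborhood size (counts the focal point) |
| n_perm (map) | 100 | splits per neighborhood |
| n_perm (module) | 1000 | splits for module-level accuracies |
| train_fraction | 0.7 | stratified per class |
| variance_threshold | 0.90 | PCs retained for LDA |
| GPA tol / max_iter | 1e-10 / 100 | consensus RMS change |
| noise_sd | 0.3 mm | digitization error |
| size_means | 760 / 800 mm | F/M centroid size (~5% dimorphism) |
| n_per_group | 60 / 60 | specimens per sex |
| n_points | 150 | generator configuration size |

The test bench and the acceptance script use 150-point configurations with
60 specimens per sex — large enough that neighborhoods, PCA truncation and
stratified splits behave as at full scale, small enough that a complete
map (15 000 discriminant fits) takes ~30 s on one CPU.

## Known limitations

* Balanced replicate designs only for repeatability (as in an 8 × 4
  digitization study); unbalanced designs are rejected, not approximated.
* Two-level signals only; no multiclass or continuous-trait mapping, no
  spatial smoothing, and no multiple-testing control across points (maps
  report raw mean accuracies).
* Sliding of semilandmarks is out of scope: the package consumes fixed or
  already-slid points.
* The fcsv reader handles the Slicer markups fiducial dialect (RAS/LPS);
  markups JSON is not parsed.
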