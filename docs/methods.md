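# Methods

`ifcpipe` quantifies how *consistently* a patient group's intrinsic
functional connectivity (iFC) between subcortical-cerebellar systems and
cortical networks is altered, by asking how reliably a linear classifier
separates patients from controls on different families of connectivity
features. This note documents the model behind every stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical conventions.

## The analysis in one paragraph

Per subject, slow (< 0.1 Hz) BOLD fluctuations are summarized in two kinds
of time courses: representative courses of 16 spherical seeds (6 mm
radius) in four "subcortical-cerebellar" systems — striatum, medial
temporal lobe (MTL), amygdala, cerebellum — and activity courses of
cortical intrinsic networks obtained by group spatial ICA. Pearson
correlations between these courses, Fisher r-to-z transformed, form four
feature families: every seed × every network (`allROIs-NWs`), the strict
upper triangles of network × network (`NWs-NWs`) and seed × seed
(`allROIs-allROIs`), and one family per system (`<system>-NWs`). Each
family is classified patient-vs-control by a linear SVM under
leave-one-out cross-validation (LOOCV); accuracy is read as the
consistency of that family's group difference across subjects, and
families are compared pairwise with an exact paired binomial (sign) test
on the per-subject correct/incorrect outcomes.

## Quality control and preprocessing

- The first 3 volumes are discarded (magnetization equilibration); motion
  traces are trimmed to match.
- Motion metrics: point-to-point displacement is the Euclidean norm of the
  volume-to-volume difference of the three translation (rotation)
  parameters; *cumulative translation* is read as the maximum Euclidean
  displacement from the first retained volume (an alternative, the sum of
  point-to-point steps, is available via `cumulative_mode="sum-p2p"`).
  Exclusion thresholds: cumulative > 3 mm, mean point-to-point translation
  > 0.15 mm, mean point-to-point rotation > 0.1°. Motion files store
  rotations in radians (SPM rp-file dialect) and are converted to degrees
  on read, so thresholding happens in degrees.
- tSNR is the voxelwise temporal mean over temporal SD, averaged over a
  mask; zero-SD voxels are excluded and counted.
- Band-pass: Butterworth 0.009–0.08 Hz. The order is not uniquely implied
  by the analysis description, so order 4 applied forward–backward
  (zero-phase, `sosfiltfilt`) is the default; both are configurable. The
  effective gain is the squared single-pass magnitude response.
- Seed courses: voxel courses inside a seed are reduced to the first
  right-singular vector of the centred voxel × time block, unit variance,
  sign fixed by non-negative correlation with the seed-mean course.
- Nuisance regression removes, by OLS with intercept, the global
  gray-matter, white-matter and CSF mean signals plus the six motion
  parameters. Processing order is band-pass first, then regression with
  the regressors themselves band-passed to the same band — regressing
  raw nuisance signals out of filtered data would reintroduce out-of-band
  variance. The order can be switched (`bandpass_before_regression`).
- Whether network (ICA) time courses receive the same cleanup is left as
  a flag (`clean_network_tcs`), default off: only the seed courses are
  cleaned.

## Group ICA

Temporal concatenation with two-step PCA: each subject is reduced along
time to `n_subject_pcs` dimensions (default 1.5 × the group dimension,
capped by rank), subjects are stacked, and a second PCA cuts to
`n_group_components`. A single subject's two-step reduction equals its
direct PCA exactly (no re-centring between stages). Infomax ICA
(natural-gradient, logistic nonlinearity, minibatch updates with
learning-rate annealing on blow-up or oscillation) unmixes spatial
sources; the logistic nonlinearity suits the sparse, super-Gaussian
spatial maps of interest. Stability is assessed ICASSO-style: the
decomposition is repeated `n_icasso_runs` times from different seeds
(optionally with bootstrap resampling of voxels), all components are
clustered by average linkage on 1 − |spatial correlation| into
`n_group_components` clusters, and each cluster's centrotype is kept. The
stability index is within-cluster mean |r| minus between-cluster mean
|r|; with one run it is undefined (NaN with a warning).

Components of interest are selected at the group level by spatial
multiple regression of each template map on all component maps
simultaneously; the standardized coefficient is the goodness, assignment
is greedy in descending |coefficient| without replacement (a contested
component goes to the template scoring it higher), and plain spatial
correlation is available as a fallback. Subject-specific maps and time
courses of the selected components come from dual regression
(data → time courses on group maps, then data → maps on those time
courses); this variant was chosen among back-reconstruction options for
its transparency and testability. All downstream correlations are
invariant to component sign flips.

Desk-scale defaults (8 components, 10 ICASSO runs) keep simulation
studies fast; a full-scale configuration (75 components, 40 runs, 22
cortical templates) is a plain config choice.

## Connectivity features

Pearson correlations are Fisher-transformed, z = arctanh(r), with |r|
clipped at 1 − 1e-7 (every clip logged) so features stay finite. Feature
order is fixed lexicographic by (row entity, column entity) and identical
across subjects. No across-subject standardization happens at this stage;
any scaling lives inside the classifier's training fold to prevent
leakage across LOOCV folds.

## Classification

The linear soft-margin SVM is solved natively by sequential minimal
optimization (Platt-style working-set selection, KKT tolerance 1e-3
default, deterministic given a seed). The threshold is canonicalized
after solving: mean over free support vectors, else the midpoint of the
KKT-feasible interval. Hyperparameters are not dictated by the analysis
being reproduced (a stock SMO configuration is implied), so C = 1 with
within-fold z-standardization (train-fold statistics applied to the
held-out subject) is the default; both are configurable. Patient is the
positive class: sensitivity is the patient detection rate. LOOCV holds
each subject out once; a decision value of exactly zero goes to the
control class, deterministically.

## Family comparison

For two families' outcome vectors, W counts subjects correct under the
first and wrong under the second, N the discordant subjects; under the
null W ~ Binomial(N, 1/2) and the one-sided p-value P(Bin ≥ W) is
computed exactly from binomial coefficients (integer numerator over a
power of two — exact in floating point). N = 0 returns p = 1 by
convention. Two-sided (twice the smaller tail, capped at 1) is available;
no multiple-testing correction is applied by default, and a Holm
step-down adjustment can be requested on the pairwise table
(`compare_all_families(..., correction="holm")`). Pairwise tables orient each
pair so W counts wins of the numerically better family; note that this
data-dependent orientation makes the *reported* one-sided p-values
anti-conservative as a simultaneous test (each tail gets the nominal
level) — the exact test itself, with a fixed orientation, is conservative,
and the type-I calibration test covers exactly that property.

## Synthetic cohorts

No empirical data accompany the analysis, so a seeded generator produces
cohorts with known ground truth. Defaults are the study conditions: 18
controls + 18 patients, 300 volumes at TR 2 s, a desk-scale MNI-like grid
of 20 × 27 × 16 voxels at 4 mm (~10⁴ voxels, chosen to contain all seed
centres), 8 latent networks standing in for 22.

Per subject: latent network courses are unit-variance band-limited
(0.009–0.08 Hz) Gaussian signals; seed j's course is
`Σ_k b_jk · network_k + √(1 − ‖b_j‖²) · innovation_j`, so the coupling
matrix *is* the population seed-network correlation and validity reduces
to row norms ≤ 1 (violations beyond a 1e-6 margin are errors naming the
seed; within the margin the row is projected onto the unit sphere with a
warning). Voxel data are baseline intensity (100) + network maps × courses
(compact Gaussian blobs with well-separated random centres, amplitude 3)
+ seed courses on the seed spheres (amplitude 2) + global/WM/CSF nuisance
fields (amplitude 0.5 each, on a GM mask and on deep boxes the cortical
blobs cannot reach) + i.i.d. unit Gaussian noise, giving a realistic tSNR
near 30. Motion traces are zero-origin random walks (0.02 mm / 2e-4 rad
steps), independent of the BOLD content, sized to pass QC; they exist to
exercise the QC stage.

The group effect is planted exactly where the analysis looks: each
system's seeds couple to "home" networks at 0.35 in controls; in patients
that coupling is shifted down by a per-system effect size —
cerebellum 0.50, MTL 0.45, striatum 0.10, amygdala 0.10 — the
differential-consistency scenario (strong cerebello-/MTL-cortical
changes, weak striatal/amygdalar changes). Between-subject coupling
jitter is N(0, 0.08). Under these conditions the strong systems classify
near-perfectly and the weak systems far from perfectly, reproducing the
qualitative ordering; `NWs-NWs` carries group signal only through
estimation leakage and `allROIs-allROIs` through shared-network coupling,
so their absolute accuracies are emergent, not planted.

What the generator does **not** emulate: hemodynamics and neural mass
dynamics, scanner artifacts, spatial autocorrelation of noise, smoothing,
subject-specific anatomy, or motion-BOLD coupling. Passing tests
demonstrate that the pipeline recovers planted covariance structure and
orders feature families correctly under those idealized conditions — not
that it would do so on scanner data with registration error and
structured noise.

## Numerical conventions and degenerate inputs

- Determinism: one global seed fans out via `SeedSequence` to simulation,
  ICA and SVM stage seeds; identical configs give bit-identical reports.
- Zero-variance entities (flat time courses) are errors naming the
  entity; all-constant volumes make tSNR undefined (error).
- Rank-deficient nuisance designs are rejected naming the collinear
  columns; rank-deficient group-map matrices abort dual regression.
- SVD and ICA sign indeterminacies are resolved by explicit conventions
  (seed-mean correlation; template-goodness sign), and results are
  invariant to them.
- Stage products are cached on disk keyed by a content hash of the full
  configuration; a rerun with unchanged config reuses the cached seed and
  network time courses and reproduces the report exactly.

## Problem sizes used in the shipped studies

The simulation studies shipped with the package (test suite and
acceptance script) run the default desk-scale conditions: 36 subjects,
297 retained volumes, ~10⁴ voxels, 8 networks, 10 ICASSO runs; the
ordering study uses 50 independent seeds, the null-calibration studies
100 LOOCV replicates and 2000 sign-test replicates. These sizes were
chosen so a complete run remains a desk-side computation on one core.

## Known limitations

- The exact binomial comparison needs per-subject outcomes; published
  p-values of an empirical study cannot be reconstructed without them.
- Greedy template assignment is order-dependent in pathological ties;
  ties are broken deterministically (higher goodness, then template and
  component index).
- The infomax implementation targets super-Gaussian (sparse) spatial
  sources; sub-Gaussian sources would need an extended-infomax switch
  that is deliberately out of scope.
- At desk scale the ICA model order equals the number of planted
  networks; model-order estimation is not addressed.
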