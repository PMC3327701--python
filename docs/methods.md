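# Methods

This note describes, in the package's own terms, exactly what each stage of
`tlemorph` computes and which choices are modelling decisions rather than
mathematical necessities.

## Anatomy and volumetry

Subjects are described by an 83-region whole-brain parcellation: 40 bilateral
structure stems (left/right pairs) plus 3 midline structures. The catalog is
shipped as `tlemorph/resources/structures.json` and exposed through
`StructureCatalog`.

Regional volumes are computed from an integer label image and a grey-matter
(GM) probability map on the same voxel grid:

- For most structures, a voxel contributes its full voxel volume if and only
  if its GM probability is **strictly greater than 0.5**. A voxel at exactly
  0.5 does not count.
- 18 structures are **GM-exempt** and counted over all their labelled voxels
  regardless of GM probability: the lateral ventricles (frontal, temporal,
  occipital and parietal horns, left and right), the third ventricle, corpus
  callosum, brainstem, and the deep grey nuclei (thalamus, caudate, putamen,
  pallidum, substantia nigra — left and right where applicable). These are
  structures that are either CSF-filled, white matter, or whose voxels sit
  near the GM-probability decision boundary, where thresholding would be
  noise rather than signal.

Normalization for head size divides every regional volume (mm³) by the
subject's intracranial volume (ICV, converted from cm³ to mm³), yielding
dimensionless ratios. This is a simple ratio correction, not a regression
(covariate) correction; it assumes regional volume scales proportionally
with ICV, which is exactly the assumption the synthetic generator encodes.

## Synthetic cohort generator

No subject data ships with the package. `generate_cohort` draws cohorts from
an explicit generative model:

1. Per subject, ICV (cm³) is drawn from a normal distribution truncated at
   zero, with group-specific mean and SD. Defaults: controls 1483 ± 160
   (n = 28), TLE-HA 1387 ± 128 (33 left-focus + 27 right-focus), TLE-N
   1423 ± 150 (11 left-focus + 9 right-focus). TLE-HA denotes patients with
   hippocampal atrophy on MRI; TLE-N denotes MRI-negative patients.
2. Each structure has a fixed base fraction `f_s` of ICV. The noiseless
   volume is `f_s · ICV_mm³ · (1 − effect_s)`, where `effect_s` is a
   group-specific fractional atrophy (0 for controls). The default effect
   tables plant the strongest atrophy in the ipsilateral hippocampus, with
   graded smaller effects in ipsilateral medial/anterior temporal and
   orbitofrontal regions, milder and more diffuse effects for TLE-N, and
   some contralateral involvement.
3. Right-focus effect tables are the exact left–right mirror of the
   left-focus tables (`StructureCatalog.mirror_effects`); midline structures
   map to themselves.
4. Multiplicative lognormal measurement noise: volume × exp(ε) with
   ε ~ N(0, σ²), σ² = log(1 + cv²), default cv = 0.08. This keeps volumes
   positive and makes the coefficient of variation of the noise factor
   exactly `cv`.

Because volume is proportional to ICV before noise, volumes and ICV are
positively correlated within group, and ratio normalization removes the
head-size component exactly in the noiseless limit.

The generator is **not** an image simulator: there is no registration error,
partial-volume modelling, scanner bias, or age/sex structure. Effect
magnitudes are modelling choices selected to give a realistic ordering of
difficulty (TLE-HA easy, TLE-N hard), not measurements.

Label-image pairs for the fusion/overlap utilities are produced by
`generate_label_pair`, which degrades a reference parcellation by reassigning
a seeded fraction of each region's voxels (`flip_fraction`), so Dice overlap
degrades smoothly from 1 (fraction 0) to 0 (fraction 1).

## Label fusion and overlap

`vote_fuse` performs per-voxel plurality voting over candidate label images
on a common grid; ties are broken deterministically toward the lowest label
code. `dice` and `jaccard` are the standard overlap coefficients computed on
binarized region masks; two empty masks are defined to overlap perfectly
(coefficient 1). `overlap_comparison` summarizes per-region Dice between
paired segmentations.

## Structure selection: kernel separability criterion

For a single structure with normalized volumes split into classes
`x` (n₁ subjects) and `y` (n₂ subjects), define kernel mean terms

    A = (1/n₁²) Σᵢⱼ k(xᵢ, xⱼ)
    B = (1/n₂²) Σᵢⱼ k(yᵢ, yⱼ)
    C = (1/(n₁n₂)) Σᵢⱼ k(xᵢ, yⱼ)

and the within-class scatter `s² = var(x)·n₁/n + var(y)·n₂/n` using biased
(population) variances, `n = n₁ + n₂`. The separability criterion is

    J = (A + B − 2C) / (s² + ε),   ε = 1e-8.

`A + B − 2C` is the squared distance between the two class means in the
kernel feature space. With the **linear** kernel `k(a,b) = ab` it equals
`(mean(x) − mean(y))²`, so J reduces exactly to the classical Fisher
discriminant ratio — this identity is the main test oracle for the module.
The default **gaussian** kernel uses the median heuristic: bandwidth equal
to the median of pairwise absolute differences of the z-scored values,
floored at 1e-3 to stay finite under ties.

Ranking (`rank_structures_bin`) follows the Best Individual N (BIN) rule:
score every structure independently, sort descending by J with a stable sort
(ties break toward catalog order), keep the top D.

`SeparabilityEngine` precomputes, from full-cohort z-scores, one (n × n)
kernel matrix per structure, and serves two label-dependent queries without
touching held-out labels:

- `rank(labels, idx, D)`: BIN ranking restricted to subject subset `idx`.
- `criterion_values_loo(labels)`: for each subject i, the criterion computed
  on the other n − 1 subjects, via rank-one updates of the kernel sums. Row
  i is provably independent of label i (flipping label i leaves row i
  unchanged), which is what makes permutation tests with per-split selection
  affordable.

## Spectral similarity features

For each selected structure, z-score its normalized volumes over the
subjects in play (population SD), then build the complete similarity graph

    W_ij = exp(−(z_i − z_j)² / c),   c = 2 by default,

and the unnormalized graph Laplacian L = D − W (a symmetric normalized
variant is available). The embedding takes the k = 2 eigenvectors of L with
the smallest eigenvalues, each scaled to unit norm with the sign fixed so
the largest-magnitude entry is positive (determinism). For a connected graph
the first eigenvector is constant and acts as an intercept; the second
(Fiedler) vector carries the cluster structure. Blocks from the D selected
structures are concatenated into an N × kD feature matrix.

Two evaluation modes exist because the graph couples all subjects:

- **transductive** (default): the graph is built over training and test
  subjects jointly — test *features* see test inputs but never test labels.
- **train_only**: the graph and eigenvectors come from training subjects
  only; test subjects are mapped in by the Nyström extension
  v(x) = (Σⱼ W(x, j) vⱼ) / (d(x) − λ), which reproduces training embeddings
  exactly on training points.

Structures with exactly zero variance are rejected by name (z-scores would
be undefined).

## Classification and evaluation

Two schemes:

- **volumetric**: RBF-kernel SVM on the raw normalized volumes of the D
  selected structures;
- **spectral**: linear SVM on the spectral feature matrix (kD columns).

Hyperparameters (C, γ for RBF, and D) are selected by leave-one-out accuracy
**within each training split only**; structure selection also runs inside the
split. Grid ties break toward the smallest D, then C, then γ. Two grid
profiles exist: `ClassifierSpec.full()` and the faster
`ClassifierSpec.reduced()` (C ∈ {1, 8, 64}, γ ∈ {0.125, 0.5, 2},
D ∈ {1, 2, 4, 8}) used throughout the tests and examples.

Outer evaluation is seeded, stratified, repeated k-fold
(`evaluate_repeated_kfold`); `folds == n` is honoured as literal
leave-one-out. Reported metrics are mean ± SD accuracy over repeats, plus
sensitivity and specificity with the patient (or left-focus) class as
positive. Probability outputs for the left/right side-fusion rule come from
Platt-style sigmoid calibration (`CalibratedClassifierCV` around the SVC);
`combine_side_classifiers` assigns a subject to the side whose classifier is
more confident, with a strict > 0.5 threshold (exactly 0.5 → control).

## Permutation test

`permutation_test` measures significance of a leave-one-out accuracy:
hyperparameters are frozen at the grid medians, but structure selection is
re-run inside every leave-one-out split of every permutation (using the
engine's rank-one LOO machinery), so the null distribution includes
selection variability. The p-value is

    p = (1 + #{null accuracy ≥ observed}) / (1 + B),

with B ≥ 99 permutations required. Because LOO accuracy on small cohorts
takes few distinct values, null p-values are mildly super-uniform
(conservative); the test suite checks they stay within a
Dvoretzky–Kiefer–Wolfowitz band around uniformity rather than demanding
exact uniformity.

## Demographics

`cohort_statistics` reports per-group ICV summaries, Welch's unequal-variance
t-test and the asymptotic Mann–Whitney U test (tie-corrected, with continuity
correction) for group ICV differences, the Pearson correlation between
hippocampal volume and ICV (a positive correlation is a sanity check on the
generative model), and per-structure coefficients of variation. Both
hypothesis tests are two-sided.

## Limitations

- Simple-ratio ICV normalization is exact only under strict proportionality;
  real cohorts often need covariate regression.
- The transductive spectral mode is standard for this family of methods but
  means test inputs influence the feature basis; use `train_only` mode for a
  strictly inductive protocol.
- All reported accuracies characterize the pipeline on synthetic cohorts
  whose effect sizes are assumptions, and transfer no clinical claim.
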