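# Methods

## Model and procedure

The pipeline tests whether a patient's network organization changed
between two sessions more than healthy test–retest variability predicts,
and whether those changes follow one of four patterns in the
altered × original network adjacency matrix: one-with-self (a diagonal
cell), one-with-other (an off-diagonal cell), one-with-many (a row), or
many-with-one (a column).

**Dual regression.** Stage 1 regresses, per time frame, the volume on
the K template maps plus an intercept (ordinary least squares across
voxels); stage 2 regresses, per voxel, the time series on the resulting
K network time courses plus an intercept. Volumes and templates are
demeaned across voxels before stage 1, and stage-1 time courses are
scaled to unit variance (sample SD, n−1) before stage 2. Both
normalizations are flags (default on): the field's common dual-regression
implementations behave this way, and the variance normalization makes
the PE maps comparable across subjects when network amplitudes differ.
Rank-deficient designs raise an error naming the collinear templates
(identified by pivoted QR).

**Smoothing.** PE maps (never the raw data) are smoothed with a
Gaussian kernel, sigma = FWHM / (2√(2 ln 2)), using symmetric-reflection
boundaries. With a symmetric kernel this makes the smoothing operator
doubly stochastic, so constant maps are fixed points and the spatial
mean of every map is conserved to machine precision — a property the
tests assert. FWHM is in physical units; in synthetic mode the voxel
size is 1, so FWHM is effectively in voxels.

**z-difference maps.** Patient difference maps (post − pre) are
z-scored voxelwise against the control difference distribution (mean,
SD with n−1). Voxels with zero control SD are masked (NaN) rather than
infinite and stay excluded from every downstream extremum, count and
cluster.

**Permutation null and FWER.** Per network, each of `n_perm`
permutations draws 18 subjects without replacement from the pooled 62,
z-scores each selected difference map against the remaining 44 (which
may contain patients), and stores each selected map's maximum and
minimum z over unmasked voxels. Pooling is per-map by default
(N = 18·n_perm stored extrema); a per-permutation-max option exists for
sensitivity analysis. Empirical p-values use the add-one convention
p = (c + 1)/(N + 1) with ties counting as extreme, so p = 0 is
unattainable; the literal c/N convention is available by flag. The two
conventions differ by at most one null draw; the add-one default is the
standard safeguard for Monte Carlo p-values. Thresholding is strictly
two-tailed at alpha = 0.025 per tail; increase and decrease ROIs are
extracted separately as face-connected components (6-connectivity in
3D, 4-connectivity in 2D), with no minimum cluster size by default.

**Adjacency and attribution.** An ROI's original network is the argmax
over networks of the mean unthresholded template value across the ROI's
voxels (peak statistic and a template z-threshold are options; ties
break to the lower index with a logged warning). Mean attribution is
the default because it is robust to single-voxel spikes. Per patient
and direction, the binary matrix records each (altered, original) pair
at most once regardless of ROI multiplicity; group frequency matrices
are plain sums and are never symmetrized.

**Hypothesis tests.** The expected count is the grand sum of the K × K
frequency matrix over K² cells. Each cell gets an upper-tail binomial
p, P(X ≥ obs) for X ~ B(n_patients, expected/n_patients) — one-tailed
because the procedure thresholds converted z-scores at positive
cut-offs only — converted to z = Φ⁻¹(1 − p). Row/column counts of
cells with z > 1.96 (strict) are referred to Monte Carlo null
distributions of the maximum row and column count, obtained by
uniformly permuting each patient's K² binary entries (preserving that
patient's total, but no row/column margins — nothing stronger is
implied by a plain within-matrix shuffle), rebuilding the frequency
matrix, and re-running the whole cell-test-and-threshold step. Since
the shuffle preserves the group total, the recomputed expected count is
identical in every repetition; the implementation exploits this by
reducing the per-cell test to a critical patient count, which changes
nothing in the result but makes 10⁵ repetitions cheap. Single cells
beyond z > 3.6623 (p < 0.025/200, Bonferroni over two 100-cell
matrices; strict) are reported, flagged as subsumed when they lie in an
already-significant row or column.

**Individual level.** Per patient and direction, the fraction of ROIs
attributed to each network forms a probability profile (flagged missing
when the patient has no ROIs). Arcsine-transformed profiles enter a
classical two-factor within-subject ANOVA (Coherence × Network), each
effect tested against its own subject-by-factor interaction error term
— dfs (1, n−1), (K−1, (K−1)(n−1)) — without sphericity correction. An
everywhere-constant response is flagged undefined rather than producing
0/0. Prevalence of a network being the (equally-)most-likely original
network is tested with an exact upper-tail binomial whose null
probability is an explicit argument (it is not derivable from the other
reported quantities, so the code never guesses it); a generic exact
binomial power routine (smallest critical count with size ≤ alpha,
power = upper tail at the alternative) accompanies it.

**Clinical statistics.** EDSS uses only patients with both assessments
(12 of 18): this restriction is required to reproduce the published
summary statistics, and the signed-rank statistic W = 53.5 is the
positive-rank sum of relapse − remission after dropping zero
differences and midranking ties — a standardized normal deviate of
that size would be impossible at n = 12, so the printed "z" is read as
the rank sum. The two-tailed p is computed by exact enumeration of all
sign assignments for up to 15 nonzero differences (the fixture has 10,
giving p = 6/1024 ≈ 0.0059) and by the tie-corrected normal
approximation above that. Lesion load uses the paired t-test on the 17
complete pairs of printed two-decimal values, which reproduces the
published t to ~2 decimals. Quartiles follow the median-of-halves rule
(overall median excluded for odd n), the convention that reproduces
the published IQRs from the table.

## Synthetic cohorts

The generator emulates the study's structure: K Gaussian-blob template
maps placed on a jittered lattice and z-scored over voxels (pairwise
correlation driven below a configurable overlap bound by shrinking the
blob width; an exactly zero overlap is unattainable for z-scored
compact maps, which share a small negative baseline); per-session data
`Mᵀ·diag(loadings)·C + ε` with time courses C generated as white noise
smoothed by a 5-sample moving average and standardized (band-limited,
BOLD-like, no hemodynamic model), loadings i.i.d. N(1, 0.1²) per
subject/session/network (test–retest amplitude variability), and
i.i.d. Gaussian noise (default SD 1). Defaults follow the study scale:
18 patients, 44 controls, two sessions each (124 sessions, 62
subjects), a 20×20×1 grid for desk-scale speed, T = 60 frames.

Effects are injected additively on the post session only: for an entry
(patient, altered a, original o, delta), `delta · C[a]` is added to the
time series of a compact patch of voxels inside o's territory. The
patch is seeded at the voxel whose template value sits at the 0.7
within-territory quantile, *not* at the blob peak: a patch at the peak
is nearly collinear with template o itself, so on a small grid the
spatial-regression stage absorbs the injected course into o's time
course and the effect largely disappears — an instructive failure mode
of dual regression at low voxel counts. Mid-territory placement keeps
the absorption small while the patch still belongs unambiguously to
o's territory. Ground truth is retained in machine-readable form for
recovery scoring.

What the generator does **not** model: hemodynamics, head motion,
spatial autocorrelation of real BOLD noise, surface geometry, lesions,
or inter-scan-interval effects (the interval distribution is not
specified beyond its mean and is ignored). Passing recovery tests
therefore show that the *statistical machinery* behaves as claimed
under the assumed mixing model — not that real acquisitions meet those
assumptions.

## Desk-scale test conditions

End-to-end checks run at reduced sizes chosen to finish in minutes on
one CPU while keeping the study's subject structure intact
(18 + 44 × 2 sessions always):

* **Null FWER calibration:** 200 effect-free cohorts, K = 4, 20×20
  grid, T = 60, 500 permutations, FWHM 2 voxels (proportional to the
  20-voxel grid; 5 voxels would smooth a quarter of the field of
  view). The fraction of (patient, network) maps with any
  suprathreshold voxel is compared to 0.025 per tail within a 95% band
  whose standard error is estimated from the independent
  cohort × network block fractions — robust to the (empirically
  negligible) dependence among the 18 patients of one cohort, and
  equal to the plain binomial band when blocks are independent.
* **Row/column FWER:** 200 cohorts of 18 structureless random binary
  matrices (cells i.i.d. Bernoulli(0.1), about the empirical density
  of such matrices), 2000 shuffle repetitions; row and column families
  are checked separately at the 5% + binomial-tolerance bound because
  the procedure builds separate max-row and max-column nulls.
* **Recovery:** K = 10 with the canonical labels, 13 of 18 patients
  injected (delta = 2 in units of the unit-variance course, a moderate
  localized amplitude), altered networks cycling over four networks
  for the many-with-one column fixture (target Crb) and original
  networks cycling for the one-with-many row fixture (altered ECN);
  50 seeded replicates each, 500 permutations and 2000 shuffle
  repetitions per replicate.

Library defaults are the study's own constants (10,000 permutations,
100,000 shuffle repetitions, FWHM 5, alpha 0.025 per tail, Bonferroni
0.025/200); the reduced numbers above are per-run config choices of the
test fixtures, and every report records its resolved config.

## Numerical choices and degenerate inputs

* Monte Carlo p-values: add-one convention by default (see above);
  strict inequalities at both z thresholds.
* Zero-SD voxels masked; a null with every voxel masked in every
  permutation (e.g., all-identical difference maps) raises a
  degenerate-data error, as does a permutation whose selected map is
  fully masked.
* Attribution ties break deterministically to the lower network index
  with a warning.
* ANOVA on an incomplete design raises (no imputation); the pipeline
  records the stage as skipped when zero-ROI patients make a direction
  incomplete, since single-direction fixtures are legitimate runs.
* Missing clinical values are never imputed; pairs with any missing
  member are excluded and counted.
* Reports are JSON with sorted keys and no timestamps, so identical
  configs give byte-identical reports (asserted by a test).

## Known limitations

* The voxelwise null assumes exchangeability of difference maps across
  subjects; group-specific acquisition differences in real data would
  violate it (the design mitigates this by comparing differences of
  differences, but the package cannot verify it).
* Real-volume mode reads NIfTI/TSV volumes but performs no
  preprocessing, registration, or surface handling; inputs must already
  be aligned to a common grid.
* The within-patient shuffle null treats cells as exchangeable within a
  patient's matrix; dependence between cells beyond the per-patient
  total is not modeled.
* Exact signed-rank enumeration is limited to 15 nonzero pairs
  (2¹⁵ assignments); beyond that the tie-corrected normal approximation
  is used without continuity correction.
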