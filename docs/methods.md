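# Methods

This note documents the statistical model behind the package, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not demonstrate.

## Pipeline model

The pipeline assumes a feature table of raw, positive ion-count
intensities (features × samples) with missing cells marking
non-detections, and per-sample annotations: sample type (blank, control,
treated, QC), preparation batch, 1-based injection order, replicate
group, compound, and class label. Stages run in a fixed order; any stage
can be skipped but not reordered, because the later stages' contracts
depend on the earlier ones (log2 before LOESS, filters before modeling).

1. **Charge filter** — features with no established charge state (charge
   0) are unreliable identifications and are dropped.
2. **Blank filter** — a feature is a contaminant if its median intensity
   over blank injections exceeds 1% (`blank_ratio`) of its maximum over
   all other samples. A blank non-detection counts as intensity 0
   (absence of evidence in a blank *is* evidence of absence), whereas
   missing cells in non-blank samples are ignored in the maximum; this
   asymmetry makes the rule sensitive to presence-in-blanks only. Blanks
   are dropped from the table afterwards.
3. **Batch-specific filter** — features whose every detection falls in
   fewer than `batch_specific_min_batches` (default 2) batches cannot be
   distinguished from batch artifacts and are removed, as are features
   never detected at all.
4. **log2 transform** — compresses the dynamic range; the raw matrix is
   retained because the total ion count remains an ion-count concept.
5. **TIC outlier filter** — a non-blank sample is a failed injection if
   its total ion count (sum of detected raw intensities) is below 70%
   (`tic_fraction`) of the mean TIC over all non-blank samples. The mean
   includes the candidates themselves — a single-pass rule, no iterative
   trimming.
6. **Replicate concordance** — within each replicate group a spectrum is
   kept iff its best Pearson correlation to any *other* member exceeds
   0.8 (`replicate_r_min`), computed on features detected in both
   spectra (at least 3, otherwise the sample is flagged, not removed).
   The pass is non-cascading: each spectrum is compared against the
   original group.
7. **Cyclic LOESS** — for every pair of samples, the log-ratio
   M = x_i − x_j is regressed on the mean A = (x_i + x_j)/2 with a
   degree-1 LOESS (span 0.7) and half of the fitted trend is moved from
   one column to the other; three full sweeps over all pairs in
   lexicographic order. This flattens intensity-dependent distortions
   such as decay over the injection sequence. The smoother uses the
   `delta` interpolation shortcut (1% of the A-range), which changes
   fitted values negligibly while making the O(N²) pair sweep affordable.
8. **Shift and batch removal (OOS-DA)** — see below.
9. **Replicate merging** — per-feature median over each replicate group;
   a merged cell is missing only when all replicates are missing.

## OOS-DA

The discriminant decomposition extracts orthonormal directions
w₁, w₂, … where w₁ maximizes the Fisher ratio
J(w) = wᵀS_b w / wᵀS_w w and each wᵢ maximizes J subject to
orthonormality with its predecessors. The constrained problems are
solved exactly: project S_b and S_w onto an orthonormal basis of the
complement of span(w₁…wᵢ₋₁) (via QR) and take the leading generalized
eigenvector there. For two classes and one axis this reduces to the
classical Fisher discriminant S_w⁻¹(m₁ − m₂), which the test suite
verifies on 200 random instances.

Conventions and numerics:

- Scatter matrices are raw sums (no 1/N); the ratio is scale-invariant.
- S_b weights class means by class size; an unweighted variant is
  available (`scatter_weighting="unweighted"`).
- Sign convention: each axis's largest-magnitude entry is positive, so
  repeated fits are bit-identical.
- S_w with condition number above 1e8 (or exactly rank-deficient) raises
  an error directing the caller to increase the pre-compression
  parameter k; the generalized eigensolver falls back to a trace-scaled
  ridge (1e-10 · trace/p) only if the factorization itself fails.

### PCA pre-compression and removal

Spectra are compressed to min(N − k, p) dimensions by column-centered
PCA before fitting (missing cells imputed to 0, matching the upstream
convention in which a zero denotes a failed feature link). Removal
subtracts the projection onto the first d axes in the score space and
back-projects through the PCA loadings; the saved missing-cell positions
are reinstated afterwards so no spurious values are introduced. k
defaults to 2 for the two-level shift nuisance and 8 for batches;
if the within-class scatter is still ill-conditioned, k is raised
automatically until the fit succeeds.

### Dimension tuning

b(d) is the mean distance between anchor-replicate centroids and their
global centroid after removing d axes, evaluated in the compressed score
space (orthonormal back-projection preserves distances, so this is
equivalent and cheaper). The anchors are grouped by the nuisance classes
being removed — pre/post-shift groups in the shift step, batches in the
batch step — because those are the centroids the removal should
collapse. d_best is the smallest d with |b(d+1) − b(d)|/b(d) < 1%
(`d_rel_tol`); if the curve never stabilizes by d_max
(default min(20, N − k − 1)), d_max is used with a warning. Tuning runs
separately for the shift and batch steps, on unmerged anchor replicates
(more samples per class).

**A property worth knowing:** d_best generally *overshoots* the true
rank of the nuisance. The axes are whitened by the *sampled*
within-class scatter, so each axis captures only part of the
nuisance-mean subspace (the sampling tilt grows as the compressed
dimension approaches N), and b(d) decays gradually toward the anchor
noise floor rather than dropping and flattening exactly at the true
rank. Simulations with a known rank-q batch effect show the rule firing
several dimensions past q. The overshoot is benign in practice — the
extra axes remove residual nuisance at a small cost in retained signal,
and the efficacy tests (below) pass with tuned d — but b(d) should be
read as a stopping heuristic, not a rank estimator.

### Separation score and permutation test

s_sep = b/w, where b is the mean distance of class centroids from their
unweighted global centroid and w the mean within-class distance of
samples from their own centroid, both in the 3-D (`sep_dims`) OOS-DA
space. The permutation test refits the model on each of `n_perm`
(default 10,000) uniformly permuted label vectors and reports the
add-one estimator p = (1 + #{s_null ≥ s_obs})/(1 + n_perm), which can
never return 0. The PCA pre-compression ignores labels and is computed
once outside the loop. This test exists precisely because OOS-DA (like
any flexible discriminant method) finds visually clean separations for
*random* labels in high dimensions; only the permutation p-value, never
the score plot, is evidence.

## The simulator

`simulate_experiment` emulates a four-batch cell-exposure design:
27 compounds × 3 biological replicates (replicate trios spread across
batches), 3 anchor-compound replicates per batch (12 total), 12 vehicle
controls in cross-batch trios, and 6 solvent blanks per batch — 129
injections, ~3800 features, injection order randomized. On a clean log2
signal (feature baselines N(18, 2.5²), per-class effects of ±1 log2 on
10% of features, biological noise 0.2) it adds:

- **batch offsets**: rank-q (default 2) with orthogonal ±1 design
  coefficients per batch (jittered 0.15), per-feature RMS 0.6 log2;
- **step shift**: a fixed random direction added to all injections after
  index 55, per-feature RMS 0.8 log2;
- **decay**: −0.005 log2 per injection, uniform across features;
- **measurement noise**: N(0, 0.3²);
- **contaminants**: 2% of features keep full intensity in blanks (other
  features drop 8 log2 units there);
- **missingness**: raw intensities below 2¹¹ are masked, so missing
  cells concentrate in low-intensity features (~1% of retained
  non-blank cells at the defaults).

The generator is seed-deterministic and its truth record reconstructs
the observed matrix from the clean one exactly.

What it does *not* emulate: correlated feature blocks (co-eluting ions,
isotopes, adducts), retention-time-local distortions, heteroscedastic
feature noise, carry-over between adjacent injections, and QC-pool
drift. Passing tests therefore demonstrate correctness of the
algorithms under the stated additive low-rank nuisance model, not
robustness to every artifact of real chromatography.

On missingness: the zero-imputation convention places missing cells ~18
log2 units below the data, so each masked cell acts as a large spike.
At ~1% missingness this is harmless; at several percent the spikes
dominate the PCA/OOS-DA geometry and both tuning and removal degrade.
Tables with heavy missingness should be imputed or filtered for
detection rate upstream — a known limitation of the zero convention.

## Problem sizes used by the tests

Unit tests run on toy tables (≤ 10 × 6) and small simulations (40–250
features). The efficacy and end-to-end acceptance tests run the full
default scale (3800 × 129). The dimension-tuning recovery study uses
250-feature simulations with a strong (RMS 1.5) batch effect, 100 seeds
per rank; the permutation-calibration study uses 200 pure-noise datasets
(30 samples × 40 features, 200 permutations each). These sizes are the
package's own choices for a thorough desk-scale validation.

## Known limitations

- d_best overshoots the true nuisance rank (mechanism above).
- The permutation test is exact only under label exchangeability; with
  replicate structure left unmerged, exchanging individual injections
  overstates the effective sample size — run it on merged data.
- With very few exchangeable units in one class (e.g., 4 merged control
  groups), the test is honest but underpowered.
- Cyclic LOESS results depend weakly on the pair sweep order; the order
  is fixed (lexicographic) for reproducibility.
- Supervised removal protects signal only insofar as the signal is not
  collinear with the nuisance labels; a confounded design (class nested
  in batch) cannot be rescued.
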