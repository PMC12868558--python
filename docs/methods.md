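# Methods

This note documents the models and procedures `hetconn` implements, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not establish.

## Heterogeneous matrix factorization (meta-BOLD)

**Model.** Subject $i$'s standardized region × time matrix is
$M_i = U_g V_{gi}^\top + U_{li} V_{li}^\top + E_i$ with orthonormal-column
bases, the constraint $U_g^\top U_{li} = 0$, and the Frobenius
reconstruction loss $\tfrac12 \sum_i \lVert M_i - U_g V_{gi}^\top -
U_{li} V_{li}^\top\rVert_F^2$. The shared basis is common to the cohort;
its reconstruction $U_g V_{gi}^\top$ is the meta-BOLD signal.

**Solver.** Alternating least squares where each step is an exact
minimizer:

* given $U_g$: $V_{gi} = M_i^\top U_g$, and $(U_{li}, V_{li})$ from the
  rank-$r_l$ truncated SVD of $(I - U_g U_g^\top) M_i$ — the constraint
  holds by construction;
* given the specific factors: $U_g$ from the top-$r_g$ left singular
  subspace of the column-concatenation of $M_i - U_{li} V_{li}^\top$.

Both steps can only decrease the loss (the previous specific factors,
projected into the new complement, are a feasible point of the constrained
subproblem), so the recorded loss trace is non-increasing; the tests
assert this at slack 1e-10. Bases stay orthonormal with scale absorbed
into coefficients; the sign of each basis column is fixed by making its
largest-magnitude entry positive. $U_g$ is identified only up to rotation
within the shared subspace, so all comparisons use projectors or principal
angles. Initialization is deterministic (top left singular vectors of the
concatenated data). Convergence: relative loss change below `rel_tol`
(default 1e-6) or `max_iter` (default 200). Ranks are user-supplied;
`rank_curve` reports MSE-versus-rank but makes no automatic choice.

**Diagnostics.** `reconstruction_mse` (meta-only mode is the fidelity
metric), `within_group_variability` (mean across-subject SD of FC edges),
and `snr_metric` (edgewise squared group-mean difference over pooled
variance — a standard contrast-to-noise definition; other definitions
exist, so its absolute values are not comparable across conventions).

## Connectivity and edge space

FC is Pearson correlation of region time series (constant regions get zero
correlations with a warning). "Standardization" is implemented as two
explicit, separable steps: Fisher r-to-z per edge (|r| clipped at
1 − 1e-7), then edgewise z-scoring across subjects before PLS (ddof = 1).
Edge vectorization uses upper-triangle, 0-based, row-major order through
`EdgeIndexMap`; no module assumes the order implicitly. Covariate removal
is OLS residualization on intercept + dummy-coded categorical and numeric
covariates with column means added back; it is idempotent. Site is handled
as a categorical covariate — a deliberate, simpler stand-in for dedicated
batch-harmonization tools. The atlas utility merges integer label volumes
by offsetting later volumes past the running maximum label, keeping the
larger label on overlap, and removing labels under `min_voxels`
(default 10).

## Shared pattern and deviations

With a centered binary response, the first PLS weight vector is
$w \propto X^\top y$ — this closed form is both the implementation and the
test oracle, and it is exactly the between-group-separation-maximizing
first component; no deflation is needed because only component 1 defines
the pattern. Labels are coded HC = −1, patient = +1; the sign of $w$ makes
the patient-mean projection positive. Deviations use the unit-norm $w$, so
residuals are exactly orthogonal to it and the Pythagorean identity holds.

**A structural constraint worth knowing.** DSCDs are means of residuals of
a column-centered (restandardized) patient cohort, so they satisfy
$\sum_g n_g \, \mathrm{DSCD}_g = 0$ identically. Two equal-sized disorders
therefore always yield cosine −1, and an arbitrary planted geometry is not
estimable. `synth.closed_deviation_geometry` constructs the closed
three-disorder geometry (third direction proportional to the negative
weighted sum of the first two) in which a requested pairwise cosine
survives centering unchanged; the demo and the recovery benchmarks use it.
A second analytic effect is shrinkage: averaging $n$ noisy residuals
leaves a noise floor with squared norm ≈ (edges)/n, attenuating cosines by
roughly $1/(1 + E/(n\,m^2))$ for deviation magnitude $m$. At the benchmark
conditions (45 edges, n = 150, m = 4, edge noise SD 1) the planted −0.9 is
expected near −0.88, within the ±0.05 recovery band.

Edge profiling takes the top `fraction` (default 1%) of |weights| with
ties broken by ascending edge index, counts unordered network pairs,
summarizes subjects by the first principal component over those edges
(loading sign fixed by its largest-|·| entry), and associates scores with
clinical scales by Spearman correlation with a seeded 1,000-resample
bootstrap percentile CI (the CI method is our choice; nothing canonical
exists).

## Molecular annotation

**Correlated gene expression.** Variables may be z-scored across regions
first (`normalize="zscore"`, the convention for expression data on
incommensurate scales) or left raw (`"none"`); note the cross-region
centering in the z-score variant slightly deflates correlations when
regions are strongly spatially correlated, which matters for closed-loop
decay recovery on synthetic maps. The distance decay
$r(d) = A e^{-d/\text{scale}} + B$ is fitted by bounded nonlinear least
squares (init: amplitude = value range, offset = min value, scale = median
distance; scale bounded by 10× the max distance; tolerances 1e-12);
residualization subtracts the fitted curve.

**Gene contributions.** Contribution of gene $g$ to pair $(i,j)$ is
$z_{ig} z_{jg}/(G-1)$ with row-standardized profiles — the unique additive
decomposition whose gene-sum reproduces the pair's Pearson correlation
exactly (asserted at 1e-10). This conservation law is the reason this
decomposition was chosen over alternatives the literature leaves
unspecified.

**Feature (neurotransmitter/mitochondrial) contributions.** The
region-by-region covariance treats feature maps as observations. Shrinkage
follows Ledoit–Wolf with the scaled-identity target
$\mathrm{tr}(S)/p \cdot I$, where $p$ is the dimension of $S$ — the number
of regions; taking $p$ as the number of features would put the target on
the wrong scale for a region-indexed covariance, so the region reading is
used. The analytic optimal intensity is re-estimated per reduced feature
set by default (`alpha_policy="frozen"` reuses or fixes it; a fixed α with
uncentered moments makes the estimate exactly invariant to duplicate
columns, which the tests exploit). Precisions come from Cholesky solves
with a recorded condition number. The perturbation score
$S_{ij,f} = P^{\mathrm{full}}_{ij} - P^{-f}_{ij}$ equals the residual form
$(P^{\mathrm{full}} - E)_{ij} - (P^{-f} - E)_{ij}$ because the theoretical
matrix $E$ cancels; the identity is asserted at 1e-12 on every call. $E$'s
diagonal is set to 0 (the decay curve is defined for distinct regions).
Note that subtracting a correlation-scale $E$ from a precision-scale
matrix mixes scales; it is implemented exactly as specified and is
irrelevant to the perturbation scores by the cancellation.

**PLS annotation.** Edges are observations, contributions are predictors,
the edge-weight pattern is the response. Component count maximizes 5-fold
cross-validated explained variance, capped at 10 (or the feature count).
Components are oriented so their scores covary positively with the
response. Significance uses spatially constrained permutations: regions
are binned into quintiles of mean inter-region distance and shuffled
within bins, preserving the gross spatial profile while destroying
identity — a declared approximation to variogram-matched surrogate maps;
`null_generator` accepts any replacement. Bootstrap (edge resampling,
sign-aligned) yields per-variable z scores, two-sided normal p-values, and
Benjamini–Hochberg flags at q < 0.05.

## Validation machinery

Bootstrap resamples are stratified by class to avoid degenerate draws.
Cross-validation refits the direction inside every training fold (chosen
to keep held-out estimates leakage-free; possibly stricter than common
practice), then fits a univariate logistic model on training projections;
accuracy thresholds predicted probability at 0.5. The permutation test
statistic is the absolute between-group mean projection difference; nulls
refit the direction per shuffle, and p uses the add-one formula, so it is
never zero and is exactly uniform under exchangeability — the calibration
benchmark checks the type-I rate over 200 null simulations at α = 0.05.
Split-half reliability correlates half-group mean edge vectors over seeded
random splits.

## Synthetic data: what it emulates and what it does not

* **BOLD cohorts** are exact low-rank superpositions plus white noise; the
  specific basis is drawn in the orthogonal complement of the shared one,
  so the model's constraint holds in truth and recovery tests are
  well-posed. Rows are z-scored after noise injection (matching the
  standardized-input convention); z-scoring distorts the planted subspace
  slightly (per-subject row rescaling), so exact-recovery oracles disable
  it. Defaults allocate 1% of shared-signal variance to subject-specific
  components and (in the benchmark) 2% to noise: the regime where the
  shared signal dominates, which is the regime the meta-BOLD fidelity
  analysis describes — shared components explaining ≳96% of the
  standardized signal. With that composition the fidelity benchmark lands
  near MSE 0.034. No hemodynamics, scanner physics, temporal
  autocorrelation, or site batch structure is simulated.
* **Edge cohorts** are baseline + planted group shift + per-disorder
  deviations (with exact requested Gram geometry, orthogonal to the
  shift) + white noise; clinical scores are a noisy monotone (exponential)
  transform of each patient's realized deviation score, with the noise
  scale bisected until the realized Spearman correlation is within ±0.03
  of the requested coupling. Deviation magnitude defaults to 4 with
  per-subject SD 1 (edge noise SD 1): strong but subject-variable
  deviations, giving the geometry benchmarks a ~0.02 analytic attenuation
  rather than a noise-dominated estimate.
* **Spatial profiles** are $K^{1/2}W$ draws with kernel
  $K_{ij} = A e^{-d_{ij}/s} + B$ (unit diagonal), so expected inter-region
  profile correlation follows the decay curve by construction; the
  closed-loop benchmark refits the planted (0.8, 0.05, 20 mm) triple
  within 10% at 500 variables.
* **Label volumes** place labels in disjoint grid cells with known
  counts, one deliberately sub-threshold label, and optional overlaps.

One integer seed fans out to fixed named substreams
(`hetconn._utils.STREAM_TAGS`); the tag table is part of the public
contract, and identical seeds give bit-identical outputs, which the
end-to-end determinism benchmark checks via sha256 hashes of every stage
output.

Passing these benchmarks shows the estimators are correct and calibrated
under the generative assumptions they encode — additive low-rank
structure, white noise, exponential spatial decay. It does not show
robustness to hemodynamic confounds, motion, site effects, non-exponential
spatial autocorrelation, or model misspecification in real cohorts.

## Problem sizes

The default test and benchmark sizes (≤ 20 subjects × 100 regions × 200
timepoints for factorization; 600-subject, 45-edge cohorts for geometry;
≤ 120 regions × 500 variables for annotation) were chosen so each
benchmark isolates one estimator at a scale where its expected behaviour
is analytically predictable; the algorithms themselves are dense linear
algebra and scale to atlas-sized problems (324 regions, 52,326 edges)
without modification.
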