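# Methods

This note records the model, the numerical conventions, and the design
choices made where the procedure left genuine freedom. Everything stated
here is computed by the test suite or the example scripts; no empirical
claim beyond those is made.

## Preprocessing

Input is a genes × samples matrix of already-normalized expression
summaries (raw-array normalization is out of scope). The pipeline is:
KNN imputation → variance screening → rescaling, in that order. Imputation
must precede screening because variances are undefined on incomplete rows;
screening must precede rescaling because rescaled genes all have variance
one, which would make a variance screen vacuous.

* **KNN imputation** (default k = 10, the common microarray default): a
  missing entry (g, s) is replaced by the mean over the k nearest gene rows
  observed at s, with distance the root-mean-square difference over
  co-observed samples. Observed entries are never modified; fewer than k
  usable neighbors fall back to those available; a fully missing gene is an
  error.
* **Variance screening** keeps the `d_keep` (default 2000) genes with the
  largest unbiased (n−1) sample variance; ties break by input order.
* **Rescaling** maps each gene to zero median (even n: midpoint of the two
  central order statistics) and unit ddof-1 variance; it is idempotent to
  1e-8 and rejects constant genes.

## Network construction

Similarity S = |Pearson correlation|; adjacency a = S^b off-diagonal.

* **Self-term convention.** Connectivity and topological-overlap sums
  exclude self terms (a_{k,k} treated as 0, and l_{k,j} = Σ_u a_{k,u}a_{j,u}
  with u ∉ {k, j}); under this convention the overlap ω and hence
  D = 1 − ω are guaranteed to lie in [0, 1]. A `literal_sums` flag instead
  includes the diagonal terms as the formulas read when written with sums
  over all u; since ω can then exceed 1, entries are clipped back into
  [0, 1]. The default (exclusion) is the standard weighted-coexpression
  formulation.
* **Power selection.** For each candidate power (default 1…10) the
  connectivity distribution is split into 10 equal-width bins (empty bins
  dropped) and log10(frequency) is regressed on log10(mean bin
  connectivity); the chosen power is the smallest with R² ≥ 0.8, else the
  maximizer, else an optional fallback of 6 (the conventional value for
  these networks). Equal-width binning is used because equal-count bins
  make the bin frequencies constant by construction, degenerating the
  regression.
* **Module detection.** Average-linkage hierarchical clustering of D.
  The default cut height is adaptive, in the spirit of dynamic tree cut:
  the tree is cut just below the lowest merge that joins two branches each
  already holding ≥ `min_module_size` (default 25) leaves (just below the
  final merge when no such join exists). A fixed fraction of the maximum
  merge height is unreliable here: for soft-thresholded networks the TOM
  heights concentrate near 1 and a fixed-fraction cut shreds genuine
  modules. The adaptive rule assumes a module is not internally split into
  two branches that both reach the minimum size, i.e. modules smaller than
  twice the minimum size are always safe. An explicit `cut_height`
  overrides the rule. Modules are labeled 1..M by decreasing size (ties by
  smallest member index); label 0 means unassigned.

## Representative features

PCA is run per module on the samples × genes submatrix, column-centered.
Score columns are unit-norm and orthogonal; variance fractions are the
normalized squared singular values. Sign is fixed deterministically: each
score column is flipped to correlate non-negatively with the module's mean
expression profile, with the largest-magnitude loading forced positive on
exact ties — rebuilding from the same bytes is bit-identical.

R1/R2 use each module's first PC; R3/R4 use the smallest m* PCs per module
whose cumulative variance fraction reaches ξ% (default 80). R2/R4 append
all pairwise products (quadratics i = j included) of their first-order
columns; only i ≤ j is stored. Product columns are not re-centered or
re-scaled at construction — standardization is the fitter's concern. New
samples are always projected with the *training* means and loadings.

## Cox model and TGDR

Ties are handled by Breslow risk sets r_i = {k : Y_k ≥ Y_i}, matching the
risk-set definition the partial likelihood is written with. The likelihood
and gradient are computed by suffix cumulative sums over time-sorted
subjects with a max-subtraction overflow guard (risk sums additionally
clamped away from zero at extreme coefficients).

Features are internally centered and scaled to unit Euclidean norm before
fitting: thresholding compares |g_j| across features, which is only
meaningful on a common scale (PC columns are already unit-norm; product
columns are not). Coefficients are mapped back to the input scale on
output. With Δν = 10⁻³ on unit-norm features the ascent is monotone in
practice; the step count K does the regularization.

The modified thresholding evaluates second-order components first, then
first-order components: (0, j) is selected if its own gradient passes the
threshold or any selected second-order term has j as a parent. Because a
parent is updated in the same iteration as its child, a nonzero product
coefficient always has nonzero parent coefficients.

**Tuning.** (τ, K) are tuned jointly by stratified (on the event
indicator) V-fold cross-validation of the Verweij–van Houwelingen
criterion Σ_v [R_all(β^{(−v)}) − R_{(−v)}(β^{(−v)})], evaluated after every
update along each fold's path; the search along K stops after `patience`
(default 200) non-improving steps, with K_max defaulting to 2500. Ties
prefer smaller K, then larger τ (stronger thresholding). Whether to
standardize product features and whether K is tuned per τ or jointly are
not dictated by the procedure itself; the choices above (standardize;
jointly) are exposed in the API.

## Evaluation

Out-of-fold risk scores come from V-fold (default 5) cross-validation with
nested inner tuning. By default the network, modules and features — all
unsupervised — are built once on the full data and only the regularized
estimation is re-run per fold; a strict mode rebuilds everything inside
each fold and projects held-out samples with training loadings. Scores
equal to the median go to the low-risk group (deterministic). The logrank
statistic is delegated to lifelines; Harrell's C counts a pair as usable
when the earlier observed time is an event and the times differ, with tied
scores worth 1/2.

The gene-level rewriting uses the fact that each first-order feature is
w′(u − μ) with w supported on one module: the linear part is Σ β_{0,i} w_i
and each product contributes a rank-one quadratic. Gene-level risk scores
reproduce feature-level ones exactly. Because all genes are rescaled to
equal variance, coefficient magnitudes across linear, quadratic and
interaction terms are compared directly when ranking the top (default 20)
terms.

## Simulator

The generator emulates a prognosis study at desk scale. Defaults: 200
subjects (split 100/100 train/test), 500 genes in 10 modules of 40 plus
100 background genes; per module a standard-normal latent factor F with
gene loadings ρ ~ Uniform(0.3, 0.9), U = ρF + √(1−ρ²)·noise; background
genes independent noise; the matrix is then rescaled like real data. This
preserves the one property the downstream method needs — block correlation
structure — but is deliberately simpler than real microarray data: no
heavy tails, no overlapping or hierarchical modules, no batch effects, and
a single factor per module (so first PCs carry most of the block signal).
Passing tests therefore demonstrate correctness of the machinery and
qualitative behavior, not performance on real arrays.

Survival: 10 randomly chosen representative features get i.i.d.
Uniform(−0.5, 0.5) coefficients; event times are exponential with rate
λ₀·exp(lp), λ₀ = 0.5; censoring times are independent exponentials whose
rate is calibrated by Brent root-finding so the expected censoring
fraction E[λ_c/(λ_c + λ₀ e^lp)] hits the target (default 40%). The linear
predictor applies the coefficients to variance-standardized feature
columns: on the unit-norm scale a score entry is O(1/√n), so fixed-range
coefficients would carry vanishing signal as n grows; standardizing makes
Uniform(−0.5, 0.5) a meaningful effect size at any n. The exponential
censoring family is the simplest independent family with a tractable
censoring probability.

**Study sizes.** The replicate study (`run_study`) builds everything on
the training half only and projects the test half. The packaged tests run
it at reduced scale — 10 modules of 25 genes, ξ = 45, a coarse τ grid,
V = 3, 20 replicates — chosen once so that the R4 expansion (which grows
as P(P+3)/2) stays at a tractable dimension while preserving the
qualitative contrasts of interest: nested truths predict well under every
kind, and interaction truths are predicted best by the kinds that contain
products. Paper-scale settings (ξ = 80, τ grid 1.0…0, K_max 2500, 500
replicates) remain reachable through `SimConfig`.

## Known limitations

* The adaptive cut is a static approximation to dynamic tree cut; deeply
  nested or very unequal-height module structure may need an explicit
  `cut_height`.
* TGDR with a fixed Δν converges slowly near the optimum; exact MLE
  agreement (used only as a test oracle) needs ~10⁵ iterations on toys.
* The simulator's single-factor modules make higher PCs mostly noise, so
  ξ = 80% keeps many PCs per module; analyses of such data at full ξ are
  expensive by construction, which is a property of the generator rather
  than of the method.
* `literal_sums` is provided for exactness of the printed sums but clips
  the resulting dissimilarities; it is not recommended for analysis.
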