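# Methods

`mrnet` implements a master-regulator (MR) screen for case/control expression
cohorts: reverse-engineer each cohort's transcription-factor (TF) → target
network from mutual information, score every TF's regulon against the
case-vs-control signature with a rank-based enrichment statistic calibrated by
sample permutation, intersect the significant TFs across cohorts, and relate
the surviving MRs to ordinal pathology grades, survival and cell-infiltration
scores. A synthetic-cohort generator with planted ground truth makes every
stage testable at desk scale.

## Network deconvolution

**MI estimator.** For each candidate (regulator, gene) pair, both profiles are
replaced by their copula margins (ordinal ranks mapped to (0, 1)); the joint
density on the n rank points is a product Gaussian kernel with bandwidth
h = sd(u)·n^(−1/6), and MI (nats) is the mean log density ratio over the data
points, clipped at 0. Because every gene's ranks are a permutation of the same
grid, the kernel matrix and the marginal density are computed once per sample
size. Consequences: symmetry and invariance under strictly monotone transforms
are *exact*, and MI(x, x) bounds MI(x, y) for every y (Cauchy–Schwarz on the
kernel products). Constant-expression genes are undefined under ranks and are
dropped with a logged count before estimation.

**Independence null and the 1e-8 threshold.** The null is built by estimating
MI between randomly chosen gene pairs after shuffling one profile's sample
order (n_perm ≥ 100, default 1000; < 20 points above the 95th percentile is an
error). An empirical null cannot resolve p ≈ 1e-8, so an exponential tail is
fitted by maximum likelihood to the exceedances over the upper-5% quantile and
extrapolated; below the quantile the empirical survival function is used, so
the p-value is continuous at the splice and monotone in MI. Edges are kept
when the *raw* tail p falls below the threshold (default 1e-8). In the
original network-deconvolution convention that per-pair threshold is chosen
deliberately tiny precisely because of the multiplicity of tested pairs;
applying a Bonferroni factor on top of it double-counts the correction and, on
the planted benchmark below, halves recall. The Bonferroni-corrected p over
the candidate universe |regulators| × (|genes| − 1) is still reported on every
edge, and `p_corrected=True` switches the threshold to it for users who want
the stricter reading.

**DPI trimming.** For every kept edge (x, y) and every regulator z closing a
triangle in the *original* edge list, the edge is removed when
MI(x, y) < (1 − tolerance)·min[MI(x, z), MI(z, y)] (tolerance default 0.1).
The pass is single-shot — removal decisions never cascade — and equality keeps
the edge. Tests check exact agreement with an exhaustive-triple oracle.

**Regulons.** Surviving edges are grouped per TF; the mode of each interaction
is the Spearman correlation between TF and target expression (sign =
activation vs repression) and the confidence weight is the edge MI divided by
the regulon's maximum MI, so the best-supported interaction has weight 1.
TFs with fewer than `min_size` targets (default 25) are dropped with a logged
warning.

## Regulon activity

**Signature.** Per-gene Welch t (cases minus controls) mapped through the t
distribution to a normal z-score, computed as sign(t)·Φ⁻¹(sf(|t|)) so that
swapping the labels negates every value bitwise; |z| is capped at 8 and a
variance floor of 1e-12 guards degenerate genes (logged).

**Enrichment score.** The signature is rank-transformed to symmetrized normal
quantiles of i/(N+1); a regulon's score is
NES = Σᵢ wᵢ·modeᵢ·q(targetᵢ) / √(Σᵢ wᵢ²), with wᵢ the interaction likelihood.
Under random regulons this is ~N(0, 1) (checked by Monte Carlo and by
exhaustive enumeration on tiny universes). This is a deliberate simplification
of the full three-tail VIPER combination: modes here come from Spearman signs
and are near ±1, so the two-tail term for weak modes is omitted. Pleiotropy /
shadow correction is *not* implemented; the CLI reserves `--pleiotropy` and
errors if it is set, because no defensible parameterization was available.

**Permutation null.** Labels are shuffled (by sample index, preserving group
sizes), the signature and all scores recomputed, n_perm times (default 1000,
minimum 100). Each TF's null scores are standardized by their own mean and SD
— this absorbs the TF-specific variance inflation caused by regulon coherence
under sample permutation — and the standardized nulls are pooled across TFs
for tail resolution. The reported NES is the observed score on the same
standardized scale; the two-sided p is the pooled-tail frequency with a
pseudocount, so the smallest attainable p is 1/(n_perm·n_TF + 1).
Benjamini–Hochberg adjustment across TFs gives the selection criterion
(adjusted p < α, default 0.05); raw p is also reported. Consensus MRs must be
significant in *every* cohort with a concordant NES sign; discordant TFs are
excluded and logged, and the candidate-overlap count is kept in the result's
metadata for transparency.

**Power regime (important).** With a rank-based score and a sample-permutation
null, the null NES retains a regulon-coherent component whose per-target size
is ≈ s·σ_activity/σ_target (latent-activity sampling plus shift mixing) — it
does not shrink with sample size — while the observed NES saturates once a
regulon's targets occupy the extreme ranks. Two consequences shape any
benchmark: (i) when planted targets are a large fraction of the universe the
rank transform loses resolution and nothing is significant; (ii) power comes
from measurement noise being at least comparable to the regulatory signal,
which shrinks the coherent null relative to the (already saturated) observed
score. The shipped MR benchmark (`mrnet.synthetic.mr_benchmark`: 14 activated
+ 8 repressed among 50 TFs, regulons of 20–50 targets over 5000 genes, effect
size 2, noise SD 1.5, two cohorts of 100 cases + 100 controls) sits in that
regime and is recovered essentially completely. The same analysis implies the
network stage and the activity stage prefer *opposite* signal-to-noise
regimes: edge detection at p < 1e-8 needs strong per-edge correlation (noise
SD ≲ 0.5 for the strengths used), while activity significance needs noise SD ≳
1.5. Chaining both stages at a single intermediate noise recovers only a
minority of planted MRs; the two stages are therefore benchmarked in their own
regimes, and real-data users should expect the screen to recover only the
strongest regulators — consistent with the small fraction of the TF panel such
screens report in practice.

## Clinical association

Ordinal inflammation/fibrosis grades (0–3) enter Pearson correlation as
numeric values; the result is invariant to affine re-coding of the scale. The
p-value is the two-sided t transform with n − 2 degrees of freedom on
pairwise-complete samples (≥ 3 required; constant inputs are errors).

Survival uses a single-covariate Cox proportional-hazards model, fitted by
Newton–Raphson on the partial likelihood with Breslow handling of ties
(tolerance 1e-8, ≤ 50 iterations). Monotone likelihood (perfect separation)
and non-convergence are reported through a flag, not an exception. The fit is
cross-checked against an independent survival library in the test suite
(agreement to ~1e-5) and calibrated by simulation (|bias| < 0.05 and ~95%
Wald CI coverage at n = 500).

Cell-infiltration scores are single-sample GSEA: per sample, genes are ranked
by expression descending; the score is the sum over ranks of the difference
between the in-set ECDF weighted by rank^0.25 (rank counted from the bottom,
top gene largest) and the unweighted out-set ECDF; sets mapping < 3 genes are
dropped; scores are normalized by the global max − min across the matrix (raw
scores available). Per-sample TF activity, needed to correlate activity with
cell scores, is the enrichment score of each regulon on the sample's
one-vs-rest z signature (gene-wise standardization against the cohort). Both
choices follow the common conventions for these statistics; neither is
prescribed in more detail by the problem.

## Over-representation analysis

Hypergeometric upper tail of a query list against each gene set, after
restricting sets to an in-universe size within [5, 2000]; BH FDR across tested
sets ("B&H" is interpreted as Benjamini–Hochberg; Bonferroni available by
flag). The universe is a mandatory explicit input because the result is
universe-sensitive; the pipeline defaults to the union of expressed genes.

## Synthetic cohorts

Per sample, each TF has latent activity a_t ~ N(0, 1), shifted by
±effect_size in cases for planted-activated/-repressed TFs. A TF's own
expression is a_t plus N(0, noise_sd); a target's expression is
Σ strength·mode·a_t over its regulators plus noise; all other genes are pure
noise. Optional count mode puts Poisson sampling on the exponentiated scale
(log1p output) to emulate RNA-seq. The clinical table (cases only) draws
ordinal 0–3 grades by thresholding a Gaussian latent, ρ = 0.6-correlated with
the driver TF's activity, at fixed quartile cutpoints; survival is exponential
with log-hazard 0.7 per activity SD, baseline hazard 1/36 per month, and
administrative censoring at 36 months (≈ 30–40% censored). Four cell types
with 15 signature genes each (drawn from regulon-free genes) receive an
additive latent-abundance term; cell type 1's abundance is ρ = 0.6-linked to
the driver. All numbers are configurable; the defaults are one fixed choice of
a realistic regime, not fitted to anything.

What the generator does *not* emulate: platform/batch effects, probe-level
artifacts, mean–variance coupling, realistic tissue composition, symbol
aliasing, or nonlinear regulation (the linear-Gaussian activity→expression
link is an assumption). Passing tests therefore demonstrate correctness of the
algorithms under the model's assumptions, not performance on any particular
real dataset.

## Determinism and numerics

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from the single top-level seed by hashing the stage name
(stable across runs and platforms, < 2³¹). Reruns with the same config and
seed produce byte-identical outputs, verified by checksum in the manifest.
Tie handling is deterministic everywhere (ordinal ranks, stable sorts);
equality keeps the edge in DPI; p-values are capped into (0, 1]; BH-adjusted
values are clamped to be ≥ raw. Benchmarks and test problem sizes (e.g.
n_perm = 200 in recovery tests, 40 replicate null cohorts of 30 + 30) are the
package's own desk-scale choices, sized so the full suite runs in minutes.
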