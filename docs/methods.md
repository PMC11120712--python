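# Methods

`coresnp` mines a small, maximally trait-informative subset of SNPs (a
"core SNP" panel) from a genome-wide dosage matrix and one quantitative
trait. The workflow is a filter-then-wrap design: fast univariate filter
statistics rank all SNPs, and an incremental feature selection (IFS)
sweep finds, for each ranking and each prediction model, the smallest
top-*m* panel whose predictive accuracy is maximal. This document states
the models, conventions and numerical choices the implementation commits
to, and what the synthetic benchmark does and does not establish.

## Data model and preprocessing

**Dosage encoding.** Genotypes are counts of alternate alleles per
biallelic site: 0, 1 or 2. Missing calls are an explicit sentinel until
imputation; they are never silently treated as homozygous reference.
Phased and unphased genotype separators are equivalent. Internal
positions are 1-based (VCF convention); the BED-like export is 0-based
half-open.

**Imputation.** Missing calls are replaced by the per-SNP modal dosage
among observed calls, with ties resolved to the smaller dosage. Mode
imputation keeps the matrix integral, which matters for the MIC scorer
(dosage bins stay discrete). SNPs with no observed call at all are
dropped.

**Quartile discretization.** The continuous trait maps to three ordinal
levels by rank, not by value: after a stable sort (ties keep input
order), the lowest `floor(n/4)` samples become Level 1, the highest
`n − floor(3n/4)` become Level 3, the rest Level 2. Level proportions
are therefore exactly 25/50/25 whenever `n` is divisible by 4, even with
heavily tied trait values. Fewer than 4 samples is an error.

**Train/test split.** The hold-out size is `round(test_fraction · n)`
(default fraction 0.2, which reproduces a 2239/560 partition of 2799
samples). Stratified mode apportions the test count over levels by
largest remainder, so each level's share deviates from exact
proportionality by at most one sample. The partition is a pure function
of `(ids, fraction, seed, stratified)`.

**LD pruning.** Sliding windows of `window` SNPs (default 1000) advance
by `step` SNPs (default 100) within each chromosome; within a window,
while any kept pair has squared Pearson dosage correlation above the
threshold (default 0.1), one member is removed. The window unit is SNP
count, the common reading of the `1000 100 0.1` parameter triple without
a "kb" suffix; both interpretations are exposed through `PruneConfig`.
Because the external tool this emulates leaves the removal order
unspecified, a deterministic rule is fixed: offending pairs resolve in
decreasing r² order, and the removed member is the one with the larger
pre-imputation missing rate, ties going to the later position.
Zero-variance columns have r² = 0 by convention. One pass over the
windows suffices for the guarantee that no kept within-window pair
exceeds the threshold: removal is monotone, so a pair cleared in the
last window containing it stays cleared.

## Filter statistics

All three scorers are univariate: one SNP column against the target.
Ranks are assigned in decreasing score order with ties broken by column
order, making every ranking a pure function of its inputs.

**ANOVA F.** Categorical mode is the one-way ANOVA F over the trait
levels: `F = (SSB/(k−1)) / (SSW/(n−k))`. Quantitative mode is the
univariate regression F, `(n−2) r²/(1−r²)`. Degenerate conventions: a
constant feature scores 0; zero within-group (or residual) variance with
non-zero between-group variance scores `inf`, which sorts above every
finite score. For two classes the statistic equals the squared pooled
t statistic; the tests verify this identity against scipy.

**Fisher score.** `Σ_k n_k(μ_k−μ)² / (Σ_k n_k σ²_k + ε)` with population
(divide-by-`n_k`) within-class variances and `ε = 1e−12` guarding
perfectly separable features (their score is finite but ~1/ε, and still
ranks on top). The Fisher score is class-based by definition, so in the
quantitative task it is computed against the three quartile levels — the
minimal consistent reading of using a class-scatter statistic on a
continuous trait, exposed as configuration.

**MIC.** The maximal information coefficient: over all axis-parallel
grids with `nx·ny ≤ B(n)` and at least 2 bins per axis, the maximum of
binned mutual information normalised by `log2(min(nx, ny))`. The budget
is `B(n) = max(4, n^0.6)` — the literature's default exponent with a
floor that keeps a 2×2 grid admissible at tiny n. Two search strategies
share this definition:

* *Exhaustive*: every placement of grid lines between consecutive
  distinct sorted values is enumerated for every admissible shape. Exact
  by construction; feasible for n ≤ 60 (and guarded by a grid-count
  limit). This is the package's internal oracle.
* *Dynamic programming*: one axis is equipartitioned at distinct-value
  gaps nearest the equal-frequency targets; the other axis's cut points
  are optimised by a prefix DP (the objective `H(P) − H(P,Q)` is
  additive over bins), maximising over admissible shapes and both
  orientations. Candidate cut points are capped (default 64 per axis) to
  bound cost. Every grid the DP considers is a realizable grid, so the
  DP result never exceeds the exhaustive value.

`mic_score` dispatches automatically: exhaustive when `n ≤ 40`, where
enumeration is cheap and exact, DP otherwise. This makes the score exact
on small samples and a documented lower-bound approximation on large
ones. MIC is symmetric and invariant under strictly monotone transforms
of either variable (grid lines depend only on order), and for SNP
features the DP is cheap because a dosage axis has at most three
distinct values.

## Learners and evaluation

The four prediction models — gradient-boosted trees (xgboost), SVM (RBF
kernel, C = 1), k-nearest neighbours (Euclidean distance, default
k = 5) and random forest — are delegated to xgboost and scikit-learn
behind one facade with `fit`/`predict` and a seed; no hyperparameter
search is performed. The classification task predicts the three levels
directly. The regression task predicts the continuous trait; to report
the same accuracy scale, real-valued predictions *and* held-out true
values are binned at the 25th/75th percentiles of the *training* trait
values, so a perfect regressor scores accuracy 1 and no test information
leaks into the thresholds.

Metrics follow the standard confusion-matrix definitions: accuracy
`(TP+TN)/total`, recall `TP/(TP+FN)`, precision `TP/(TP+FP)`, F1 their
harmonic mean (0 when precision + recall = 0, and precision is 0 when
nothing is predicted positive). Binary tables use the larger label as
the positive class, exactly matching the two-class formulas; three-level
tables macro-average precision/recall/F1 over one-vs-rest classes, the
symmetric default when no class is privileged, with accuracy as the
trace fraction. Protocols: resubstitution, hold-out, or k-fold CV
(stratified for classification) returning fold-mean metrics, all
deterministic given seeds.

## Incremental feature selection

For a fixed ranking, nested subsets of the top `m = step, 2·step, …`
SNPs are each evaluated; the optimum is the *smallest* size attaining
the maximum accuracy, preferring compact panels at equal performance.
The default step is 10 SNPs. The grid crosses every scorer with every
learner (3 × 4 = 12 curves by default); rankings are computed from
training samples only under the hold-out protocol. Curve maxima are
selected on the same protocol they were traced with — no nested
cross-validation corrects the optimistic bias of picking the best point
on an observed curve, a known limitation of the IFS design.

## Panel comparison

Top-K id sets per scorer (defaults K = 300 and 1000), the seven Venn
regions of a three-method comparison computed by exact membership
enumeration, and a BED-like per-SNP position table for chromosome
distribution plots. Outputs are plain tables; figure rendering is left
to downstream tools.

## Synthetic data generator

The generator emulates a crop diversity panel at desk scale: per-SNP
minor-allele frequencies uniform on a configurable range (default
0.05–0.5), `Binomial(2, f_j)` dosages from two independent allele
draws, SNPs laid sequentially on 12 chromosomes at 1 kb spacing. LD
blocks, when requested, come from thresholding a latent first-order
autoregressive Gaussian per allele draw: adjacent latent correlation
`ld_rho` induces tunable adjacent-dosage r² while preserving each SNP's
marginal frequency. The trait is additive: `value = Σ β_j·dosage_j + E +
baseline`, with causal SNPs drawn without replacement, β defaulting to
standard-normal draws, and the noise rescaled so the realized-sample
variance ratio `Var(G)/Var(value)` equals the requested heritability
exactly — enforcing h² on the realized draw (not the theoretical
population) keeps definitional checks tight at moderate n. `h² = 0`
yields a trait independent of genotype. A location constant keeps
values positive on a days-to-heading-like scale. Everything is
bit-reproducible from the seed.

What this does **not** emulate: population structure and kinship,
dominance and epistasis, realistic allele-frequency spectra and
coalescent LD decay, genotyping-error correlation with MAF. Passing
tests therefore demonstrate that the machinery is correct and that
planted additive signal is recovered under clean conditions — not that
any particular accuracy level will transfer to a real diversity panel,
where structure confounding typically inflates filter scores.

## Benchmark problem sizes

The test suite and the acceptance script run on simulations of a few
hundred samples and up to 2000 SNPs: the recovery benchmark uses
500 × 2000 with 20 causal SNPs at h² = 0.6 (ANOVA top-200 recovery is
compared against the 99th percentile of a 200-draw random-ranking null),
and the grid demonstration prunes at window 200/step 20/r² 0.1 and
sweeps to 250 features in steps of 25 under a stratified 80/20 hold-out.
These sizes exercise every code path while keeping a full run in the
order of a minute; all of them are configuration, not limits.

## Known limitations

* Filter scorers are univariate: haplotype effects and interactions are
  invisible to them by design.
* The DP MIC is a lower bound off the exhaustive value when the optimal
  grid is not axis-equipartitioned; for genotype data (≤3 distinct
  dosage values on one axis) the gap is small in practice.
* IFS optima are optimistically biased estimates of panel performance
  (selection on the evaluation curve).
* No multiple-testing control is attached to scores; they are used for
  ranking only.
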