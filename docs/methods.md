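# Methods

## Graph encoding of interaction sources

An interaction source is a list of unordered gene pairs with optional
positive weights.  Ingestion drops self-pairs, and collapses duplicate pairs
either to presence/absence (`max`, the default: repeated evidence for the
same pair does not inflate its weight) or additively (`sum`, used when
several sources are pooled into one graph — pooling adds adjacencies).

The graph is always built over the *expression matrix's* gene order: source
pairs mentioning genes absent from the expression data are dropped, and
expression genes absent from the source become isolated nodes.  This keeps
the gene–gene similarity matrix aligned with the data columns by
construction.

**Isolated genes.** The design goal is to add information, never to discard
genes.  An isolated gene receives a unit degree entered in the degree matrix
`D` only.  Had the unit been added as a true self-loop edge (entering both
`W` and `D`), the Laplacian diagonal would cancel to zero and the gene's row
of `L⁺` would vanish — silently deleting the gene from every kernel.  With
the D-only convention, `L_kk = 1` and `G_kk = 1`: the gene participates in
patient similarity with exactly the standard inner-product weight, and its
off-diagonal similarities are zero ("zero patterns" in `G`).

**Pseudoinverse.** `G = L⁺` is computed by symmetric eigendecomposition;
eigenvalues below `rank_tolerance × λ_max` (default 10⁻¹⁰) are treated as
exact zeros, and tiny negative eigenvalues from round-off are clipped first.
`G` is the covariance of the commute-time embedding of the graph: its
entries grow with the number of connecting paths and shrink with their
length, so it acts as a similarity that sees *indirect* connections.  The
pseudoinverse zeroes each connected component's constant mode and weights
the remaining graph modes by 1/λ — low-frequency (smooth) patterns over the
network are amplified relative to high-frequency ones.  A normalized
Laplacian variant (`D^−1/2 L D^−1/2`) is available behind a flag; the
package makes no claim about which performs better.

## Preprocessing

* **Variance filter:** keep the `n_keep` (default 5000) genes with the
  largest sample variance (n−1 denominator); ties at the cutoff keep the
  earlier gene; input order is preserved.  The cap also keeps the p × p
  eigendecomposition tractable.
* **k-NN imputation** (default k = 15): genes missing in more than half the
  samples are dropped first.  A missing value of gene g in sample s is the
  weighted average of the k genes nearest to g — Euclidean distance over
  co-observed samples, weights 1/(d + 10⁻¹²) — among genes observed at s.
  The routine is written in-package because the common library
  implementations impute from nearest *samples* with a rescaled NaN metric,
  which is a different estimator.
* **Fold-safe z-scoring:** per-gene mean and sample sd are fitted on the
  training folds and the same constants are applied to the held-out folds.
  Constant training genes (sd = 0) are centered but not divided — the gene
  is uninformative either way, and this avoids manufacturing infinities.

## Kernels

Baseline `K = X Xᵀ`; adapted `K = X G Xᵀ` (symmetrized as `(K+Kᵀ)/2`
against round-off), PSD because `G` is.  Kernels are normalized by the
trace, `K̂ = K/trace(K)`; any global scale is immaterial downstream because
the regularization grid is re-selected per kernel, but a common scale keeps
per-source models comparable for combination.  At prediction time the
test-vs-train rows are divided by the *training* trace, so a single test
sample is embedded consistently without touching other test samples.

## Weighted LS-SVM

Primal: minimize ½‖w‖² + (γ/2) Σ ζᵢ eᵢ² subject to yᵢ(w·xᵢ + b) = 1 − eᵢ,
with class weights ζᵢ = N/(2N_P) for positives and N/(2N_N) for negatives,
equalizing the aggregate influence of the two classes under unbalance.  The
dual is one (N+1)-dimensional symmetric linear system with matrix
`[[0, yᵀ],[y, Ω + diag(1/(γζ))]]` and right-hand side `[0, 1_N]`, where
`Ω = yyᵀ ∘ K`; solutions are accepted only if the relative residual is
≤ 10⁻⁸.  Decision values are f(x) = Σ αᵢ yᵢ k(x, xᵢ) + b, classified
positive when strictly above 0.

**γ selection.** 40 log-spaced values spanning 10⁻⁴…10⁶ (endpoints exact).
Stratified internal 5-fold CV on the training folds; out-of-fold decision
values are *pooled* before computing AUC/BER/sensitivity/specificity —
pooling is more stable than per-fold averaging at the small per-fold counts
this protocol produces.  Selection: max AUC → min BER → max
(sensitivity+specificity) → smallest γ (the strongest regularization, as an
overfitting guard).  The model is then refit on all training folds at the
chosen γ.

## Combination rules

Combiners consume raw LS-SVM latent values (trace normalization already
puts sources on a common scale; no per-classifier standardization is
applied).  Mean and median need no training.  Weighted sums use the
internal-CV training AUC of each source as weight, normalized by Σw so the
output stays on the latent scale; the "scaled" variant divides by the
largest AUC, realizing the ]0,1] rescaling as max-normalization with the
best source at exactly 1.  The exhaustive rule scores every nonempty subset
with the unweighted mean and keeps the best training AUC (ties: fewer
members, then lexicographic).  Naive Bayes uses Gaussian class-conditionals
(the latent inputs are continuous); logistic regression carries a tiny
ridge (10⁻⁶); LDA computes the pooled-covariance discriminant direction
directly, adding a 10⁻⁸-scale ridge when the covariance is near-singular.
All combiners output larger-means-positive scores.

## Evaluation protocol

Each repeat draws outcome-stratified 10-folds by class-wise shuffled
round-robin with a running counter across classes, so both the per-fold
class proportions and the fold sizes differ by at most one.  Roles are
fixed: folds 1–5 (50%) train the per-source models and the γ search; folds
6–8 extend the combiner training data to 80% (combiners therefore see
in-sample scores on folds 1–5 and out-of-sample scores on folds 6–8 — the
optimism this introduces is part of the protocol); folds 9–10 (20%) are
untouched test data.  Per-gene normalization is fitted on folds 1–5 only.
Repeat r is seeded `master_seed + r`, and every model inside a repeat shares
the split and the internal-CV folds — consequently a source whose G-matrix
is the identity reproduces the baseline *bit for bit*, a reduction identity
the test suite asserts.

A failed repeat is logged and skipped; the run aborts if more than 10% of
repeats fail.

**Statistics.** Per dataset, per-repeat test AUCs are compared with the
one-sided paired t-test (zero-variance differences short-circuit to 0, 1 or
0.5 by sign; the overlap between repeats inflates type-I error, which is
why the cross-dataset test exists).  Across datasets, mean AUCs are compared
with the Wilcoxon signed-rank test: zero differences dropped, midranks for
ties, exact p by subset-sum enumeration of the full sign distribution for
n ≤ 15, and the tie-adjusted normal approximation (no continuity
correction) above; sidedness is an explicit argument.  Source scores per
dataset: sources beating the baseline mean AUC are ranked descending, the
best getting M points for M candidates, then M−1, ...; others 0; per-source
sums aggregate the table.  Classifier dependence is quantified by the
mutual information (base 2, in bits) between binarized predictions
(score > 0).

## Synthetic data

The generator reproduces the complementary-pathway scenario: parallel
routes through a pathway, with different patients dysregulating different
routes.

* **Pathway source.** Genes are partitioned into consecutive blocks
  (default: five pathways of 20 genes in a 1000-gene universe).  The default
  `branched` topology builds each pathway as two within-branch cliques (the
  two halves) joined by 2 bridge edges — two parallel routes sharing entry
  and exit points.  This topology is what makes the branch contrast a
  low-frequency mode of the pathway graph: `L⁺` weights it by 1/λ with λ
  small (bridges are few), amplifying exactly the signal direction the
  complementary dysregulation produces.  A `clique` topology (every
  within-pathway pair, the flat semantics of curated same-pathway gene
  lists) is available; note that a uniform clique has a flat non-null
  spectrum, so its `L⁺` can only remove the pathway-mean, not amplify the
  branch contrast.
* **Expression.** Background i.i.d. Normal(0, σ²), σ = 1.  Balanced labels
  (positive fraction 0.5, 120 samples).  Each positive patient, in each of
  the 2 informative pathways, dysregulates one uniformly chosen branch:
  the first branch is *repressed* by δ = 1.5 or the alternative branch is
  *activated* by δ — the two complementary trajectories.  Because only
  about half the positives move any given gene, single-gene t-statistics
  are attenuated relative to a design shifting all positives (asserted in
  the tests); the class signal lives in the within-pathway contrast, which
  the adapted kernel picks up and the plain inner product dilutes.
* **Null source.** Uniformly random gene pairs, count-matched to the
  pathway source, independent of the informative blocks — the negative
  control for source scoring.

Defaults were chosen so the full 50-repeat recovery experiment runs in
about a minute on one CPU while leaving a clear margin: under these
conditions the adapted kernel with the true source exceeds the baseline
mean test AUC by ≈ 0.08–0.16 depending on the seed, the true source
outranks the null source, and with δ = 0 all mean AUCs sit near 0.5.

**What the generator does not emulate:** platform noise models, probe
effects, correlated (pathway-level) background noise, overlapping pathway
membership, and hub-dominated degree distributions of real interactomes.
Passing recovery tests therefore demonstrate that the pipeline exploits
complementary-pathway structure when it is present in the stated form, not
that any particular real data set contains such structure.

## Numerical choices and degenerate inputs

* Rank tolerance 10⁻¹⁰ (relative) for the pseudoinverse; negative
  round-off eigenvalues clipped to zero.
* LS-SVM systems solved densely; singular or ill-conditioned systems raise,
  naming the γ value.
* AUC uses the midrank (Mann–Whitney) convention: ties count one half.
* Classification threshold fixed at 0 with strict inequality; a score of
  exactly 0 is negative.
* Single-class inputs are errors everywhere a class comparison is implied
  (training, AUC, threshold metrics, exhaustive/advanced combiners).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; two runs with the same configuration and seed
  write byte-identical summaries.

## Known limitations

* Dense p × p eigendecomposition limits the gene universe to a few thousand
  genes (the variance filter's job).
* Combining raw latent values assumes the trace normalization has made
  source scales comparable; sources with very different spectra may still
  dominate a mean.
* The per-dataset paired t-test inherits the repeat-overlap optimism of the
  protocol; cross-dataset Wilcoxon comparisons are the honest summary.
* The exhaustive combiner enumerates 2^m − 1 subsets and is meant for a
  handful of sources.
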