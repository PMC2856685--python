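# netkern

Interactome-weighted kernel classification for gene-expression outcome
prediction.

## The problem

Expression-based classifiers for cancer diagnosis and prognosis treat genes
as independent coordinates, yet patients with the same phenotype are often
genotypically different: the same pathway can be switched on through
*complementary* routes, with one patient repressing one branch and another
activating the alternative branch.  A plain inner product between two such
expression profiles is small, so sample-starved classifiers miss the shared
biology.  `netkern` injects prior knowledge about the interactome
(shared-pathway membership, protein–protein interactions, shared miRNA
targeting, ...) into the similarity measure itself, so that patients
dysregulating *linked* genes are recognized as similar.

## The method

1. **Graph prior.** Each interaction source is a list of gene pairs, turned
   into a weighted undirected graph over the expression matrix's gene order
   with adjacency `W`, degrees `D`, and Laplacian `L = D − W`.  Genes with no
   interaction keep a unit degree (entered in `D` only), so nothing is
   discarded.  The gene–gene similarity is the Moore–Penrose pseudoinverse
   `G = L⁺`, whose entries grow with the number and shortness of network
   paths between two genes (an optional normalized-Laplacian variant
   `D^−1/2 L D^−1/2` is available).

2. **Adapted kernel.** For patients × genes data `X` (5000 most-varying
   genes, per-gene z-scored with training-fold statistics), the baseline
   kernel `K = X Xᵀ` is replaced by the quadratic form `K = X G Xᵀ`,
   trace-normalized (`K̂ = K / trace(K)`) so kernels from different sources
   are comparable.

3. **Weighted LS-SVM.** Per source, a least-squares SVM with per-class error
   weights ζᵢ = N/(2N_P) or N/(2N_N) is trained by solving one linear system
   in `(b, α)`; the regularization γ is picked from a 40-point log grid
   (10⁻⁴…10⁶) by internal stratified 5-fold CV on pooled out-of-fold AUC
   (ties: lowest balanced error rate, then highest sensitivity+specificity,
   then smallest γ).

4. **Combination.** Per-source predictions are combined with fixed rules
   (mean, median), AUC-weighted sums (raw or rescaled to ]0,1]), an
   exhaustive subset search, and trained combiners (Gaussian naive Bayes,
   logistic regression, LDA).

5. **Evaluation.** Repeated (default 200×) stratified 10-fold protocol with
   fold roles 5/3/2: folds 1–5 train the LS-SVMs, folds 6–8 extend the
   combiner training data, folds 9–10 are the test set.  Models are compared
   per dataset by a one-sided paired t-test over per-repeat test AUCs and
   across datasets by the exact Wilcoxon signed-rank test; sources are
   ranked per dataset (best improving source gets M points, next M−1, ...,
   non-improving 0) and the scores summed across datasets.

A synthetic-data module generates the scenario the method targets: pathways
built as two parallel branch cliques joined by bridge edges, with each
positive patient repressing one branch or activating the alternative one,
plus matched random-pair null sources as negative controls.

## Worked example

```python
import netkern as nk

spec = nk.SyntheticSpec(seed=7)            # 120 patients x 1000 genes
X = nk.generate_complementary_expression(spec)

true_src = nk.generate_pathway_source(spec)       # within-pathway gene pairs
null_src = nk.generate_null_source(spec, seed=8)  # random-pair control

g_true = nk.gmatrix_for_source(true_src, X.gene_ids)
g_null = nk.gmatrix_for_source(null_src, X.gene_ids)

report = nk.run_protocol(
    X, {"pathways": g_true, "random": g_null},
    nk.RepeatConfig(n_repeats=20, master_seed=1, rules=("mean", "weighted")),
)
print(report.summary_frame().to_string(index=False))

scores = nk.score_sources(
    {"pathways": report.mean_auc("pathways"), "random": report.mean_auc("random")},
    report.mean_auc("baseline"))
print("source scores:", scores)
```

Output:

```
   model  mean_auc  std_auc  p_vs_baseline  neg_log10_p
baseline  0.836806 0.073060            NaN          NaN
pathways  0.984722 0.018387   5.858998e-10     9.232177
  random  0.767014 0.075047   9.999117e-01     0.000038
    mean  0.779514 0.088671   9.957723e-01     0.001840
weighted  0.779861 0.089362   9.953962e-01     0.002004
source scores: {'pathways': 2, 'random': 0}
```

The kernel weighted by the true pathway graph lifts the mean test AUC from
0.84 to 0.98 (one-sided paired t-test p ≈ 6e-10 over 20 repeated splits),
while the random-pair source hurts slightly and is scored 0; the informative
source receives the top score (2 of 2 candidate sources).  The combiners
average an informative and an uninformative source and land in between —
which is exactly why source selection precedes combination.

The same pipeline is available from the shell:

```sh
netkern simulate --out-dir sim/
netkern run --expr sim/expression.tsv --labels sim/labels.tsv \
    --sources sim/true_source.tsv --repeats 50 --seed 1 --out results/
netkern stats --report results/report.json
```

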