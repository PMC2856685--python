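"""Repeated 10-fold evaluation protocol, source scoring, and statistics.

Each repeat splits the samples into 10 outcome-stratified folds with fixed
roles: folds 1-5 train the per-source LS-SVMs (including the internal 5-fold
search for gamma), folds 6-8 extend the training material for the trained
combination rules, and folds 9-10 are the untouched test set.  Per-gene
normalization constants are fitted on folds 1-5 and applied to folds 6-10.
The split is redrawn ``n_repeats`` times (repeat r is seeded with
``master_seed + r``); all models within a repeat share the same split, so a
source whose G-matrix is the identity reproduces the baseline bit for bit.

Model comparison follows the protocol's two statistics: a one-sided paired
t-test across the per-repeat test AUCs of two models on one dataset, and the
Wilcoxon signed-rank test across the per-dataset mean AUCs of two models
(exact enumeration for n <= 15, tie-adjusted normal approximation above).
Sources are scored per dataset by ranking the sources that beat the baseline
(best gets M points for M candidate sources, next M-1, ...; non-improving
sources get 0) and summing the scores over datasets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combiners import ALL_RULES, PredictionBundle, apply_combiner, fit_combiner
from .graph_prior import GMatrix
from .kernels import KernelMatrix
from .lssvm import auc, decision_values, default_gamma_grid, select_gamma, stratified_assignment
from .preprocess import ExpressionMatrix, zscore_train_apply

logger = logging.getLogger(__name__)

__all__ = [
    "SplitScheme",
    "RepeatConfig",
    "EvaluationReport",
    "MIEstimate",
    "BASE_FOLDS",
    "COMBINER_FOLDS",
    "TEST_FOLDS",
    "stratified_folds",
    "run_protocol",
    "score_sources",
    "aggregate_scores",
    "paired_t_one_sided",
    "wilcoxon_signed_rank",
    "binarize_predictions",
    "mutual_information_binary",
    "mutual_information_from_joint",
]

#: fold roles of the 10-fold scheme (1-based fold ids)
BASE_FOLDS = (1, 2, 3, 4, 5)
COMBINER_FOLDS = (6, 7, 8)
TEST_FOLDS = (9, 10)


@dataclass
class SplitScheme:
    """Per-sample fold ids 1..k plus the 5/3/2 role partition."""

    fold_assignment: np.ndarray
    k: int = 10

    def indices(self, folds: Sequence[int]) -> np.ndarray:
        return np.where(np.isin(self.fold_assignment, folds))[0]

    @property
    def base_train(self) -> np.ndarray:
        return self.indices(BASE_FOLDS)

    @property
    def combiner_train(self) -> np.ndarray:
        return self.indices(BASE_FOLDS + COMBINER_FOLDS)

    @property
    def test(self) -> np.ndarray:
        return self.indices(TEST_FOLDS)


def stratified_folds(y, k: int = 10, seed: int = 0) -> SplitScheme:
    """Outcome-stratified folds by class-wise shuffled round-robin.

    Deterministic given the seed.  A class with fewer than k members still
    yields a valid (best-effort) assignment, with a warning.
    """
    y = np.asarray(y)
    for cls in (1, -1):
        if 0 < (y == cls).sum() < k:
            logger.warning("class %+d has fewer than %d members; stratification "
                           "is best-effort", cls, k)
    return SplitScheme(fold_assignment=stratified_assignment(y, k, seed) + 1, k=k)


@dataclass
class RepeatConfig:
    n_repeats: int = 200
    master_seed: int = 0
    gamma_grid: np.ndarray | None = None
    rules: tuple[str, ...] = ALL_RULES
    n_inner_folds: int = 5
    max_failed_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.gamma_grid is None:
            self.gamma_grid = default_gamma_grid()
        unknown = set(self.rules) - set(ALL_RULES)
        if unknown:
            raise ValueError(f"unknown combination rules: {sorted(unknown)}")


@dataclass
class EvaluationReport:
    """Per-repeat test AUCs for the baseline, every source and every combiner."""

    model_names: list[str]
    auc_matrix: np.ndarray  # (n_repeats, n_models), NaN for failed repeats
    master_seed: int
    n_repeats: int
    failed_repeats: list[int] = field(default_factory=list)

    def auc_vector(self, name: str) -> np.ndarray:
        return self.auc_matrix[:, self.model_names.index(name)]

    def mean_auc(self, name: str) -> float:
        return float(np.nanmean(self.auc_vector(name)))

    def std_auc(self, name: str) -> float:
        return float(np.nanstd(self.auc_vector(name), ddof=1))

    def p_vs_baseline(self, name: str) -> float:
        a, b = self.auc_vector(name), self.auc_vector("baseline")
        ok = ~np.isnan(a) & ~np.isnan(b)
        return paired_t_one_sided(a[ok], b[ok])

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.model_names:
            p = np.nan if name == "baseline" else self.p_vs_baseline(name)
            rows.append({
                "model": name,
                "mean_auc": self.mean_auc(name),
                "std_auc": self.std_auc(name),
                "p_vs_baseline": p,
                "neg_log10_p": np.nan if np.isnan(p) else (
                    np.inf if p == 0 else -np.log10(p)),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "model_names": self.model_names,
            "auc_matrix": self.auc_matrix.tolist(),
            "master_seed": self.master_seed,
            "n_repeats": self.n_repeats,
            "failed_repeats": self.failed_repeats,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(model_names=list(d["model_names"]),
                   auc_matrix=np.asarray(d["auc_matrix"], dtype=float),
                   master_seed=int(d["master_seed"]),
                   n_repeats=int(d["n_repeats"]),
                   failed_repeats=list(d.get("failed_repeats", [])))


def _normalized_kernel_full(Xn: np.ndarray, G: GMatrix | None,
                            train_idx: np.ndarray) -> np.ndarray:
    """Full N x N kernel on normalized data, scaled by the train-block trace."""
    K = Xn @ Xn.T if G is None else (Xn @ G.G) @ Xn.T
    K = 0.5 * (K + K.T)
    tr = float(np.trace(K[np.ix_(train_idx, train_idx)]))
    if tr <= 0:
        raise ValueError("degenerate kernel: training trace <= 0")
    return K / tr


def run_protocol(X: ExpressionMatrix, sources: Mapping[str, GMatrix],
                 config: RepeatConfig | None = None) -> EvaluationReport:
    """Run the repeated 10-fold protocol for the baseline, each source and
    each requested combination rule.

    ``X`` must carry labels and be fully preprocessed (complete, filtered).
    All G-matrices must share X's gene order.  Combiners operate on the
    per-source models only and are skipped when fewer than one source is
    given; with a single source they are still computed (each rule then
    returns a monotone transform of that source's scores).
    """
    config = config or RepeatConfig()
    if X.labels is None:
        raise ValueError("expression matrix must carry labels")
    y = np.asarray(X.labels, dtype=float)
    for name, g in sources.items():
        if g.genes != list(X.gene_ids):
            raise ValueError(f"G-matrix {name!r} gene order does not match expression")

    source_names = list(sources)
    combiner_names = list(config.rules) if source_names else []
    model_names = ["baseline"] + source_names + combiner_names
    A = np.full((config.n_repeats, len(model_names)), np.nan)
    failed: list[int] = []

    for r in range(config.n_repeats):
        seed_r = config.master_seed + r
        try:
            A[r] = _one_repeat(X.values, y, sources, config, seed_r,
                               source_names, combiner_names)
        except Exception as exc:  # noqa: BLE001 - a repeat may abort, run survives
            logger.warning("repeat %d failed: %s", r, exc)
            failed.append(r)
        if len(failed) > config.max_failed_fraction * config.n_repeats:
            raise RuntimeError(
                f"{len(failed)} of {config.n_repeats} repeats failed; aborting")

    return EvaluationReport(model_names=model_names, auc_matrix=A,
                            master_seed=config.master_seed,
                            n_repeats=config.n_repeats, failed_repeats=failed)


def _one_repeat(Xv: np.ndarray, y: np.ndarray, sources: Mapping[str, GMatrix],
                config: RepeatConfig, seed_r: int, source_names: list[str],
                combiner_names: list[str]) -> np.ndarray:
    scheme = stratified_folds(y, 10, seed_r)
    tr = scheme.base_train
    rest = scheme.indices(COMBINER_FOLDS + TEST_FOLDS)
    comb = scheme.combiner_train
    te = scheme.test

    Xn = np.empty_like(Xv)
    Xn[tr], Xn[rest] = zscore_train_apply(Xv[tr], Xv[rest])

    out = np.empty(1 + len(source_names) + len(combiner_names))
    score_cols: dict[str, np.ndarray] = {}
    train_aucs: dict[str, float] = {}
    for mi, (name, G) in enumerate([("baseline", None)]
                                   + [(n, sources[n]) for n in source_names]):
        K = _normalized_kernel_full(Xn, G, tr)
        sel = select_gamma(K[np.ix_(tr, tr)], y[tr], grid=config.gamma_grid,
                           n_folds=config.n_inner_folds, seed=seed_r)
        f_all = decision_values(sel.model, K[:, tr])
        out[mi] = auc(f_all[te], y[te])
        if name != "baseline":
            score_cols[name] = f_all
            train_aucs[name] = sel.chosen_cv_auc

    for ci, rule in enumerate(combiner_names):
        F = np.column_stack([score_cols[n] for n in source_names])
        fit_bundle = PredictionBundle(source_names, F[comb], training_auc=train_aucs)
        model = fit_combiner(fit_bundle, rule, y_train=y[comb])
        test_bundle = PredictionBundle(source_names, F[te], training_auc=train_aucs)
        out[1 + len(source_names) + ci] = auc(apply_combiner(model, test_bundle), y[te])
    return out


def score_sources(mean_auc_per_source: Mapping[str, float],
                  baseline_mean_auc: float, M: int | None = None) -> dict[str, int]:
    """Rank-based per-dataset scores: the best source beating the baseline
    gets M points, the next M-1, ...; sources not beating it get 0.

    ``M`` defaults to the number of candidate sources.  Ties in mean AUC are
    broken by source name for determinism.
    """
    names = list(mean_auc_per_source)
    if M is None:
        M = len(names)
    if M < len(names):
        raise ValueError("M must be at least the number of sources scored")
    beating = sorted((n for n in names if mean_auc_per_source[n] > baseline_mean_auc),
                     key=lambda n: (-mean_auc_per_source[n], n))
    scores = {n: 0 for n in names}
    for rank, n in enumerate(beating, start=1):
        scores[n] = M - rank + 1
    return scores


def aggregate_scores(table: pd.DataFrame) -> pd.Series:
    """Column sums of a datasets x sources score table."""
    df = pd.DataFrame(table)
    return df.sum(axis=0)


def paired_t_one_sided(auc_a, auc_b) -> float:
    """One-sided paired t-test p-value for mean(a) > mean(b).

    Zero-variance differences short-circuit to 0, 1 or 0.5 by the sign of the
    common difference (logged).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length vectors (n >= 2)")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        logger.info("paired t-test: zero-variance differences")
        if d.mean() > 0:
            return 0.0
        if d.mean() < 0:
            return 1.0
        return 0.5
    return float(stats.ttest_rel(a, b, alternative="greater").pvalue)


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), ranks


def _exact_signed_rank_cdf(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of W+ over all sign vectors by subset-sum convolution.

    Works on doubled ranks so midranks (.5 steps) stay integral.  Returns the
    count vector over W+*2 = 0..sum(2r) and the total 2^n.
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        counts[r:] += counts[:counts.size - r].copy()
    return counts, int(2 ** len(ranks))


def wilcoxon_signed_rank(a, b, sided: str = "two-sided", method: str = "auto") -> float:
    """Wilcoxon signed-rank test p-value on paired vectors.

    Zero differences are dropped (all zero -> p = 1); tied absolute
    differences get midranks.  ``method='exact'`` enumerates the full sign
    distribution (default for n <= 15); ``'approx'`` uses the tie-adjusted
    normal approximation without continuity correction (default above).
    ``sided`` is 'two-sided' or 'greater' (median of a-b positive).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if sided not in ("two-sided", "greater"):
        raise ValueError("sided must be 'two-sided' or 'greater'")
    if method == "auto":
        method = "exact" if d.size <= 15 else "approx"

    w_plus, ranks = _signed_rank_statistic(d)
    if method == "exact":
        counts, denom = _exact_signed_rank_cdf(ranks)
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / denom
        p_le = counts[:w2 + 1].sum() / denom
        if sided == "greater":
            return float(p_ge)
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    if method != "approx":
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    mean = ranks.sum() / 2.0
    sd = np.sqrt(np.sum(ranks ** 2) / 4.0)
    z = (w_plus - mean) / sd
    if sided == "greater":
        return float(stats.norm.sf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


def binarize_predictions(scores) -> np.ndarray:
    """1 iff the latent score is strictly positive, else 0."""
    return (np.asarray(scores, dtype=float) > 0).astype(int)


@dataclass
class MIEstimate:
    value: float  # bits
    joint: np.ndarray  # 2x2 joint probability table

    def __post_init__(self) -> None:
        if self.value < 0:
            # tiny negatives can only come from round-off
            self.value = max(self.value, 0.0)


def mutual_information_from_joint(R) -> MIEstimate:
    """Mutual information (bits) of a 2x2 joint probability table."""
    R = np.asarray(R, dtype=float)
    if R.shape != (2, 2) or (R < 0).any() or not np.isclose(R.sum(), 1.0):
        raise ValueError("joint must be a 2x2 probability table summing to 1")
    P = R.sum(axis=1)
    Q = R.sum(axis=0)
    val = 0.0
    for i in range(2):
        for j in range(2):
            if R[i, j] > 0:
                val += R[i, j] * np.log2(R[i, j] / (P[i] * Q[j]))
    return MIEstimate(value=float(val), joint=R)


def mutual_information_binary(x, y) -> MIEstimate:
    """Mutual information (bits) between two binary prediction vectors."""
    x = np.asarray(x).astype(int)
    y = np.asarray(y).astype(int)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("binary MI needs two nonempty equal-length vectors")
    R = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            R[i, j] = np.mean((x == i) & (y == j))
    return mutual_information_from_joint(R)
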