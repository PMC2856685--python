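"""Second-level combination of per-source classifier predictions.

Each interactome source yields one LS-SVM whose latent decision values are
combined across sources: fixed rules (mean, median), trained weighted sums
(weights = training AUCs, raw or rescaled so the best source gets weight 1),
an exhaustive search over unweighted subsets, and three trained models --
Gaussian naive Bayes, logistic regression and linear discriminant analysis.
Every combiner obeys the orientation contract: larger output means the
positive class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB

from .lssvm import auc

__all__ = [
    "PredictionBundle",
    "CombinerModel",
    "FIXED_RULES",
    "TRAINED_RULES",
    "ADVANCED_RULES",
    "ALL_RULES",
    "combine_fixed",
    "fit_weighted",
    "fit_exhaustive",
    "fit_advanced",
    "fit_combiner",
    "apply_combiner",
]

FIXED_RULES = ("mean", "median")
TRAINED_RULES = ("weighted", "scaled_weighted", "exhaustive")
ADVANCED_RULES = ("nb", "lr", "lda")
ALL_RULES = FIXED_RULES + TRAINED_RULES + ADVANCED_RULES


@dataclass
class PredictionBundle:
    """Latent scores of several classifiers on the same samples.

    ``score_matrix`` is (n_samples, n_classifiers); ``training_auc`` maps
    classifier name to its training AUC (needed by the weighted rules).
    """

    classifier_names: list[str]
    score_matrix: np.ndarray
    training_auc: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        self.score_matrix = np.atleast_2d(np.asarray(self.score_matrix, dtype=float))
        if self.score_matrix.shape[1] != len(self.classifier_names):
            raise ValueError("score_matrix column count != number of classifier names")
        if np.isnan(self.score_matrix).any():
            raise ValueError("missing scores in prediction bundle")
        if self.training_auc is not None:
            for name in self.classifier_names:
                if name not in self.training_auc:
                    raise ValueError(f"training AUC missing for classifier {name!r}")
                a = self.training_auc[name]
                if not 0.0 <= a <= 1.0:
                    raise ValueError(f"training AUC for {name!r} out of [0,1]: {a}")

    @property
    def n_classifiers(self) -> int:
        return len(self.classifier_names)

    def column(self, name: str) -> np.ndarray:
        return self.score_matrix[:, self.classifier_names.index(name)]

    def subset(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.classifier_names.index(n) for n in names]
        return self.score_matrix[:, idx]


@dataclass
class CombinerModel:
    kind: str
    classifier_names: list[str]
    weights: dict[str, float] | None = None          # weighted kinds
    subset: tuple[str, ...] | None = None            # exhaustive
    fitted: object = None                            # nb / lr estimator
    lda_direction: np.ndarray | None = None
    lda_intercept: float = 0.0
    subset_aucs: dict[tuple[str, ...], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ALL_RULES:
            raise ValueError(f"unknown combiner kind {self.kind!r}")
        if self.kind in ("weighted", "scaled_weighted"):
            if not self.weights:
                raise ValueError("weighted combiner needs weights")
            for name, w in self.weights.items():
                if not np.isfinite(w) or w <= 0:
                    raise ValueError(f"weight for {name!r} must be positive finite")
        if self.kind == "exhaustive" and not self.subset:
            raise ValueError("exhaustive combiner needs a nonempty subset")


def combine_fixed(bundle: PredictionBundle, rule: str) -> np.ndarray:
    """Per-sample mean or median of the classifier scores."""
    if bundle.n_classifiers == 0:
        raise ValueError("empty prediction bundle")
    if rule == "mean":
        return bundle.score_matrix.mean(axis=1)
    if rule == "median":
        return np.median(bundle.score_matrix, axis=1)
    raise ValueError(f"unknown fixed rule {rule!r}")


def fit_weighted(bundle: PredictionBundle, scaled: bool = False) -> CombinerModel:
    """Weighted sum with weights = training AUCs.

    ``scaled=True`` divides all weights by the largest AUC, mapping them into
    the half-open interval ]0,1] with the best source at exactly 1.
    """
    if bundle.training_auc is None:
        raise ValueError("weighted combiner requires training AUCs")
    w = {n: float(bundle.training_auc[n]) for n in bundle.classifier_names}
    if scaled:
        m = max(w.values())
        if m <= 0:
            raise ValueError("cannot scale: all training AUCs are zero")
        w = {n: v / m for n, v in w.items()}
    return CombinerModel(kind="scaled_weighted" if scaled else "weighted",
                         classifier_names=list(bundle.classifier_names), weights=w)


def fit_exhaustive(bundle: PredictionBundle, y_train) -> CombinerModel:
    """Best unweighted (mean-rule) subset of classifiers by training AUC.

    All 2^m - 1 nonempty subsets are scored; ties prefer fewer members, then
    lexicographic name order.
    """
    y = np.asarray(y_train, dtype=float)
    if len(np.unique(y[np.isfinite(y)])) < 2:
        raise ValueError("exhaustive combiner needs both classes in training labels")
    names = sorted(bundle.classifier_names)
    scored: dict[tuple[str, ...], float] = {}
    for r in range(1, len(names) + 1):
        for comb in itertools.combinations(names, r):
            scored[comb] = auc(bundle.subset(comb).mean(axis=1), y)
    best = min(scored, key=lambda s: (-scored[s], len(s), s))
    return CombinerModel(kind="exhaustive",
                         classifier_names=list(bundle.classifier_names),
                         subset=best, subset_aucs=scored)


def _check_class_counts(y: np.ndarray) -> None:
    n_pos = int((y > 0).sum())
    n_neg = int((y <= 0).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("advanced combiners need at least 2 samples per class")


def fit_advanced(bundle: PredictionBundle, y_train, kind: str) -> CombinerModel:
    """Fit naive Bayes ('nb'), logistic regression ('lr') or LDA ('lda').

    nb: Gaussian class-conditionals, output = posterior probability of the
    positive class.  lr: maximum likelihood with a tiny ridge (1e-6), output
    = fitted probability.  lda: pooled-covariance discriminant direction
    (ridge 1e-8 * mean diagonal added when near-singular), output = projection
    oriented so larger means positive.
    """
    y = np.asarray(y_train, dtype=float)
    _check_class_counts(y)
    F = bundle.score_matrix
    if kind == "nb":
        est = GaussianNB().fit(F, y)
        return CombinerModel(kind="nb", classifier_names=list(bundle.classifier_names),
                             fitted=est)
    if kind == "lr":
        est = LogisticRegression(C=1e6, solver="lbfgs", max_iter=2000).fit(F, y)
        return CombinerModel(kind="lr", classifier_names=list(bundle.classifier_names),
                             fitted=est)
    if kind == "lda":
        pos, neg = F[y > 0], F[y <= 0]
        if np.any(F.std(axis=0) == 0):
            raise ValueError("constant feature: LDA is degenerate")
        mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
        Sp = np.cov(pos, rowvar=False, ddof=1) * (len(pos) - 1)
        Sn = np.cov(neg, rowvar=False, ddof=1) * (len(neg) - 1)
        S = np.atleast_2d((Sp + Sn) / (len(F) - 2))
        if np.linalg.cond(S) > 1e12:
            S = S + 1e-8 * np.mean(np.diag(S)) * np.eye(S.shape[0])
        w = np.linalg.solve(S, mu_p - mu_n)
        # orient: positive-class mean projects higher by construction, keep it
        b = -0.5 * float(w @ (mu_p + mu_n))
        return CombinerModel(kind="lda", classifier_names=list(bundle.classifier_names),
                             lda_direction=w, lda_intercept=b)
    raise ValueError(f"unknown advanced combiner {kind!r}")


def fit_combiner(bundle: PredictionBundle, rule: str, y_train=None) -> CombinerModel:
    """Fit (or wrap) any rule by name; fixed rules need no labels."""
    if rule in FIXED_RULES:
        return CombinerModel(kind=rule, classifier_names=list(bundle.classifier_names))
    if rule == "weighted":
        return fit_weighted(bundle, scaled=False)
    if rule == "scaled_weighted":
        return fit_weighted(bundle, scaled=True)
    if y_train is None:
        raise ValueError(f"rule {rule!r} requires training labels")
    if rule == "exhaustive":
        return fit_exhaustive(bundle, y_train)
    return fit_advanced(bundle, y_train, rule)


def apply_combiner(model: CombinerModel, bundle: PredictionBundle) -> np.ndarray:
    """Combined scores under the larger-means-positive orientation contract."""
    if set(bundle.classifier_names) != set(model.classifier_names):
        raise ValueError("bundle classifiers do not match the combiner model")
    if model.kind in FIXED_RULES:
        return combine_fixed(bundle, model.kind)
    if model.kind in ("weighted", "scaled_weighted"):
        w = np.array([model.weights[n] for n in bundle.classifier_names])
        return bundle.score_matrix @ w / w.sum()
    if model.kind == "exhaustive":
        return bundle.subset(model.subset).mean(axis=1)
    F = bundle.subset(model.classifier_names)
    if model.kind in ("nb", "lr"):
        proba = model.fitted.predict_proba(F)
        pos_col = int(np.where(model.fitted.classes_ > 0)[0][0])
        return proba[:, pos_col]
    if model.kind == "lda":
        return F @ model.lda_direction + model.lda_intercept
    raise AssertionError(model.kind)
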