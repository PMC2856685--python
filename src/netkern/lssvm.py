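"""Weighted least-squares SVM: dual training, prediction, model selection.

The weighted LS-SVM minimizes (1/2)||w||^2 + (gamma/2) sum_i zeta_i e_i^2
subject to y_i (w . phi(x_i) + b) = 1 - e_i, with per-class error weights
zeta that equalize the aggregate influence of positives and negatives:

    zeta_i = N / (2 N_P)  for positives,   N / (2 N_N)  for negatives.

The dual is one symmetric linear system of size N+1,

    [ 0   y^T          ] [ b     ]   [ 0   ]
    [ y   Omega + V    ] [ alpha ] = [ 1_N ],

with Omega_ij = y_i y_j K_ij and V = diag(1 / (gamma zeta_i)); the decision
value of a new sample is f(x) = sum_i alpha_i y_i K(x, x_i) + b.

The regularization constant gamma is picked from a 40-point logarithmic grid
spanning 1e-4..1e6 by stratified internal cross-validation; pooled
out-of-fold decision values are scored by AUC, ties broken by balanced error
rate, then sensitivity + specificity, then the smaller gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .kernels import CrossKernel, KernelMatrix

__all__ = [
    "LSSVMModel",
    "ModelSelectionResult",
    "default_gamma_grid",
    "train_weighted_lssvm",
    "decision_values",
    "auc",
    "threshold_metrics",
    "select_gamma",
    "stratified_assignment",
]


def default_gamma_grid(n: int = 40, low: float = 1e-4, high: float = 1e6) -> np.ndarray:
    """Log-spaced regularization grid with exact endpoints."""
    grid = np.logspace(np.log10(low), np.log10(high), n)
    grid[0], grid[-1] = low, high
    return grid


@dataclass
class LSSVMModel:
    alpha: np.ndarray
    b: float
    gamma: float
    zeta_pos: float
    zeta_neg: float
    y_train: np.ndarray
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        # dual feasibility and class-balancing identity
        if abs(float(self.y_train @ self.alpha)) > 1e-8 * max(1.0, np.abs(self.alpha).sum()):
            raise ValueError("dual feasibility y^T alpha = 0 violated")
        assert np.isclose(self.zeta_pos * self.n_pos, self.zeta_neg * self.n_neg)


@dataclass
class ModelSelectionResult:
    chosen_gamma: float
    model: LSSVMModel
    grid: np.ndarray
    cv_auc: np.ndarray
    cv_ber: np.ndarray
    cv_sensitivity: np.ndarray
    cv_specificity: np.ndarray
    chosen_index: int = 0

    @property
    def chosen_cv_auc(self) -> float:
        return float(self.cv_auc[self.chosen_index])


def _kernel_array(K) -> np.ndarray:
    return K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def class_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights zeta_i = N/(2 N_P) or N/(2 N_N)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    n_pos = int((y > 0).sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    return np.where(y > 0, n / (2.0 * n_pos), n / (2.0 * n_neg))


def train_weighted_lssvm(K_train, y, gamma: float) -> LSSVMModel:
    """Solve the (N+1)-dimensional dual system for one value of gamma."""
    K = _kernel_array(K_train)
    y = np.asarray(y, dtype=float)
    n = y.size
    if K.shape != (n, n):
        raise ValueError("training kernel must be square and aligned with y")
    zeta = class_weights(y)
    if gamma <= 0:
        raise ValueError("gamma must be positive")

    A = np.empty((n + 1, n + 1))
    A[0, 0] = 0.0
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = np.outer(y, y) * K + np.diag(1.0 / (gamma * zeta))
    rhs = np.concatenate(([0.0], np.ones(n)))
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular LS-SVM system at gamma={gamma:g}") from exc
    resid = np.linalg.norm(A @ sol - rhs) / np.linalg.norm(rhs)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"ill-conditioned LS-SVM system at gamma={gamma:g} "
            f"(relative residual {resid:.2e})")

    n_pos = int((y > 0).sum())
    n_neg = n - n_pos
    return LSSVMModel(alpha=sol[1:], b=float(sol[0]), gamma=float(gamma),
                      zeta_pos=n / (2.0 * n_pos), zeta_neg=n / (2.0 * n_neg),
                      y_train=y, n_pos=n_pos, n_neg=n_neg)


def decision_values(model: LSSVMModel, k_rows) -> np.ndarray:
    """Latent scores f(x) = sum_i alpha_i y_i k(x, x_i) + b (larger = positive)."""
    rows = k_rows.rows if isinstance(k_rows, CrossKernel) else np.asarray(k_rows, dtype=float)
    rows = np.atleast_2d(rows)
    if rows.shape[1] != model.alpha.size:
        raise ValueError("kernel rows are not aligned with the training samples")
    return rows @ (model.alpha * model.y_train) + model.b


def auc(scores, y) -> float:
    """Area under the ROC curve by the midrank (Mann-Whitney) formula.

    Equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = y > 0
    n_pos = int(pos.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def threshold_metrics(scores, y, threshold: float = 0.0) -> tuple[float, float, float]:
    """(balanced error rate, sensitivity, specificity) at a fixed cut-off.

    A sample is predicted positive iff its score is strictly above the
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    pos = y > 0
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("threshold metrics need both classes")
    pred_pos = scores > threshold
    sens = float((pred_pos & pos).sum() / pos.sum())
    spec = float((~pred_pos & neg).sum() / neg.sum())
    return 1.0 - (sens + spec) / 2.0, sens, spec


def stratified_assignment(y, k: int, seed: int) -> np.ndarray:
    """Fold indices 0..k-1 by class-wise shuffled round-robin.

    Deterministic given the seed; per-fold class counts differ by at most one
    from exact proportionality.
    """
    y = np.asarray(y)
    if k > y.size:
        raise ValueError(f"cannot make {k} folds from {y.size} samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    counter = 0  # carried across classes so fold sizes also balance
    for cls in (1, -1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        folds[idx] = (counter + np.arange(idx.size)) % k
        counter += idx.size
    return folds


def select_gamma(K, y, grid: np.ndarray | None = None, n_folds: int = 5,
                 seed: int = 0) -> ModelSelectionResult:
    """Pick gamma by stratified internal CV, then refit on all provided data.

    For each grid value the out-of-fold decision values are pooled and scored
    once (AUC, BER, sensitivity, specificity).  Selection order: highest AUC,
    then lowest BER, then highest sensitivity + specificity, then the
    smallest gamma.
    """
    if grid is None:
        grid = default_gamma_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("gamma grid is empty")
    K = _kernel_array(K)
    y = np.asarray(y, dtype=float)
    folds = stratified_assignment(y, n_folds, seed)

    # cache per-fold subkernels and index sets
    splits = []
    for f in range(n_folds):
        te = np.where(folds == f)[0]
        tr = np.where(folds != f)[0]
        if te.size and len(np.unique(y[tr])) == 2:
            splits.append((tr, te))

    n = y.size
    cv_auc = np.empty(grid.size)
    cv_ber = np.empty(grid.size)
    cv_sens = np.empty(grid.size)
    cv_spec = np.empty(grid.size)
    for gi, g in enumerate(grid):
        pooled = np.empty(n)
        pooled.fill(np.nan)
        for tr, te in splits:
            m = train_weighted_lssvm(K[np.ix_(tr, tr)], y[tr], g)
            pooled[te] = decision_values(m, K[np.ix_(te, tr)])
        mask = ~np.isnan(pooled)
        cv_auc[gi] = auc(pooled[mask], y[mask])
        cv_ber[gi], cv_sens[gi], cv_spec[gi] = threshold_metrics(pooled[mask], y[mask])

    order = sorted(
        range(grid.size),
        key=lambda i: (-cv_auc[i], cv_ber[i], -(cv_sens[i] + cv_spec[i]), grid[i]),
    )
    best = order[0]
    model = train_weighted_lssvm(K, y, grid[best])
    return ModelSelectionResult(
        chosen_gamma=float(grid[best]), model=model, grid=grid,
        cv_auc=cv_auc, cv_ber=cv_ber, cv_sensitivity=cv_sens,
        cv_specificity=cv_spec, chosen_index=best,
    )
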