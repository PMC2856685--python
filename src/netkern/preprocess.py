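"""Expression-matrix container, gene filtering, imputation and normalization.

All preprocessing that may leak information across samples is split into a
fit-on-training / apply-to-held-out pair (:func:`zscore_train_apply`), so the
repeated cross-validation protocol can normalize folds 1-5 and carry the same
per-gene constants onto folds 6-10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "read_labels",
    "variance_filter",
    "knn_impute",
    "zscore_train_apply",
    "ImputationError",
]


class ImputationError(ValueError):
    """A missing value could not be imputed (no eligible neighbor gene)."""


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with optional binary outcome labels.

    ``values`` is an (N, p) float array (NaN marks missing entries),
    ``labels`` an optional length-N vector in {-1, +1}.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x genes array")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match values")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length does not match values")
        if len(set(self.gene_ids)) != p:
            raise ValueError("gene_ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match number of samples")
            bad = set(np.unique(self.labels)) - {-1, 1}
            if bad:
                raise ValueError(f"labels must be in {{-1,+1}}, found {sorted(bad)}")
            if n >= 2 and len(np.unique(self.labels)) < 2:
                logger.warning("expression matrix labels contain a single class")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, idx: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in np.atleast_1d(idx)],
            gene_ids=list(self.gene_ids),
            labels=None if self.labels is None else self.labels[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def read_expression(
    path: str,
    transposed: bool = False,
    label_column: str | None = None,
    labels_path: str | None = None,
    sep: str = "\t",
) -> ExpressionMatrix:
    """Read delimited expression text: samples x genes with a gene-id header
    row and sample ids in the first column ("NA"/empty = missing).

    ``transposed=True`` reads genes x samples files.  Labels come either from
    a named column of the table or from a separate two-column file.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    if transposed:
        df = df.T
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = df[label_column].to_numpy(dtype=int)
        df = df.drop(columns=[label_column])
    X = ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        labels=labels,
    )
    if labels_path is not None:
        lab = read_labels(labels_path)
        X.labels = np.asarray([lab[s] for s in X.sample_ids])
    return X


def read_labels(path: str, sep: str = "\t") -> dict[str, int]:
    """Two-column sample-id / label file; labels coerced to {-1,+1}."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    out: dict[str, int] = {}
    for _, row in df.iterrows():
        val = int(row.iloc[1])
        if val == 0:
            val = -1
        if val not in (-1, 1):
            raise ValueError(f"label {row.iloc[1]} for sample {row.iloc[0]} not binary")
        out[str(row.iloc[0])] = val
    return out


def variance_filter(X: ExpressionMatrix, n_keep: int = 5000) -> ExpressionMatrix:
    """Keep the ``n_keep`` genes with the largest sample variance (ddof=1).

    Gene order of the input is preserved; ties at the cutoff are broken in
    favor of earlier input genes (stable sort).  ``n_keep >= p`` is a no-op.
    """
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    if np.isnan(X.values).any():
        raise ValueError("variance_filter requires a complete matrix (impute first)")
    p = X.n_genes
    if n_keep >= p:
        return X
    var = X.values.var(axis=0, ddof=1)
    chosen = np.sort(np.argsort(-var, kind="stable")[:n_keep])
    return ExpressionMatrix(
        values=X.values[:, chosen],
        sample_ids=list(X.sample_ids),
        gene_ids=[X.gene_ids[i] for i in chosen],
        labels=X.labels,
    )


def knn_impute(X: ExpressionMatrix, k: int = 15, max_missing_frac: float = 0.5) -> ExpressionMatrix:
    """Impute missing entries from the k most similar genes.

    Genes missing in more than ``max_missing_frac`` of samples are dropped
    first (logged).  A missing value of gene g in sample s is the weighted
    average -- weights 1/(distance + 1e-12) -- of the k genes closest to g in
    Euclidean distance over their co-observed samples, among genes observed
    at s.  Observed entries are returned unchanged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    V = X.values
    if not np.isnan(V).any():
        return X

    frac = np.isnan(V).mean(axis=0)
    keep = frac <= max_missing_frac
    if not keep.all():
        dropped = [g for g, kp in zip(X.gene_ids, keep) if not kp]
        logger.info("knn_impute: dropped %d gene(s) missing in more than %.0f%% "
                    "of samples: %s", len(dropped), 100 * max_missing_frac,
                    ", ".join(dropped[:10]))
    V = V[:, keep]
    gene_ids = [g for g, kp in zip(X.gene_ids, keep) if kp]

    out = V.copy()
    eps = 1e-12
    missing_genes = np.where(np.isnan(V).any(axis=0))[0]
    for j in missing_genes:
        col = V[:, j]
        obs_j = ~np.isnan(col)
        # distance of every other gene to gene j over co-observed samples
        dists = np.full(V.shape[1], np.inf)
        for q in range(V.shape[1]):
            if q == j:
                continue
            shared = obs_j & ~np.isnan(V[:, q])
            if not shared.any():
                continue
            diff = col[shared] - V[shared, q]
            dists[q] = float(np.sqrt(np.sum(diff * diff)))
        for s in np.where(~obs_j)[0]:
            eligible = np.where(np.isfinite(dists) & ~np.isnan(V[s, :]))[0]
            if eligible.size == 0:
                raise ImputationError(
                    f"gene {gene_ids[j]!r}: no eligible neighbor for sample "
                    f"{X.sample_ids[s]!r}")
            nearest = eligible[np.argsort(dists[eligible], kind="stable")[:k]]
            w = 1.0 / (dists[nearest] + eps)
            out[s, j] = float(np.sum(w * V[s, nearest]) / np.sum(w))
    return ExpressionMatrix(values=out, sample_ids=list(X.sample_ids),
                            gene_ids=gene_ids, labels=X.labels)


def zscore_train_apply(
    train_values: np.ndarray,
    apply_values: np.ndarray,
    train_genes: Sequence[str] | None = None,
    apply_genes: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-score fitted on training rows, applied to both matrices.

    Mean and sample standard deviation (ddof=1) are computed per training
    column and the same constants transform ``apply_values``.  Constant
    training genes (sd = 0) are centered but not divided.
    """
    if train_genes is not None and apply_genes is not None:
        if list(train_genes) != list(apply_genes):
            raise ValueError("train and apply matrices have different gene sets/order")
    Xt = np.asarray(train_values, dtype=float)
    Xa = np.asarray(apply_values, dtype=float)
    if Xt.shape[1] != Xa.shape[1]:
        raise ValueError("train and apply matrices have different numbers of genes")
    mu = Xt.mean(axis=0)
    sd = Xt.std(axis=0, ddof=1) if Xt.shape[0] > 1 else np.zeros(Xt.shape[1])
    denom = np.where(sd > 0, sd, 1.0)
    return (Xt - mu) / denom, (Xa - mu) / denom
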