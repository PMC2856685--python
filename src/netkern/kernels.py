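"""Patient-by-patient kernels: plain, interactome-adapted, and normalized.

The baseline kernel is the linear kernel K = X X^T.  The adapted kernel
replaces the inner product by the quadratic form K = X G X^T, where G is the
Laplacian-pseudoinverse similarity of an interactome source aligned with the
gene order of X; it is PSD because G is.  Kernels from different sources are
made comparable by trace normalization, and prediction-time rows are scaled
by the *training* trace so that one test sample at a time is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_prior import GMatrix
from .preprocess import ExpressionMatrix

__all__ = [
    "KernelMatrix",
    "CrossKernel",
    "linear_kernel",
    "adapted_kernel",
    "normalize_kernel",
    "cross_kernel",
    "write_kernel",
]


@dataclass
class KernelMatrix:
    K: np.ndarray
    normalized_flag: bool = False
    train_trace: float | None = None  # raw trace used for normalization
    sample_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.K.shape[0]


@dataclass
class CrossKernel:
    """Test-vs-train kernel rows (M x N), scaled by the training trace."""

    rows: np.ndarray
    train_trace: float = 1.0

    @property
    def n_train(self) -> int:
        return self.rows.shape[1]


def _values(X) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    if isinstance(X, ExpressionMatrix):
        return X.values, list(X.sample_ids), list(X.gene_ids)
    return np.asarray(X, dtype=float), None, None


def _raw_kernel(Xv: np.ndarray, G: np.ndarray | None) -> np.ndarray:
    K = Xv @ Xv.T if G is None else (Xv @ G) @ Xv.T
    return 0.5 * (K + K.T)


def linear_kernel(X) -> KernelMatrix:
    """K = X X^T on complete data."""
    Xv, sids, _ = _values(X)
    if np.isnan(Xv).any():
        raise ValueError("kernel input contains missing values")
    return KernelMatrix(K=_raw_kernel(Xv, None), sample_ids=sids)


def adapted_kernel(X, G: GMatrix) -> KernelMatrix:
    """K = X G X^T, the inner product re-weighted by interactome similarity."""
    Xv, sids, genes = _values(X)
    if np.isnan(Xv).any():
        raise ValueError("kernel input contains missing values")
    if Xv.shape[1] != G.n_genes:
        raise ValueError(
            f"expression has {Xv.shape[1]} genes but G-matrix has {G.n_genes}")
    if genes is not None and genes != G.genes:
        raise ValueError("gene order of expression matrix and G-matrix differ")
    return KernelMatrix(K=_raw_kernel(Xv, G.G), sample_ids=sids)


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Divide by the trace so that trace(K-hat) = 1; records the raw trace."""
    tr = float(np.trace(K.K))
    if tr <= 0:
        raise ValueError(f"degenerate kernel: trace {tr} <= 0")
    return KernelMatrix(K=K.K / tr, normalized_flag=True, train_trace=tr,
                        sample_ids=K.sample_ids)


def cross_kernel(X_test, X_train, G: GMatrix | None = None,
                 train_trace: float | None = 1.0) -> CrossKernel:
    """Rows = X_test G X_train^T / train_trace (G omitted -> inner products).

    ``train_trace`` must be the raw-kernel trace recorded when the training
    kernel was normalized (1.0 if it was not).
    """
    if train_trace is None:
        raise ValueError("train_trace is required (1.0 for an unnormalized "
                         "training kernel)")
    Xe, _, genes_e = _values(X_test)
    Xt, _, genes_t = _values(X_train)
    if Xe.shape[1] != Xt.shape[1]:
        raise ValueError("test and train matrices have different numbers of genes")
    if genes_e is not None and genes_t is not None and genes_e != genes_t:
        raise ValueError("gene order of test and train matrices differ")
    if G is not None:
        if G.n_genes != Xt.shape[1]:
            raise ValueError("G-matrix gene count does not match expression")
        rows = (Xe @ G.G) @ Xt.T
    else:
        rows = Xe @ Xt.T
    return CrossKernel(rows=rows / train_trace, train_trace=float(train_trace))


def write_kernel(K: KernelMatrix, path: str) -> None:
    ids = K.sample_ids or [f"s{i}" for i in range(K.n)]
    pd.DataFrame(K.K, index=ids, columns=ids).to_csv(path, sep="\t")
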