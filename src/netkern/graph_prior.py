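"""Gene-interaction graphs and their Laplacian-pseudoinverse similarity matrices.

An interactome source is a list of gene pairs (optionally weighted).  It is
turned into an undirected weighted graph over a fixed, ordered gene universe,
from which the graph Laplacian ``L = D - W`` and its Moore-Penrose
pseudoinverse ``G = L^+`` are computed.  ``G`` acts as a gene-gene similarity:
entries grow with the number and shortness of network paths between two genes
(it is the covariance of the commute-time embedding of the graph), and it
re-weights the inner product between expression profiles downstream.

Genes of the universe without any retained interaction are kept rather than
discarded: they receive a unit degree entered in ``D`` only, so ``L_kk = 1``
and ``G_kk = 1`` -- the gene contributes to patient similarity with the
standard inner-product weight while staying decoupled from the network.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenePairList",
    "GeneGraph",
    "LaplacianMatrix",
    "GMatrix",
    "ParseError",
    "read_gene_pairs",
    "pool_pair_lists",
    "build_graph",
    "laplacian",
    "pseudoinverse_laplacian",
    "gmatrix_for_source",
    "write_gmatrix",
    "read_gmatrix",
]

#: header tokens recognized when sniffing a header line in edge-list files
_HEADER_TOKENS = {"gene_a", "gene_b", "gene_k", "gene_l", "gene1", "gene2",
                  "source", "target", "weight"}


class ParseError(ValueError):
    """Malformed edge-list input, carrying the offending line number."""


@dataclass
class GenePairList:
    """One interactome source as a list of unordered gene pairs.

    After ingestion pairs are unique per unordered gene pair, self-pairs are
    removed, and every weight is strictly positive.
    """

    source_name: str
    pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, l, w in self.pairs:
            if not k or not l:
                raise ValueError("gene identifiers must be nonempty")
            if k == l:
                raise ValueError(f"self-pair {k!r} not allowed after ingestion")
            if not w > 0:
                raise ValueError(f"pair ({k}, {l}) has non-positive weight {w}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for k, l, _ in self.pairs:
            out.add(k)
            out.add(l)
        return out


@dataclass
class GeneGraph:
    """Weighted undirected graph over an ordered gene universe.

    ``W`` is the symmetric nonnegative adjacency with zero diagonal; ``d`` the
    degree vector.  Genes with no retained edge are flagged in
    ``isolated_mask`` and get the synthetic unit degree d_k = 1.
    """

    genes: list[str]
    W: np.ndarray
    d: np.ndarray
    isolated_mask: np.ndarray
    source_name: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class LaplacianMatrix:
    """Graph Laplacian, optionally symmetrically degree-normalized."""

    L: np.ndarray
    genes: list[str]
    normalized_flag: bool = False
    source_name: str = ""


@dataclass
class GMatrix:
    """Laplacian pseudoinverse: the gene-gene similarity of one source."""

    G: np.ndarray
    genes: list[str]
    rank_tolerance: float = 1e-10
    source_name: str = ""

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _collapse(pairs: Iterable[tuple[str, str, float]], how: str) -> list[tuple[str, str, float]]:
    """Collapse duplicate unordered pairs; ``how`` is 'max' or 'sum'.

    'max' with unit input weights yields binary presence/absence weights;
    'sum' is the additive semantics needed when pooling sources.
    """
    if how not in ("max", "sum"):
        raise ValueError(f"collapse must be 'max' or 'sum', got {how!r}")
    acc: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    for k, l, w in pairs:
        key = (k, l) if k <= l else (l, k)
        if key in acc:
            acc[key] = acc[key] + w if how == "sum" else max(acc[key], w)
        else:
            acc[key] = w
            order.append(key)
    return [(k, l, acc[(k, l)]) for k, l in order]


def read_gene_pairs(
    path_or_stream: str | IO[str],
    delimiter: str | None = None,
    collapse: str = "max",
    source_name: str | None = None,
    header: str = "auto",
) -> GenePairList:
    """Read a two- or three-column edge list into a :class:`GenePairList`.

    Columns are ``gene_a, gene_b[, weight]`` with weight defaulting to 1.
    Lines starting with ``#`` and blank lines are skipped; self-pairs are
    dropped (logged); duplicate unordered pairs are collapsed ('max' default,
    'sum' for additive semantics).  ``header`` is 'auto', 'present' or 'none'.
    """
    if isinstance(path_or_stream, str):
        name = source_name or str(path_or_stream)
        fh: IO[str] = open(path_or_stream, "r", encoding="utf-8")
        close = True
    else:
        name = source_name or getattr(path_or_stream, "name", "<stream>")
        fh, close = path_or_stream, False

    raw: list[tuple[str, str, float]] = []
    n_self = 0
    try:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            fields = text.split(delimiter) if delimiter else text.replace(",", "\t").split()
            fields = [f.strip() for f in fields if f.strip() != ""]
            if len(fields) < 2:
                raise ParseError(f"line {lineno}: expected >=2 columns, got {len(fields)}")
            if first_data_line:
                first_data_line = False
                if header == "present":
                    continue
                if header == "auto":
                    lowered = {f.lower() for f in fields[:3]}
                    third_not_num = False
                    if len(fields) >= 3:
                        try:
                            float(fields[2])
                        except ValueError:
                            third_not_num = True
                    if lowered & _HEADER_TOKENS or third_not_num:
                        continue
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: bad weight {fields[2]!r}") from exc
            else:
                w = 1.0
            if w <= 0:
                raise ParseError(f"line {lineno}: non-positive weight {w}")
            k, l = fields[0], fields[1]
            if k == l:
                n_self += 1
                continue
            raw.append((k, l, w))
    finally:
        if close:
            fh.close()

    if n_self:
        logger.info("%s: dropped %d self-pair line(s)", name, n_self)
    if not raw:
        logger.warning("%s: empty gene-pair list", name)
    return GenePairList(source_name=name, pairs=_collapse(raw, collapse))


def pool_pair_lists(sources: Sequence[GenePairList], name: str = "pooled") -> GenePairList:
    """Pool several sources into one by adding edge weights of shared pairs."""
    merged: list[tuple[str, str, float]] = []
    for src in sources:
        merged.extend(src.pairs)
    return GenePairList(source_name=name, pairs=_collapse(merged, "sum"))


def build_graph(pairs: GenePairList, gene_universe: Sequence[str]) -> GeneGraph:
    """Restrict a pair list to an ordered gene universe and build the graph.

    Pairs mentioning genes outside the universe are ignored (logged).  Genes
    left without any edge get the synthetic unit degree and are flagged
    isolated.
    """
    genes = list(gene_universe)
    if not genes:
        raise ValueError("gene universe must be nonempty")
    index = {g: i for i, g in enumerate(genes)}
    if len(index) != len(genes):
        raise ValueError("duplicate identifiers in gene universe")

    p = len(genes)
    W = np.zeros((p, p))
    n_outside = 0
    for k, l, w in pairs.pairs:
        ik, il = index.get(k), index.get(l)
        if ik is None or il is None:
            n_outside += 1
            continue
        W[ik, il] += w
        W[il, ik] += w
    if n_outside:
        logger.info("%s: ignored %d pair(s) outside the gene universe",
                    pairs.source_name, n_outside)

    d = W.sum(axis=1)
    isolated = d == 0
    d = np.where(isolated, 1.0, d)
    return GeneGraph(genes=genes, W=W, d=d, isolated_mask=isolated,
                     source_name=pairs.source_name)


def laplacian(graph: GeneGraph, normalized: bool = False) -> LaplacianMatrix:
    """Graph Laplacian ``L = D - W`` (optionally ``D^-1/2 L D^-1/2``).

    The unit degree of isolated genes enters ``D`` only, never ``W``, so the
    diagonal does not cancel: isolated genes keep ``L_kk = 1`` in both forms.
    """
    L = np.diag(graph.d) - graph.W
    if normalized:
        inv_sqrt = 1.0 / np.sqrt(graph.d)
        L = L * inv_sqrt[:, None] * inv_sqrt[None, :]
    return LaplacianMatrix(L=L, genes=list(graph.genes), normalized_flag=normalized,
                           source_name=graph.source_name)


def pseudoinverse_laplacian(L: LaplacianMatrix, rank_tolerance: float = 1e-10) -> GMatrix:
    """Moore-Penrose pseudoinverse of the Laplacian via symmetric eigendecomposition.

    Eigenvalues below ``rank_tolerance`` times the largest eigenvalue are
    treated as zero (tiny negatives from round-off are clipped first).
    """
    A = np.asarray(L.L, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("Laplacian must be square")
    asym = np.abs(A - A.T).max()
    scale = max(np.abs(A).max(), 1.0)
    if asym > 1e-8 * scale:
        raise ValueError(f"Laplacian is not symmetric (max asymmetry {asym:.3g})")
    A = 0.5 * (A + A.T)

    eigval, eigvec = np.linalg.eigh(A)
    eigval = np.clip(eigval, 0.0, None)
    if eigval.size == 0:
        raise ValueError("empty Laplacian")
    cutoff = rank_tolerance * eigval.max() if eigval.max() > 0 else np.inf
    inv = np.where(eigval > cutoff, 1.0 / np.where(eigval > 0, eigval, 1.0), 0.0)
    G = (eigvec * inv) @ eigvec.T
    G = 0.5 * (G + G.T)
    return GMatrix(G=G, genes=list(L.genes), rank_tolerance=rank_tolerance,
                   source_name=L.source_name)


def gmatrix_for_source(
    pairs: GenePairList,
    gene_universe: Sequence[str],
    normalized: bool = False,
    rank_tolerance: float = 1e-10,
) -> GMatrix:
    """Edge list -> graph -> Laplacian -> G-matrix over one gene universe."""
    graph = build_graph(pairs, gene_universe)
    return pseudoinverse_laplacian(laplacian(graph, normalized=normalized),
                                   rank_tolerance=rank_tolerance)


def identity_gmatrix(gene_universe: Sequence[str], source_name: str = "identity") -> GMatrix:
    """The G-matrix that reduces the adapted kernel to the plain inner product."""
    genes = list(gene_universe)
    return GMatrix(G=np.eye(len(genes)), genes=genes, source_name=source_name)


def write_gmatrix(g: GMatrix, path: str) -> None:
    """Export as dense TSV with gene ids as header row and first column."""
    pd.DataFrame(g.G, index=g.genes, columns=g.genes).to_csv(path, sep="\t")


def read_gmatrix(path: str, source_name: str | None = None) -> GMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("G-matrix file must have identical row and column gene ids")
    return GMatrix(G=df.to_numpy(dtype=float), genes=[str(g) for g in df.columns],
                   source_name=source_name or str(path))
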