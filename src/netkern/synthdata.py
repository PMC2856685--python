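"""Synthetic interactome sources and complementary-pathway expression data.

The generator emulates the situation the interactome-weighted kernel is
built for: a pathway contains two parallel branches through which the same
oncogenic signal can flow, and each affected patient dysregulates exactly one
of them -- one branch repressed or the alternative branch activated -- so
that two patients with the same phenotype may share no dysregulated gene at
all.  Single-gene statistics are attenuated (each informative gene moves in
only about half the positive samples), while the branch contrast is a smooth
mode of the pathway graph that the Laplacian pseudoinverse amplifies.

A pathway source lists within-pathway gene pairs.  Two topologies are
available: ``"branched"`` (default) builds each pathway as two within-branch
cliques joined by a few bridge edges -- the parallel-routes structure the
complementary signal lives on; ``"clique"`` links all pairs of pathway
members, the flat same-pathway semantics of curated pathway databases.  A
matched null source with the same number of random pairs serves as the
negative control for source scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .graph_prior import GenePairList
from .preprocess import ExpressionMatrix

__all__ = [
    "SyntheticSpec",
    "generate_pathway_source",
    "generate_complementary_expression",
    "generate_null_source",
]


@dataclass
class SyntheticSpec:
    """Study conditions of one simulated dataset.

    Defaults: 120 patients by 1000 genes, five pathways of 20 genes of which
    the first two carry the class signal, branch shift delta = 1.5 on unit
    background noise, balanced classes.
    """

    n_genes: int = 1000
    n_samples: int = 120
    pathway_size: int = 20
    n_pathways: int = 5
    n_informative_pathways: int = 2
    effect_size: float = 1.5
    noise_sd: float = 1.0
    positive_fraction: float = 0.5
    n_bridges: int = 2
    seed: int = 7

    def __post_init__(self) -> None:
        if self.pathway_size * self.n_pathways > self.n_genes:
            raise ValueError("pathways do not fit in the gene universe")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0,1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_informative_pathways > self.n_pathways:
            raise ValueError("more informative pathways than pathways")
        if self.n_bridges < 1:
            raise ValueError("need at least one bridge between branches")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    def pathway_block(self, b: int) -> range:
        start = b * self.pathway_size
        return range(start, start + self.pathway_size)

    def branches(self, b: int) -> tuple[range, range]:
        """The two disjoint halves of pathway block b."""
        blk = self.pathway_block(b)
        h = self.pathway_size // 2
        return range(blk.start, blk.start + h), range(blk.start + h, blk.stop)


def generate_pathway_source(spec: SyntheticSpec, topology: str = "branched") -> GenePairList:
    """Within-pathway gene pairs over consecutive blocks; other genes isolated.

    ``topology="clique"`` emits every within-block pair.  ``"branched"``
    emits every within-branch pair plus ``spec.n_bridges`` edges linking the
    i-th gene of one branch to the i-th of the other.
    """
    ids = spec.gene_ids
    pairs: list[tuple[str, str, float]] = []
    for b in range(spec.n_pathways):
        if topology == "clique":
            blk = list(spec.pathway_block(b))
            pairs.extend((ids[k], ids[l], 1.0)
                         for i, k in enumerate(blk) for l in blk[i + 1:])
        elif topology == "branched":
            bra, brb = (list(r) for r in spec.branches(b))
            for half in (bra, brb):
                pairs.extend((ids[k], ids[l], 1.0)
                             for i, k in enumerate(half) for l in half[i + 1:])
            for i in range(min(spec.n_bridges, len(bra), len(brb))):
                pairs.append((ids[bra[i]], ids[brb[i]], 1.0))
        else:
            raise ValueError(f"unknown topology {topology!r}")
    return GenePairList(source_name=f"pathway_{topology}", pairs=pairs)


def generate_complementary_expression(
    spec: SyntheticSpec, source: GenePairList | None = None
) -> ExpressionMatrix:
    """Labeled expression with the complementary-branch class signal.

    Background is i.i.d. Normal(0, noise_sd^2).  Labels are +1 for
    round(positive_fraction * n) randomly placed samples, -1 otherwise.  Each
    positive sample, in each informative pathway, dysregulates one uniformly
    chosen branch: the first branch is repressed by ``effect_size``, the
    alternative branch activated by the same amount.  Negatives are left at
    background.  Deterministic given ``spec.seed``.
    """
    if spec.n_informative_pathways > 0 and spec.pathway_size < 2:
        raise ValueError("informative pathways need pathway_size >= 2 "
                         "(two branches)")
    rng = np.random.default_rng(spec.seed)
    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    n_pos = int(round(spec.positive_fraction * spec.n_samples))
    y = np.full(spec.n_samples, -1, dtype=int)
    y[rng.choice(spec.n_samples, size=n_pos, replace=False)] = 1

    for i in np.where(y == 1)[0]:
        for b in range(spec.n_informative_pathways):
            bra, brb = spec.branches(b)
            if rng.random() < 0.5:
                X[i, list(bra)] -= spec.effect_size   # branch repressed
            else:
                X[i, list(brb)] += spec.effect_size   # alternative activated
    return ExpressionMatrix(values=X, sample_ids=[f"s{i:03d}" for i in range(spec.n_samples)],
                            gene_ids=spec.gene_ids, labels=y)


def generate_null_source(spec: SyntheticSpec, seed: int | None = None,
                         n_pairs: int | None = None) -> GenePairList:
    """Uninformative control: uniformly random gene pairs.

    The pair count matches the default pathway source unless given
    explicitly; pairs are drawn without replacement over all C(n_genes, 2)
    unordered pairs, independent of the informative blocks.
    """
    if n_pairs is None:
        n_pairs = len(generate_pathway_source(spec))
    total = comb(spec.n_genes, 2)
    if n_pairs > total:
        raise ValueError(f"requested {n_pairs} pairs but only {total} exist")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    flat = rng.choice(total, size=n_pairs, replace=False)
    ids = spec.gene_ids
    pairs = []
    for t in np.sort(flat):
        # unrank the t-th pair (k < l) of the lexicographic enumeration
        k = int((2 * spec.n_genes - 1 - np.sqrt((2 * spec.n_genes - 1) ** 2 - 8 * t)) // 2)
        offset = t - (k * (2 * spec.n_genes - k - 1)) // 2
        l = k + 1 + int(offset)
        pairs.append((ids[k], ids[l], 1.0))
    return GenePairList(source_name="null", pairs=pairs)
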