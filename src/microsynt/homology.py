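"""Bi-directional best-hit (BDBH) orthology and phylogenetic-profile matrices.

BDBH is the orthology criterion used throughout the engine: a reference
gene and a target gene are called orthologs when each is the other's
highest-scoring match in an all-against-all protein similarity search.
The call itself is threshold-free; identity/coverage cut-offs are applied
afterwards, explicitly, through :func:`filter_profile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import pandas as pd

from .io import leaf_order
from .records import GenomeRecord, OrthologPair, SimilarityHit


def best_hits(hits: Iterable[SimilarityHit]) -> Dict[str, SimilarityHit]:
    """Best hit per query: maximal bit score, ties by lower e-value, then
    higher percent identity, then lexicographically smallest subject id.

    Self-hits (query == subject) are discarded, the standard convention when
    a genome is compared with itself.
    """
    best: Dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        cur = best.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            best[h.query_id] = h
    return best


def _hit_key(h: SimilarityHit) -> Tuple[float, float, float, str]:
    # sort-ascending key: better hits compare smaller
    return (-h.bit_score, h.e_value, -h.pct_identity, h.subject_id)


def bdbh(
    hits_ab: Iterable[SimilarityHit],
    hits_ba: Iterable[SimilarityHit],
    target_genome_id: str = "target",
    ref_order: Optional[Sequence[str]] = None,
) -> List[OrthologPair]:
    """Reciprocal best hits between genome A (reference) and genome B.

    A pair (a, b) is returned iff b is a's best hit in ``hits_ab`` and a is
    b's best hit in ``hits_ba``. Each pair carries the forward (A→B) hit's
    metrics. Output is sorted by ``ref_order`` when given (reference gene
    order), else by reference gene id.
    """
    fwd = best_hits(hits_ab)
    rev = best_hits(hits_ba)
    pairs = []
    for a, hit in fwd.items():
        back = rev.get(hit.subject_id)
        if back is not None and back.subject_id == a:
            pairs.append(
                OrthologPair(
                    ref_gene_id=a,
                    target_genome_id=target_genome_id,
                    target_gene_id=hit.subject_id,
                    pct_identity=hit.pct_identity,
                    query_cov=hit.query_cov,
                    bit_score=hit.bit_score,
                    e_value=hit.e_value,
                )
            )
    if ref_order is not None:
        rank = {g: i for i, g in enumerate(ref_order)}
        pairs.sort(key=lambda p: (rank.get(p.ref_gene_id, len(rank)), p.ref_gene_id))
    else:
        pairs.sort(key=lambda p: p.ref_gene_id)
    return pairs


@dataclass
class ProfileMatrix:
    """Reference-gene x target-genome matrix of (pct_identity, query_cov) cells.

    An absent cell means the reference gene has no ortholog in that genome
    (an orphan gene). Rows follow reference chromosomal order; columns
    follow tree leaf order when a tree was supplied.
    """

    ref_gene_ids: List[str]
    target_genome_ids: List[str]
    cells: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)

    def cell(self, gene_id: str, genome_id: str) -> Optional[Tuple[float, float]]:
        return self.cells.get((gene_id, genome_id))

    def presence_count(self, gene_id: str) -> int:
        return sum(1 for g in self.target_genome_ids if (gene_id, g) in self.cells)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: rows = genes, columns = genomes, cell = "identity/coverage" or ""."""
        data = {}
        for genome in self.target_genome_ids:
            col = []
            for gene in self.ref_gene_ids:
                c = self.cells.get((gene, genome))
                col.append("" if c is None else f"{c[0]:g}/{c[1]:g}")
            data[genome] = col
        return pd.DataFrame(data, index=pd.Index(self.ref_gene_ids, name="gene_id"))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_profile(
    ref: GenomeRecord,
    pairs_by_genome: Mapping[str, Iterable[OrthologPair]],
    tree: Optional[dendropy.Tree] = None,
    ref_genes: Optional[Sequence[str]] = None,
) -> ProfileMatrix:
    """Assemble a phylogenetic profile from per-genome ortholog pair lists.

    Column order follows the tree's leaf order when a tree is given (its
    leaves must match the compared genome ids exactly), else the mapping's
    insertion order. ``ref_genes`` optionally restricts rows to a gene set.
    """
    genome_ids = list(pairs_by_genome.keys())
    if tree is not None:
        leaves = leaf_order(tree)
        if set(leaves) != set(genome_ids):
            missing = set(genome_ids) - set(leaves)
            extra = set(leaves) - set(genome_ids)
            raise ValueError(
                f"tree leaves do not match genome ids (missing from tree: {sorted(missing)}, "
                f"not compared: {sorted(extra)})"
            )
        genome_ids = leaves
    row_ids = ref.gene_ids if ref_genes is None else [g for g in ref.gene_ids if g in set(ref_genes)]
    known = set(ref.gene_ids)
    cells: Dict[Tuple[str, str], Tuple[float, float]] = {}
    for genome_id, pairs in pairs_by_genome.items():
        for p in pairs:
            if p.ref_gene_id not in known:
                raise KeyError(
                    f"ortholog pair references unknown reference gene {p.ref_gene_id!r}"
                )
            cells[(p.ref_gene_id, genome_id)] = (p.pct_identity, p.query_cov)
    row_set = set(row_ids)
    cells = {k: v for k, v in cells.items() if k[0] in row_set}
    return ProfileMatrix(ref_gene_ids=row_ids, target_genome_ids=genome_ids, cells=cells)


def filter_profile(
    profile: ProfileMatrix,
    min_identity: float = 0.0,
    min_cov: float = 0.0,
    keyword: Optional[str] = None,
    basket: Optional[Set[str]] = None,
    ref: Optional[GenomeRecord] = None,
) -> ProfileMatrix:
    """Apply the dynamic display filters: BLAST thresholds, a product
    keyword (case-insensitive substring; requires ``ref`` for products) and
    a gene basket. Cells below either threshold become absent; row order is
    preserved.
    """
    if not (0.0 <= min_identity <= 100.0):
        raise ValueError("min_identity must be within [0, 100]")
    if not (0.0 <= min_cov <= 1.0):
        raise ValueError("min_cov must be within [0, 1]")
    rows = list(profile.ref_gene_ids)
    if basket is not None:
        rows = [g for g in rows if g in basket]
    if keyword is not None:
        if ref is None:
            raise ValueError("keyword filtering requires the reference genome (for products)")
        kw = keyword.lower()
        rows = [g for g in rows if kw in ref.gene(g).product.lower()]
    row_set = set(rows)
    cells = {
        (gene, genome): (ident, cov)
        for (gene, genome), (ident, cov) in profile.cells.items()
        if gene in row_set and ident >= min_identity and cov >= min_cov
    }
    return ProfileMatrix(
        ref_gene_ids=rows,
        target_genome_ids=list(profile.target_genome_ids),
        cells=cells,
    )
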