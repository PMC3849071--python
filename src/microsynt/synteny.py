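"""Synteny-block detection and plot-data generation.

A synteny block is a maximal run of ortholog pairs whose reference gene
indices increase left to right and whose target gene indices move
monotonically in one direction (ascending = collinear, descending =
inverted), with gaps of at most ``max_gap`` skipped genes on either genome.
Blocks expose the data behind dot plots (one point per ortholog pair at
gene midpoints) and line plots (one segment per block).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .records import GenomeRecord, OrthologPair

COLLINEAR = "collinear"
INVERTED = "inverted"


@dataclass
class SyntenyBlock:
    """A chain of ortholog pairs with consistent relative order/orientation."""

    ref_genome_id: str
    target_genome_id: str
    pairs: List[OrthologPair]
    orientation: str
    ref_span: Tuple[int, int]
    target_span: Tuple[int, int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class DotPlotData:
    """One (ref midpoint, target midpoint, pct identity) point per ortholog pair."""

    ref_genome_id: str
    target_genome_id: str
    points: List[Tuple[float, float, float]] = field(default_factory=list)


def _indexed_pairs(
    pairs: Iterable[OrthologPair], ref: GenomeRecord, target: GenomeRecord
) -> List[Tuple[int, int, OrthologPair]]:
    """(ref gene index, target gene index, pair), sorted by reference index."""
    ref_rank = {g: i for i, g in enumerate(ref.gene_ids)}
    tgt_rank = {g: i for i, g in enumerate(target.gene_ids)}
    out = []
    for p in pairs:
        if p.ref_gene_id not in ref_rank:
            raise KeyError(f"pair references unknown reference gene {p.ref_gene_id!r}")
        if p.target_gene_id not in tgt_rank:
            raise KeyError(f"pair references unknown target gene {p.target_gene_id!r}")
        out.append((ref_rank[p.ref_gene_id], tgt_rank[p.target_gene_id], p))
    out.sort(key=lambda t: t[0])
    return out


def _make_block(
    chain: List[Tuple[int, int, OrthologPair]],
    ref: GenomeRecord,
    target: GenomeRecord,
) -> SyntenyBlock:
    orientation = COLLINEAR
    if len(chain) >= 2 and chain[1][1] < chain[0][1]:
        orientation = INVERTED
    ref_genes = [ref.genes[i] for i, _, _ in chain]
    tgt_genes = [target.genes[j] for _, j, _ in chain]
    return SyntenyBlock(
        ref_genome_id=ref.genome_id,
        target_genome_id=target.genome_id,
        pairs=[p for _, _, p in chain],
        orientation=orientation,
        ref_span=(min(g.start for g in ref_genes), max(g.end for g in ref_genes)),
        target_span=(min(g.start for g in tgt_genes), max(g.end for g in tgt_genes)),
    )


def detect_blocks(
    pairs: Iterable[OrthologPair],
    ref: GenomeRecord,
    target: GenomeRecord,
    max_gap: int = 3,
    min_pairs: int = 2,
    wrap: bool = False,
) -> List[SyntenyBlock]:
    """Chain one-to-one ortholog pairs into synteny blocks.

    Greedy left-to-right chaining over pairs sorted by reference gene index:
    a pair extends the current chain when its reference index exceeds the
    previous member's by at most ``max_gap + 1``, its target index steps by
    at most ``max_gap + 1`` in the chain's direction, and the direction
    (ascending or descending target index) stays consistent. The direction
    of a 1-pair chain is fixed by its second member. Chains shorter than
    ``min_pairs`` are discarded; every retained pair belongs to exactly one
    block, and blocks are reported in reference order.

    With ``wrap=True`` and both genomes circular, a trailing and a leading
    chain that continue each other across the origin (gap condition met on
    both genomes modulo gene count, same direction) are merged into one
    block; its spans stay in linear coordinates of the member genes.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if min_pairs < 1:
        raise ValueError("min_pairs must be >= 1")
    indexed = _indexed_pairs(pairs, ref, target)
    step = max_gap + 1
    chains: List[List[Tuple[int, int, OrthologPair]]] = []
    chain: List[Tuple[int, int, OrthologPair]] = []
    direction = 0  # +1 ascending target, -1 descending, 0 undetermined
    for item in indexed:
        ri, ti, _ = item
        if not chain:
            chain = [item]
            direction = 0
            continue
        pr, pt, _ = chain[-1]
        dt = ti - pt
        ref_ok = 0 < ri - pr <= step
        if direction == 0:
            tgt_ok = dt != 0 and abs(dt) <= step
        else:
            tgt_ok = 0 < dt * direction <= step
        if ref_ok and tgt_ok:
            chain.append(item)
            if direction == 0:
                direction = 1 if dt > 0 else -1
        else:
            chains.append(chain)
            chain = [item]
            direction = 0
    if chain:
        chains.append(chain)

    if wrap and ref.circular and target.circular and len(chains) >= 2:
        chains = _wrap_merge(chains, len(ref.genes), len(target.genes), step)

    return [_make_block(c, ref, target) for c in chains if len(c) >= min_pairs]


def _wrap_merge(chains, n_ref: int, n_tgt: int, step: int):
    """Join the last chain onto the first across the circular origin when compatible."""
    first, last = chains[0], chains[-1]
    if first is last:
        return chains

    def _dir(c):
        return 0 if len(c) < 2 else (1 if c[1][1] > c[0][1] else -1)

    ref_gap = (first[0][0] - last[-1][0]) % n_ref
    dt = (first[0][1] - last[-1][1]) % n_tgt
    d_last, d_first = _dir(last), _dir(first)
    if d_last != 0 and d_first != 0 and d_last != d_first:
        return chains
    direction = d_last or d_first
    if direction == -1:
        dt = -((last[-1][1] - first[0][1]) % n_tgt)
    if 0 < ref_gap <= step and (
        (direction >= 0 and 0 < dt <= step) or (direction <= 0 and 0 < -dt <= step)
    ):
        return [last + first] + chains[1:-1]
    return chains


def unchained_pairs(
    pairs: Iterable[OrthologPair], blocks: Iterable[SyntenyBlock]
) -> List[OrthologPair]:
    """Pairs that fell in chains below the min_pairs cut (reported, never silently lost)."""
    kept = {(p.ref_gene_id, p.target_gene_id) for b in blocks for p in b.pairs}
    return [p for p in pairs if (p.ref_gene_id, p.target_gene_id) not in kept]


def local_offset(
    anchor_gene_id: str,
    pairs: Iterable[OrthologPair],
    ref: GenomeRecord,
    target: GenomeRecord,
) -> Optional[float]:
    """Signed bp translation that brings the anchor's ortholog under the anchor.

    offset = ref anchor midpoint - target ortholog midpoint; adding it to
    target coordinates shifts the target genome into local alignment with
    the reference. ``None`` when the anchor is an orphan.
    """
    anchor = ref.gene(anchor_gene_id)  # KeyError if unknown
    for p in pairs:
        if p.ref_gene_id == anchor_gene_id:
            return anchor.midpoint - target.gene(p.target_gene_id).midpoint
    return None


def dotplot(
    pairs: Iterable[OrthologPair], ref: GenomeRecord, target: GenomeRecord
) -> DotPlotData:
    """One point per ortholog pair at (ref gene midpoint, target gene midpoint)."""
    pts = [
        (ref.genes[ri].midpoint, target.genes[ti].midpoint, p.pct_identity)
        for ri, ti, p in _indexed_pairs(pairs, ref, target)
    ]
    return DotPlotData(
        ref_genome_id=ref.genome_id, target_genome_id=target.genome_id, points=pts
    )


def lineplot(blocks: Iterable[SyntenyBlock]) -> List[Tuple[Tuple[int, int], Tuple[int, int], str]]:
    """One (ref_span, target_span, orientation) segment per block, in reference order."""
    return sorted(
        ((b.ref_span, b.target_span, b.orientation) for b in blocks),
        key=lambda seg: seg[0],
    )


def select_region(
    pairs: Iterable[OrthologPair],
    ref: GenomeRecord,
    target: GenomeRecord,
    ref_window: Tuple[float, float],
    target_window: Tuple[float, float],
) -> Set[str]:
    """Gene basket: reference genes of all pairs whose dot-plot point falls
    inside both windows (bp intervals, inclusive)."""
    for name, (lo, hi) in (("ref_window", ref_window), ("target_window", target_window)):
        if lo > hi:
            raise ValueError(f"{name} is inverted: {lo} > {hi}")
    basket: Set[str] = set()
    for ri, ti, p in _indexed_pairs(pairs, ref, target):
        x = ref.genes[ri].midpoint
        y = target.genes[ti].midpoint
        if ref_window[0] <= x <= ref_window[1] and target_window[0] <= y <= target_window[1]:
            basket.add(p.ref_gene_id)
    return basket


def write_blocks(blocks: Sequence[SyntenyBlock], path) -> None:
    rows = ["#ref_start\tref_end\ttarget_start\ttarget_end\torientation\tn_pairs\tref_gene_ids"]
    for b in blocks:
        genes = ",".join(p.ref_gene_id for p in b.pairs)
        rows.append(
            f"{b.ref_span[0]}\t{b.ref_span[1]}\t{b.target_span[0]}\t{b.target_span[1]}\t"
            f"{b.orientation}\t{b.n_pairs}\t{genes}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")


def write_dotplot(dp: DotPlotData, path) -> None:
    rows = ["#ref_midpoint\ttarget_midpoint\tpct_identity"]
    for x, y, ident in sorted(dp.points):
        rows.append(f"{x:g}\t{y:g}\t{ident:g}")
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")


def plot_dotplot(dp: DotPlotData, path) -> None:
    """Static scatter image of the dot plot (convenience export)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p[0] for p in dp.points]
    ys = [p[1] for p in dp.points]
    cs = [p[2] for p in dp.points]
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(xs, ys, c=cs, s=4, cmap="viridis", vmin=0, vmax=100)
    ax.set_xlabel(f"{dp.ref_genome_id} (bp)")
    ax.set_ylabel(f"{dp.target_genome_id} (bp)")
    fig.colorbar(sc, label="% identity")
    fig.savefig(path, dpi=120)
    plt.close(fig)
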