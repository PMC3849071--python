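"""Synthetic data with full ground truth.

Generates annotated genomes with valid ORFs, rearranged derivative genomes
with a known ortholog map and planted segment structure, random similarity
tables, random trees, and strain SNP collections simulated down a tree
under a Jukes-Cantor substitution process — everything the engine consumes,
with the true answer recorded so every pipeline is testable end to end.

All routines are deterministic per seed (numpy default_rng).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from Bio.Seq import Seq

from . import io as mio
from .records import (
    FORWARD,
    REVERSE,
    CoverageTrack,
    GeneAnnotation,
    GenomeRecord,
    OrthologPair,
    SimilarityHit,
    SnpRecord,
    StrainMetadata,
    reverse_complement,
)

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
START = "ATG"


@dataclass
class GroundTruth:
    """Everything the generator knows that the engine must rediscover."""

    ortholog_map: Dict[str, str] = field(default_factory=dict)
    # (ref gene index start, ref gene index end inclusive, orientation), in ref order
    block_structure: List[Tuple[int, int, str]] = field(default_factory=list)
    tree: Optional[dendropy.Tree] = None
    haplotypes: Dict[str, str] = field(default_factory=dict)
    # (strain, position, gene_id or None, effect)
    effects: List[Tuple[str, int, Optional[str], str]] = field(default_factory=list)
    snp_tables: Dict[str, List[SnpRecord]] = field(default_factory=dict)
    collisions: int = 0


# ---------------------------------------------------------------------------
# Genomes


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 2) random non-stop codons + a random stop codon."""
    n_body = n_codons - 2
    codons = BASES[rng.integers(0, 4, size=(n_body, 3))]
    body = np.array(["".join(c) for c in codons])
    bad = np.isin(body, STOPS)
    while bad.any():
        redo = BASES[rng.integers(0, 4, size=(int(bad.sum()), 3))]
        body[bad] = ["".join(c) for c in redo]
        bad = np.isin(body, STOPS)
    stop = STOPS[rng.integers(0, 3)]
    return START + "".join(body) + stop


def make_genome(
    n_genes: int,
    mean_gene_len: int = 900,
    intergenic_len: int = 150,
    seed: int = 1,
    genome_id: str = "ref",
    alternate_strands: bool = True,
    circular: bool = False,
) -> GenomeRecord:
    """A genome whose genes are valid ORFs (length divisible by 3, no
    internal stops), separated by random intergenic spacers."""
    if n_genes < 1 or mean_gene_len < 9 or intergenic_len < 1:
        raise ValueError("parameters must be positive (genes need >= 3 codons)")
    rng = np.random.default_rng(seed)
    chunks: List[str] = []
    genes: List[GeneAnnotation] = []
    pos = 1
    for i in range(n_genes):
        spacer_len = int(rng.integers(max(1, intergenic_len // 2), intergenic_len * 2))
        chunks.append("".join(rng.choice(BASES, size=spacer_len)))
        pos += spacer_len
        n_codons = max(4, int(round(rng.normal(mean_gene_len / 3, mean_gene_len / 12))))
        orf = _random_orf(rng, n_codons)
        strand = FORWARD if (not alternate_strands or i % 2 == 0) else REVERSE
        chunks.append(orf if strand == FORWARD else reverse_complement(orf))
        start, end = pos, pos + len(orf) - 1
        genes.append(
            GeneAnnotation(
                gene_id=f"{genome_id}_g{i + 1:05d}",
                start=start,
                end=end,
                strand=strand,
                name=f"gen{i + 1}",
                product=f"hypothetical protein {i + 1}",
                pid=str(90000000 + i),
            )
        )
        pos = end + 1
    tail = int(rng.integers(max(1, intergenic_len // 2), intergenic_len * 2))
    chunks.append("".join(rng.choice(BASES, size=tail)))
    sequence = "".join(chunks)
    return GenomeRecord(
        genome_id=genome_id, genes=genes, sequence=sequence, circular=circular,
        description=f"synthetic genome {genome_id}",
    )


# ---------------------------------------------------------------------------
# Rearrangement


def _maximal_runs(target_index: Sequence[int]) -> List[Tuple[int, int, str]]:
    """Greedy maximal runs of +/-1 steps over the target-index sequence
    (ref order), mirroring gap-free chaining; (start, end, orientation)."""
    runs: List[Tuple[int, int, str]] = []
    i = 0
    n = len(target_index)
    while i < n:
        j = i
        direction = 0
        while j + 1 < n:
            dt = target_index[j + 1] - target_index[j]
            if direction == 0 and dt in (1, -1):
                direction = dt
                j += 1
            elif direction != 0 and dt == direction:
                j += 1
            else:
                break
        runs.append((i, j, "collinear" if direction >= 0 else "inverted"))
        i = j + 1
    return runs


def rearrange(
    genome: GenomeRecord,
    n_segments: int,
    invert_prob: float = 0.3,
    seed: int = 1,
    target_id: Optional[str] = None,
) -> Tuple[GenomeRecord, GroundTruth]:
    """Cut the gene order into ``n_segments`` contiguous runs, permute them
    and invert each with probability ``invert_prob``; gene content preserved.

    The sampled permutation/orientations are redrawn (seeded, bounded) until
    no two adjacently placed segments continue each other's original run, so
    the planted segments are exactly the maximal-run structure a gap-free
    chainer must recover. Each segment keeps at least 2 genes so every
    planted block is recoverable at min_pairs=2 and its orientation is
    well defined.
    """
    n = len(genome.genes)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if n_segments > n // 2:
        raise ValueError(f"n_segments={n_segments} too large for {n} genes (need >= 2 genes each)")
    rng = np.random.default_rng(seed)
    target_id = target_id or f"{genome.genome_id}_rearr"

    for attempt in range(10000):
        # cut points spaced >= 2 apart -> every segment has >= 2 genes
        if n_segments == 1:
            bounds = [(0, n - 1)]
        else:
            cuts = sorted(rng.choice(np.arange(1, n // 2), size=n_segments - 1, replace=False) * 2)
            edges = [0] + [int(c) for c in cuts] + [n]
            bounds = [(edges[i], edges[i + 1] - 1) for i in range(n_segments)]
        order = rng.permutation(n_segments)
        inverted = rng.random(n_segments) < invert_prob
        # target index of each ref gene under this layout
        tgt_index = [0] * n
        offset = 0
        for seg in order:
            lo, hi = bounds[seg]
            idxs = range(lo, hi + 1)
            for k, ref_i in enumerate(idxs):
                tgt_index[ref_i] = offset + ((hi - lo) - k if inverted[seg] else k)
            offset += hi - lo + 1
        planted = sorted(
            (lo, hi, "inverted" if inverted[s] else "collinear")
            for s, (lo, hi) in enumerate(bounds)
        )
        if n_segments == 1 and not inverted[0]:
            planted = [(0, n - 1, "collinear")]
        if _maximal_runs(tgt_index) == planted:
            break
    else:  # pragma: no cover - sampling is overwhelmingly likely to succeed
        raise RuntimeError("could not sample a valid rearrangement")

    # rebuild the target genome: concatenate segments (sequence + genes);
    # segment sequence spans partition the whole genome (intergenic DNA
    # between segments travels with the downstream segment)
    seq = genome.sequence
    chunks: List[str] = []
    new_genes: List[GeneAnnotation] = []
    ortholog_map: Dict[str, str] = {}
    pos = 1
    for seg in order:
        lo, hi = bounds[seg]
        seg_genes = genome.genes[lo : hi + 1]
        seg_start = 1 if lo == 0 else genome.genes[lo - 1].end + 1
        seg_end = genome.length if hi == n - 1 else seg_genes[-1].end
        piece = seq[seg_start - 1 : seg_end] if seq else ""
        if inverted[seg]:
            piece = reverse_complement(piece)
            placed = list(reversed(seg_genes))
        else:
            placed = list(seg_genes)
        for g in placed:
            if inverted[seg]:
                new_start = pos + (seg_end - g.end)
                new_strand = REVERSE if g.strand == FORWARD else FORWARD
            else:
                new_start = pos + (g.start - seg_start)
                new_strand = g.strand
            new_id = g.gene_id.replace(genome.genome_id, target_id, 1)
            new_genes.append(
                GeneAnnotation(
                    gene_id=new_id, start=new_start, end=new_start + g.length - 1,
                    strand=new_strand, name=g.name, product=g.product, pid=g.pid,
                )
            )
            ortholog_map[g.gene_id] = new_id
        chunks.append(piece)
        pos += seg_end - seg_start + 1
    target = GenomeRecord(
        genome_id=target_id,
        genes=new_genes,
        sequence="".join(chunks) if seq else None,
        length=0 if seq else genome.length,
        circular=genome.circular,
        description=f"rearranged derivative of {genome.genome_id}",
    )
    truth = GroundTruth(ortholog_map=ortholog_map, block_structure=planted)
    return target, truth


def perfect_pairs(
    ortholog_map: Dict[str, str], target_genome_id: str, ref: GenomeRecord
) -> List[OrthologPair]:
    """Identity ortholog pairs from a planted map, in reference gene order."""
    rank = {g: i for i, g in enumerate(ref.gene_ids)}
    return [
        OrthologPair(ref_gene_id=a, target_genome_id=target_genome_id, target_gene_id=b)
        for a, b in sorted(ortholog_map.items(), key=lambda kv: rank[kv[0]])
    ]


# ---------------------------------------------------------------------------
# Similarity tables


def make_similarity_tables(
    ref: GenomeRecord,
    target: GenomeRecord,
    ortholog_map: Dict[str, str],
    seed: int = 1,
    noise_hits: int = 50,
) -> Tuple[List[SimilarityHit], List[SimilarityHit]]:
    """All-against-all style hit lists whose mutual-best structure equals the
    planted ortholog map: ortholog hits score >= 50 bits, noise hits < 40."""
    rng = np.random.default_rng(seed)
    fwd: List[SimilarityHit] = []
    rev: List[SimilarityHit] = []
    for a, b in sorted(ortholog_map.items()):
        ident = float(rng.uniform(70, 100))
        cov = float(rng.uniform(0.8, 1.0))
        aa = ref.gene(a).length // 3 - 1
        bit = 50.0 + aa * ident / 100.0
        ev = 10.0 ** -float(rng.uniform(30, 120))
        aln = max(1, int(aa * cov))
        fwd.append(SimilarityHit(a, b, ident, aln, bit, ev, cov))
        rev.append(SimilarityHit(b, a, ident, aln, bit, ev, cov))
    ref_ids = ref.gene_ids
    tgt_ids = target.gene_ids
    for _ in range(noise_hits):
        a = ref_ids[rng.integers(0, len(ref_ids))]
        b = tgt_ids[rng.integers(0, len(tgt_ids))]
        if ortholog_map.get(a) == b:
            continue
        ident = float(rng.uniform(20, 40))
        bit = float(rng.uniform(10, 40))
        hit_f = SimilarityHit(a, b, ident, 50, bit, 1e-3, float(rng.uniform(0.1, 0.5)))
        hit_r = SimilarityHit(b, a, ident, 50, bit, 1e-3, float(rng.uniform(0.1, 0.5)))
        fwd.append(hit_f)
        rev.append(hit_r)
    return fwd, rev


def random_similarity_instance(
    n_a: int, n_b: int, n_hits: int, seed: int = 1
) -> Tuple[List[SimilarityHit], List[SimilarityHit]]:
    """Unstructured random hit tables (both directions) for oracle testing.

    Bit scores are drawn from a small integer grid so ties are frequent and
    the documented tie-break chain is exercised.
    """
    rng = np.random.default_rng(seed)
    a_ids = [f"a{i}" for i in range(1, n_a + 1)]
    b_ids = [f"b{i}" for i in range(1, n_b + 1)]

    def _hits(qs, ss):
        out = []
        for _ in range(n_hits):
            q = qs[rng.integers(0, len(qs))]
            s = ss[rng.integers(0, len(ss))]
            bit = float(rng.integers(1, 8) * 25)
            ev = float(rng.integers(1, 4)) * 1e-10
            ident = float(rng.integers(50, 101))
            out.append(SimilarityHit(q, s, ident, 100, bit, ev, 1.0))
        return out

    return _hits(a_ids, b_ids), _hits(b_ids, a_ids)


def write_blast_tabular(hits: Sequence[SimilarityHit], path,
                        query_lengths: Dict[str, int]) -> None:
    """Serialise hits as 12-column tabular rows (dialect read by io.read_blast_tabular)."""
    rows = []
    for h in hits:
        qlen = query_lengths[h.query_id]
        qend = max(1, min(qlen, int(round(h.query_cov * qlen))))
        mism = int(round(h.aln_length * (100 - h.pct_identity) / 100))
        rows.append(
            f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t{h.aln_length}\t"
            f"{mism}\t0\t1\t{qend}\t1\t{qend}\t{h.e_value:.2g}\t{h.bit_score:.1f}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Trees and SNPs


def random_tree(
    labels: Sequence[str], seed: int = 1, bl_range: Tuple[float, float] = (0.005, 0.02)
) -> dendropy.Tree:
    """Random binary topology by sequential joins; uniform branch lengths."""
    if len(labels) < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    frags = list(labels)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        bi, bj = rng.uniform(*bl_range, size=2)
        merged = f"({frags[i]}:{bi:.6g},{frags[j]}:{bj:.6g})"
        frags = [f for k, f in enumerate(frags) if k not in (i, j)] + [merged]
    return dendropy.Tree.get(data=frags[0] + ";", schema="newick", preserve_underscores=True)


def true_effect(genome: GenomeRecord, position: int, alt: str) -> List[Tuple[Optional[str], str]]:
    """Ground-truth effect by whole-gene translation before vs after the
    substitution (independent of the codon-arithmetic classifier)."""
    seq = genome.sequence
    hits = [g for g in genome.genes if g.start <= position <= g.end]
    if not hits:
        return [(None, "intergenic")]
    out: List[Tuple[Optional[str], str]] = []
    for g in hits:
        gene_seq = seq[g.start - 1 : g.end]
        mut = seq[: position - 1] + alt + seq[position :]
        gene_mut = mut[g.start - 1 : g.end]
        if g.strand == REVERSE:
            gene_seq = reverse_complement(gene_seq)
            gene_mut = reverse_complement(gene_mut)
        usable = len(gene_seq) - len(gene_seq) % 3
        if "N" in gene_seq or "N" in gene_mut:
            out.append((g.gene_id, "unknown"))
            continue
        offset = (position - g.start) if g.strand == FORWARD else (g.end - position)
        if offset >= usable:
            out.append((g.gene_id, "unknown"))
            continue
        prot_ref = str(Seq(gene_seq[:usable]).translate(table=11))
        prot_alt = str(Seq(gene_mut[:usable]).translate(table=11))
        codon_i = offset // 3
        if prot_alt[codon_i] == "*" and prot_ref[codon_i] != "*":
            out.append((g.gene_id, "stop_gained"))
        elif prot_ref == prot_alt:
            out.append((g.gene_id, "synonymous"))
        else:
            out.append((g.gene_id, "nonsynonymous"))
    return out


def simulate_snps(
    genome: GenomeRecord,
    tree: dendropy.Tree,
    subs_per_site_per_branch: float = 1.0,
    seed: int = 1,
    record_effects: bool = True,
) -> Tuple[Dict[str, List[SnpRecord]], GroundTruth]:
    """Drop mutations along the tree's branches (Jukes-Cantor process).

    The root carries the reference sequence; each branch receives a Poisson
    number of events (rate x branch length x genome length) at uniform
    positions, each substituting a uniformly chosen different base. A site
    hit more than once on one root-to-leaf path keeps the last event
    (logged). Leaf SNP tables are the differences between each leaf
    haplotype and the reference.
    """
    if genome.sequence is None:
        raise ValueError("SNP simulation requires the reference sequence")
    if subs_per_site_per_branch < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    L = genome.length
    ref_arr = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    haplos: Dict[str, np.ndarray] = {}
    collisions = 0

    node_seq = {id(tree.seed_node): ref_arr}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = node_seq[id(node.parent_node)]
        bl = node.edge.length or 0.0
        n_mut = rng.poisson(subs_per_site_per_branch * bl * L)
        seq = parent.copy()
        if n_mut:
            pos = rng.integers(0, L, size=n_mut)
            collisions += n_mut - len(set(pos.tolist()))
            for p in pos:
                cur = seq[p].decode()
                others = [b for b in "ACGT" if b != cur]
                seq[p] = others[rng.integers(0, 3)].encode()
        node_seq[id(node)] = seq
        if node.is_leaf():
            haplos[node.taxon.label] = seq
    if collisions:
        logger.info("SNP simulation: %d same-branch site collisions (last event wins)", collisions)

    snp_tables: Dict[str, List[SnpRecord]] = {}
    effects: List[Tuple[str, int, Optional[str], str]] = []
    for strain in sorted(haplos):
        seq = haplos[strain]
        idx = np.nonzero(seq != ref_arr)[0]
        snps = [
            SnpRecord(
                strain_id=strain,
                position=int(i) + 1,
                ref_allele=ref_arr[i].decode(),
                alt_allele=seq[i].decode(),
            )
            for i in idx
        ]
        snp_tables[strain] = snps
        if record_effects:
            for s in snps:
                for gid, eff in true_effect(genome, s.position, s.alt_allele):
                    effects.append((strain, s.position, gid, eff))
    truth = GroundTruth(
        tree=tree,
        haplotypes={k: v.tobytes().decode() for k, v in haplos.items()},
        effects=effects,
        snp_tables=snp_tables,
        collisions=collisions,
    )
    return snp_tables, truth


# ---------------------------------------------------------------------------
# Demo dataset


def write_demo_dataset(outdir, seed: int = 1) -> Dict[str, str]:
    """Write a small complete dataset (1 reference + 2 derived genomes,
    20 strains with SNPs down a known tree) in every supported format.

    Returns a mapping of artefact names to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed)
    ref = make_genome(60, mean_gene_len=600, intergenic_len=120,
                      seed=rng_seed, genome_id="ref")
    paths: Dict[str, str] = {}

    mio.write_ptt(ref, outdir / "ref.ptt")
    mio.write_fasta({ref.genome_id: ref.sequence}, outdir / "ref.fasta")
    paths["ref_ptt"] = str(outdir / "ref.ptt")
    paths["ref_fasta"] = str(outdir / "ref.fasta")

    qlens_ref = {g.gene_id: g.length // 3 - 1 for g in ref.genes}
    for t, (k, prob) in enumerate([(4, 0.4), (6, 0.5)], start=1):
        tid = f"target{t}"
        target, truth = rearrange(ref, k, invert_prob=prob, seed=rng_seed + t, target_id=tid)
        mio.write_ptt(target, outdir / f"{tid}.ptt")
        mio.write_fasta({tid: target.sequence}, outdir / f"{tid}.fasta")
        pairs = perfect_pairs(truth.ortholog_map, tid, ref)
        mio.write_correspondence(pairs, outdir / f"{tid}.corr.tsv")
        fwd, rev = make_similarity_tables(ref, target, truth.ortholog_map, seed=rng_seed + t)
        qlens_tgt = {g.gene_id: g.length // 3 - 1 for g in target.genes}
        write_blast_tabular(fwd, outdir / f"ref_vs_{tid}.blast.tsv", qlens_ref)
        write_blast_tabular(rev, outdir / f"{tid}_vs_ref.blast.tsv", qlens_tgt)
        paths[f"{tid}_ptt"] = str(outdir / f"{tid}.ptt")
        paths[f"{tid}_fasta"] = str(outdir / f"{tid}.fasta")
        paths[f"{tid}_corr"] = str(outdir / f"{tid}.corr.tsv")
        paths[f"{tid}_blast_fwd"] = str(outdir / f"ref_vs_{tid}.blast.tsv")
        paths[f"{tid}_blast_rev"] = str(outdir / f"{tid}_vs_ref.blast.tsv")

    genome_tree = dendropy.Tree.get(data="(target2:0.1,target1:0.1);",
                                    schema="newick", preserve_underscores=True)
    mio.write_newick(genome_tree, outdir / "genomes.nwk")
    paths["genome_tree"] = str(outdir / "genomes.nwk")

    strains = [f"s{i:02d}" for i in range(1, 21)]
    strain_tree = random_tree(strains, seed=rng_seed + 10, bl_range=(0.002, 0.01))
    mio.write_newick(strain_tree, outdir / "strains.nwk")
    paths["strain_tree"] = str(outdir / "strains.nwk")

    snp_tables, truth = simulate_snps(ref, strain_tree, subs_per_site_per_branch=0.5,
                                      seed=rng_seed + 20)
    all_snps = [s for strain in strains for s in snp_tables[strain]]
    mio.write_snp_table(all_snps, outdir / "snps.tsv")
    paths["snps"] = str(outdir / "snps.tsv")

    metadata = [
        StrainMetadata(strain_id=s, attributes=(("group", "A" if i % 2 == 0 else "B"),
                                                ("site", f"site{i % 3 + 1}")))
        for i, s in enumerate(strains)
    ]
    mio.write_metadata(metadata, outdir / "metadata.tsv")
    paths["metadata"] = str(outdir / "metadata.tsv")

    # coverage track: uniform depth with one planted low-coverage island
    island = (20001, 23000)
    intervals = [(1, island[0] - 1, 50.0), (island[0], island[1], 1.0),
                 (island[1] + 1, ref.length, 50.0)]
    track = CoverageTrack(strain_id="s01", intervals=intervals)
    mio.write_bedgraph(track, outdir / "s01.bedgraph", chrom=ref.genome_id)
    paths["coverage"] = str(outdir / "s01.bedgraph")
    return paths
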