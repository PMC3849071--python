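"""Population-level SNP summaries.

Frequency spectra, per-gene / per-kb density maps, metadata-grouped counts,
artificial alignments (per-strain allele strings over all polymorphic
reference positions), p / Jukes-Cantor distances, neighbor-joining trees,
mutated-genome export, low-coverage interval detection and strain ordering.

Strains absent from the SNP table are treated as identical to the
reference (the tab-delimited input has no missing-data symbol), so every
requested strain gets a row in the artificial alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd

from .io import leaf_order
from .records import CoverageTrack, GenomeRecord, SnpRecord, StrainMetadata
from .snpeffect import locate

REFERENCE_ROW = "reference"
UNASSIGNED = "unassigned"

PER_GENE = "per_gene"
PER_KB = "per_kb"


# ---------------------------------------------------------------------------
# Frequency spectra


def frequency(snps: Iterable[SnpRecord], strains: Sequence[str]) -> Dict[int, Tuple[int, float]]:
    """Per polymorphic position: number and fraction of strains with a SNP there."""
    strain_set = set(strains)
    if not strain_set:
        raise ValueError("strain list must be non-empty")
    carriers: Dict[int, Set[str]] = {}
    for s in snps:
        if s.strain_id not in strain_set:
            raise ValueError(f"SNP strain {s.strain_id!r} not in the analysed strain set")
        carriers.setdefault(s.position, set()).add(s.strain_id)
    n = len(strain_set)
    return {pos: (len(c), len(c) / n) for pos, c in sorted(carriers.items())}


def write_frequency(spectrum: Mapping[int, Tuple[int, float]], path) -> None:
    rows = ["#position\tcount\tfraction"]
    for pos, (count, frac) in sorted(spectrum.items()):
        rows.append(f"{pos}\t{count}\t{frac:.6g}")
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Density maps


@dataclass
class DensityMap:
    """SNP counts per gene or per fixed kb window tiling the genome."""

    mode: str
    bins: List[Tuple[str, int]]
    scope: str = "all"

    def as_dict(self) -> Dict[str, int]:
        return dict(self.bins)

    @property
    def total(self) -> int:
        return sum(c for _, c in self.bins)


def density(
    snps: Iterable[SnpRecord],
    genome: GenomeRecord,
    mode: str = PER_GENE,
    window_kb: int = 1,
    group: Optional[Set[str]] = None,
    known_strains: Optional[Set[str]] = None,
    scope: str = "all",
) -> DensityMap:
    """SNP density along the reference.

    ``per_gene`` counts genic SNPs per gene (a SNP under two overlapping
    genes counts once for each). ``per_kb`` tiles [1, genome length] with
    fixed windows of ``window_kb * 1000`` bp (the last window may be short)
    and counts every SNP. ``group`` restricts to a strain subset;
    ``known_strains``, when given, validates the group against the analysed
    strain universe.
    """
    if mode not in (PER_GENE, PER_KB):
        raise ValueError(f"mode must be {PER_GENE!r} or {PER_KB!r}")
    if window_kb < 1:
        raise ValueError("window_kb must be >= 1")
    if group is not None and known_strains is not None:
        unknown = group - known_strains
        if unknown:
            raise ValueError(f"unknown strains in group: {sorted(unknown)}")
    snps = [s for s in snps if group is None or s.strain_id in group]
    if mode == PER_GENE:
        counts = {g.gene_id: 0 for g in genome.genes}
        for s in snps:
            _, gene_ids = locate(s, genome)
            for gid in gene_ids:
                counts[gid] += 1
        bins = [(g.gene_id, counts[g.gene_id]) for g in genome.genes]
    else:
        width = window_kb * 1000
        n_windows = max(1, math.ceil(genome.length / width))
        counts = [0] * n_windows
        for s in snps:
            if not (1 <= s.position <= genome.length):
                raise ValueError(f"SNP position {s.position} outside genome")
            counts[(s.position - 1) // width] += 1
        bins = []
        for i in range(n_windows):
            start = i * width + 1
            end = min((i + 1) * width, genome.length)
            bins.append((f"{start}-{end}", counts[i]))
    return DensityMap(mode=mode, bins=bins, scope=scope)


def group_density(
    snps: Sequence[SnpRecord],
    metadata: Sequence[StrainMetadata],
    attribute: str,
    genome: GenomeRecord,
    mode: str = PER_GENE,
    window_kb: int = 1,
) -> Dict[str, DensityMap]:
    """One density map per category of ``attribute``; strains lacking the
    attribute are collected under an explicit "unassigned" category."""
    known = {m.strain_id for m in metadata}
    groups: Dict[str, Set[str]] = {}
    for m in metadata:
        value = m.get(attribute)
        key = value if value not in (None, "", "-") else UNASSIGNED
        groups.setdefault(key, set()).add(m.strain_id)
    snp_strains = {s.strain_id for s in snps}
    stray = snp_strains - known
    if stray:
        groups.setdefault(UNASSIGNED, set()).update(stray)
    return {
        key: density(snps, genome, mode=mode, window_kb=window_kb,
                     group=members, scope=key)
        for key, members in sorted(groups.items())
    }


def write_density(dm: DensityMap, path) -> None:
    rows = [f"#key\tcount\t(mode={dm.mode}, scope={dm.scope})"]
    rows += [f"{key}\t{count}" for key, count in dm.bins]
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Artificial alignments


@dataclass
class ArtificialAlignment:
    """Strains x polymorphic-positions allele matrix (reference row first).

    Cell = the strain's alt allele where it has a SNP, else the reference
    allele; the reference row carries the reference allele at every column.
    """

    positions: List[int]
    strains: List[str]
    alleles: np.ndarray  # dtype '<U1', shape (len(strains), len(positions))

    def row(self, strain_id: str) -> str:
        i = self.strains.index(strain_id)
        return "".join(self.alleles[i])

    def to_fasta_dict(self) -> Dict[str, str]:
        return {s: "".join(self.alleles[i]) for i, s in enumerate(self.strains)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.alleles, index=pd.Index(self.strains, name="strain"),
            columns=self.positions,
        )


def artificial_alignment(
    snps: Iterable[SnpRecord],
    strains: Sequence[str],
    genome: GenomeRecord,
    gene_subset: Optional[Sequence[str]] = None,
    include_reference: bool = True,
) -> ArtificialAlignment:
    """Concatenated alleles at every polymorphic position, per strain.

    Columns are the sorted union of SNP positions across the chosen strains,
    optionally restricted to positions inside ``gene_subset`` genes. A strain
    with zero SNPs still gets a row of reference alleles.
    """
    if genome.sequence is None:
        raise ValueError("artificial alignment requires the reference sequence")
    strain_list = list(dict.fromkeys(strains))
    strain_set = set(strain_list)
    chosen = [s for s in snps if s.strain_id in strain_set]
    if gene_subset is not None:
        spans = [(genome.gene(g).start, genome.gene(g).end) for g in gene_subset]
        chosen = [s for s in chosen if any(a <= s.position <= b for a, b in spans)]
    positions = sorted({s.position for s in chosen})
    by_strain: Dict[str, Dict[int, str]] = {s: {} for s in strain_list}
    for s in chosen:
        prev = by_strain[s.strain_id].get(s.position)
        if prev is not None and prev != s.alt_allele:
            raise ValueError(
                f"conflicting SNPs for strain {s.strain_id} at position {s.position}"
            )
        by_strain[s.strain_id][s.position] = s.alt_allele
    ref_alleles = [genome.sequence[p - 1] for p in positions]
    rows = [REFERENCE_ROW] + strain_list if include_reference else list(strain_list)
    mat = np.empty((len(rows), len(positions)), dtype="<U1")
    for i, sid in enumerate(rows):
        if sid == REFERENCE_ROW and include_reference:
            mat[i] = ref_alleles
        else:
            alts = by_strain[sid]
            mat[i] = [alts.get(p, ref) for p, ref in zip(positions, ref_alleles)]
    return ArtificialAlignment(positions=positions, strains=rows, alleles=mat)


# ---------------------------------------------------------------------------
# Distances and trees

P_DISTANCE = "p_distance"
JUKES_CANTOR = "jukes_cantor"


def distances(alignment: ArtificialAlignment, model: str = P_DISTANCE) -> pd.DataFrame:
    """Pairwise distance matrix over alignment rows.

    p-distance = fraction of mismatching columns; Jukes-Cantor corrects for
    multiple hits: d = -(3/4) ln(1 - 4p/3), undefined for p >= 3/4.
    """
    if model not in (P_DISTANCE, JUKES_CANTOR):
        raise ValueError(f"unknown distance model {model!r}")
    if len(alignment.strains) < 2:
        raise ValueError("need at least 2 rows to compute distances")
    n_cols = len(alignment.positions)
    if n_cols == 0:
        raise ValueError("distance undefined on a zero-column alignment")
    mat = alignment.alleles
    n = len(alignment.strains)
    d = np.zeros((n, n))
    for i in range(n):
        diff = (mat[i + 1 :] != mat[i]).sum(axis=1) / n_cols
        d[i, i + 1 :] = diff
        d[i + 1 :, i] = diff
    if model == JUKES_CANTOR:
        if np.any(d >= 0.75):
            raise ValueError("Jukes-Cantor distance undefined: p-distance >= 3/4")
        d = -0.75 * np.log1p(-(4.0 / 3.0) * d)
        np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=alignment.strains, columns=alignment.strains)


def p_distance_to_reference(alignment: ArtificialAlignment) -> Dict[str, float]:
    if REFERENCE_ROW not in alignment.strains:
        raise ValueError("alignment has no reference row")
    d = distances(alignment, model=P_DISTANCE)
    return {
        s: float(d.loc[REFERENCE_ROW, s])
        for s in alignment.strains
        if s != REFERENCE_ROW
    }


def build_tree(distance_matrix: pd.DataFrame, method: str = "neighbor_joining") -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Deterministic: when several pairs minimise the Q criterion, the pair
    with the smallest (row, column) index in the current label order is
    joined. Returns an unrooted dendropy tree whose leaf set equals the
    matrix labels. Requires n >= 3.
    """
    if method != "neighbor_joining":
        raise ValueError(f"unknown tree method {method!r}")
    labels = list(distance_matrix.index)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = distance_matrix.to_numpy(dtype=float).copy()
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")

    nodes: List[str] = []  # newick fragments per active node
    frags = [lab for lab in labels]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) in current ordering
        flat = np.argmin(q)
        i, j = divmod(int(flat), m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        ai, aj = active[i], active[j]
        new_frag = f"({frags[ai]}:{li:.10g},{frags[aj]}:{lj:.10g})"
        # distances from the new node to every remaining node
        new_row = 0.5 * (d[ai, :] + d[aj, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        frags.append(new_frag)
        new_idx = d.shape[0] - 1
        active = [a for a in active if a not in (ai, aj)] + [new_idx]

    a, b = active
    lab = d[a, b]
    newick = f"({frags[a]}:{lab / 2:.10g},{frags[b]}:{lab / 2:.10g});"
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def write_phylip(distance_matrix: pd.DataFrame, path) -> None:
    """PHYLIP-style square distance matrix."""
    labels = list(distance_matrix.index)
    rows = [f"{len(labels)}"]
    for lab in labels:
        vals = " ".join(f"{distance_matrix.loc[lab, c]:.6f}" for c in labels)
        rows.append(f"{lab}  {vals}")
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Sequence export


def mutate_sequence(reference_sequence: str, strain_snps: Sequence[SnpRecord]) -> str:
    """Apply one strain's SNPs to the reference; length is preserved."""
    seq = list(reference_sequence.upper())
    seen: Dict[int, str] = {}
    for s in strain_snps:
        if not (1 <= s.position <= len(seq)):
            raise ValueError(f"SNP position {s.position} outside sequence")
        if seq[s.position - 1] != s.ref_allele:
            raise ValueError(
                f"SNP ref allele {s.ref_allele} at {s.position} disagrees with "
                f"reference base {seq[s.position - 1]}"
            )
        if s.position in seen and seen[s.position] != s.alt_allele:
            raise ValueError(f"conflicting SNPs at position {s.position}")
        seen[s.position] = s.alt_allele
    for pos, alt in seen.items():
        seq[pos - 1] = alt
    return "".join(seq)


def diff_sequences(reference: str, mutated: str) -> List[Tuple[int, str, str]]:
    """(position, ref base, alt base) for every differing site (the SNP-calling oracle)."""
    if len(reference) != len(mutated):
        raise ValueError("sequences differ in length")
    ref = np.frombuffer(reference.encode(), dtype="S1")
    mut = np.frombuffer(mutated.encode(), dtype="S1")
    idx = np.nonzero(ref != mut)[0]
    return [(int(i) + 1, reference[i], mutated[i]) for i in idx]


# ---------------------------------------------------------------------------
# Coverage heterogeneity


def coverage_anomalies(
    track: CoverageTrack,
    low_threshold: float,
    min_span: int,
    genome_length: Optional[int] = None,
) -> List[Tuple[int, int]]:
    """Maximal intervals with depth below ``low_threshold`` spanning at least
    ``min_span`` bp — candidate absent regions / genomic islands.

    Bases not covered by any interval count as depth 0. ``genome_length``
    extends the scanned range beyond the last interval when given.
    """
    if low_threshold < 0 or min_span < 0:
        raise ValueError("thresholds must be >= 0")
    end_of_range = max(
        genome_length or 0, max((e for _, e, _ in track.intervals), default=0)
    )
    if end_of_range == 0:
        return []
    # walk intervals + implicit zero-depth gaps, merging consecutive low runs
    events: List[Tuple[int, int, float]] = []
    cursor = 1
    for start, end, depth in track.intervals:
        if start > cursor:
            events.append((cursor, start - 1, 0.0))
        events.append((start, end, depth))
        cursor = end + 1
    if cursor <= end_of_range:
        events.append((cursor, end_of_range, 0.0))

    out: List[Tuple[int, int]] = []
    run_start: Optional[int] = None
    run_end = 0
    for start, end, depth in events:
        if depth < low_threshold:
            if run_start is None:
                run_start = start
            run_end = end
        else:
            if run_start is not None and run_end - run_start + 1 >= min_span:
                out.append((run_start, run_end))
            run_start = None
    if run_start is not None and run_end - run_start + 1 >= min_span:
        out.append((run_start, run_end))
    return out


# ---------------------------------------------------------------------------
# Strain ordering


def order_strains(
    strains: Sequence[str],
    by: str = "tree",
    tree: Optional[dendropy.Tree] = None,
    alignment: Optional[ArtificialAlignment] = None,
) -> List[str]:
    """Order strains for display.

    ``tree`` mode follows the tree's leaf order (every strain must be a
    leaf). ``autoscore`` mode sorts strains by ascending p-distance to the
    reference row of the artificial alignment, ties broken lexicographically,
    so strains most similar to the reference come first.
    """
    strains = list(strains)
    if by == "tree":
        if tree is None:
            raise ValueError("tree ordering requires a tree")
        leaves = leaf_order(tree)
        missing = set(strains) - set(leaves)
        if missing:
            raise ValueError(f"tree is missing strains: {sorted(missing)}")
        wanted = set(strains)
        return [l for l in leaves if l in wanted]
    if by == "autoscore":
        if alignment is None:
            raise ValueError("autoscore ordering requires an artificial alignment")
        score = p_distance_to_reference(alignment)
        missing = set(strains) - set(score)
        if missing:
            raise ValueError(f"alignment is missing strains: {sorted(missing)}")
        return sorted(strains, key=lambda s: (score[s], s))
    raise ValueError(f"unknown ordering mode {by!r}")
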