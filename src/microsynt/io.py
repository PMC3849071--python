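"""Readers and writers for every external format the engine touches.

Tab-delimited dialects defined here (correspondence, SNP, metadata tables)
use a leading ``#`` header line, ``.`` decimals and no locale formatting, so
outputs are byte-stable across runs. bedGraph is 0-based half-open on disk
and converted to 1-based inclusive coordinates in memory.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    FORWARD,
    REVERSE,
    CoverageTrack,
    GeneAnnotation,
    GenomeRecord,
    OrthologPair,
    RecordError,
    SimilarityHit,
    SnpRecord,
    StrainMetadata,
)

logger = logging.getLogger(__name__)

CORRESPONDENCE_HEADER = (
    "#ref_gene_id\ttarget_genome_id\ttarget_gene_id\tpct_identity\t"
    "query_cov\tbit_score\te_value"
)
SNP_HEADER = "#strain_id\tposition\tref_allele\talt_allele\tcoverage"


class ParseError(ValueError):
    """A file does not conform to its declared format; the message names the line."""


def _err(path, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# ptt (GenBank protein table)

_LOCATION_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def read_ptt(path, sequence: Optional[str] = None, genome_id: Optional[str] = None) -> GenomeRecord:
    """Read a GenBank ptt protein table into a :class:`GenomeRecord`.

    Layout: a free-text title line, an "N proteins" line, a column header
    row, then tab-separated data rows whose Location field is "start..end".
    Genome length is taken from ``sequence`` when supplied, else from a
    "1..N" range on the title line, else from the maximal gene end.
    Origin-wrapping genes (start > end) are rejected: ptt cannot represent
    them unambiguously.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated ptt file (need title, count and header lines)")
    title = lines[0].strip()
    genes: List[GeneAnnotation] = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise _err(path, lineno, f"expected 9 tab-separated columns, found {len(fields)}")
        loc, strand, _length, pid, gene_name, synonym = fields[:6]
        product = fields[8]
        m = _LOCATION_RE.match(loc.strip())
        if not m:
            raise _err(path, lineno, f"malformed Location field {loc!r} (expected start..end)")
        start, end = int(m.group(1)), int(m.group(2))
        if start > end:
            raise _err(
                path, lineno,
                f"Location {loc!r} has start > end (origin-wrapping genes are unsupported)",
            )
        if strand not in ("+", "-"):
            raise _err(path, lineno, f"bad Strand field {strand!r}")
        genes.append(
            GeneAnnotation(
                gene_id=synonym,
                start=start,
                end=end,
                strand=FORWARD if strand == "+" else REVERSE,
                name=gene_name,
                product=product,
                pid=pid,
            )
        )
    length = 0
    if sequence is None:
        m = re.search(r"\b1\.\.(\d+)\s*$", title)
        if m:
            length = int(m.group(1))
    return GenomeRecord(
        genome_id=genome_id or path.stem,
        genes=genes,
        length=length,
        sequence=sequence,
        description=title,
    )


def write_ptt(genome: GenomeRecord, path) -> None:
    """Write a GenomeRecord as a ptt table (Length column = protein length in aa)."""
    rows = [f"{genome.description or genome.genome_id} - 1..{genome.length}",
            f"{len(genome.genes)} proteins",
            "Location\tStrand\tLength\tPID\tGene\tSynonym\tCode\tCOG\tProduct"]
    for g in genome.genes:
        aa_len = g.length // 3 - 1  # protein length excludes the stop codon
        strand = "+" if g.strand == FORWARD else "-"
        rows.append(
            f"{g.start}..{g.end}\t{strand}\t{aa_len}\t{g.pid}\t{g.name}\t{g.gene_id}\t-\t-\t{g.product}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    """Read FASTA into an id -> uppercase sequence mapping; duplicate ids are errors."""
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA identifier {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records: Mapping[str, str], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# BLAST tabular (12-column dialect)


def read_blast_tabular(path, query_lengths: Optional[Mapping[str, int]] = None) -> List[SimilarityHit]:
    """Read 12-column tabular similarity reports.

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore. ``query_lengths`` (protein
    lengths, same unit as qstart/qend) enables coverage computation:
    query_cov = (qend - qstart + 1) / query length, clamped to [0, 1].
    Without lengths, coverage defaults to 1.0.
    """
    hits: List[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise _err(path, lineno, f"expected 12 columns, found {len(fields)}")
            try:
                pident = float(fields[2])
                aln_len = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise _err(path, lineno, f"non-numeric field: {exc}") from None
            cov = 1.0
            if query_lengths is not None:
                qlen = query_lengths.get(fields[0])
                if qlen:
                    cov = min(1.0, max(0.0, (qend - qstart + 1) / qlen))
            hits.append(
                SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=pident,
                    aln_length=aln_len,
                    bit_score=bitscore,
                    e_value=evalue,
                    query_cov=cov,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Correspondence (ortholog pair) tables


def read_correspondence(path) -> List[OrthologPair]:
    pairs: List[OrthologPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise _err(path, lineno, f"expected 7 columns, found {len(fields)}")
            try:
                pairs.append(
                    OrthologPair(
                        ref_gene_id=fields[0],
                        target_genome_id=fields[1],
                        target_gene_id=fields[2],
                        pct_identity=float(fields[3]),
                        query_cov=float(fields[4]),
                        bit_score=float(fields[5]),
                        e_value=float(fields[6]),
                    )
                )
            except ValueError as exc:
                raise _err(path, lineno, f"non-numeric field: {exc}") from None
    return pairs


def write_correspondence(pairs: Iterable[OrthologPair], path) -> None:
    rows = [CORRESPONDENCE_HEADER]
    for p in pairs:
        rows.append(
            f"{p.ref_gene_id}\t{p.target_genome_id}\t{p.target_gene_id}\t"
            f"{p.pct_identity:g}\t{p.query_cov:g}\t{p.bit_score:g}\t{p.e_value:g}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# SNP tables


def read_snp_table(path, reference: Optional[GenomeRecord] = None) -> List[SnpRecord]:
    """Read a tab-delimited SNP table; validates alleles against ``reference`` if given."""
    snps: List[SnpRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (4, 5):
                raise _err(path, lineno, f"expected 4 or 5 columns, found {len(fields)}")
            try:
                pos = int(fields[1])
                cov = int(fields[4]) if len(fields) == 5 and fields[4] not in ("", "-") else None
            except ValueError as exc:
                raise _err(path, lineno, f"non-numeric field: {exc}") from None
            try:
                snp = SnpRecord(
                    strain_id=fields[0],
                    position=pos,
                    ref_allele=fields[2].upper(),
                    alt_allele=fields[3].upper(),
                    coverage=cov,
                )
            except RecordError as exc:
                raise _err(path, lineno, str(exc)) from None
            if reference is not None:
                if snp.position > reference.length:
                    raise _err(
                        path, lineno,
                        f"position {snp.position} beyond reference length {reference.length}",
                    )
                if reference.sequence is not None:
                    base = reference.sequence[snp.position - 1]
                    if base != snp.ref_allele:
                        raise _err(
                            path, lineno,
                            f"ref allele {snp.ref_allele} at position {snp.position} "
                            f"disagrees with reference base {base}",
                        )
            snps.append(snp)
    return snps


def write_snp_table(snps: Iterable[SnpRecord], path) -> None:
    rows = [SNP_HEADER]
    for s in snps:
        cov = "" if s.coverage is None else str(s.coverage)
        row = f"{s.strain_id}\t{s.position}\t{s.ref_allele}\t{s.alt_allele}"
        rows.append(row + (f"\t{cov}" if cov else ""))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Strain metadata


def read_metadata(path) -> List[StrainMetadata]:
    """Tab-delimited metadata: header row (strain_id then attribute names), one row per strain."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        return []
    header = lines[0].lstrip("#").split("\t")
    attr_names = header[1:]
    out: List[StrainMetadata] = []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise _err(path, lineno, f"expected {len(header)} columns, found {len(fields)}")
        sid = fields[0]
        if sid in seen:
            raise _err(path, lineno, f"duplicate strain_id {sid!r}")
        seen.add(sid)
        out.append(StrainMetadata(strain_id=sid, attributes=tuple(zip(attr_names, fields[1:]))))
    return out


def write_metadata(strains: Sequence[StrainMetadata], path) -> None:
    if not strains:
        Path(path).write_text("strain_id\n")
        return
    attr_names = [a for a, _ in strains[0].attributes]
    rows = ["strain_id\t" + "\t".join(attr_names)]
    for s in strains:
        rows.append(s.strain_id + "\t" + "\t".join(s.get(a, "") or "" for a in attr_names))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# bedGraph coverage


def read_bedgraph(path, strain_id: Optional[str] = None) -> CoverageTrack:
    """Read a bedGraph track (0-based half-open) into 1-based inclusive intervals."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise _err(path, lineno, f"expected 4 columns, found {len(fields)}")
            try:
                start0, end0, depth = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise _err(path, lineno, f"non-numeric field: {exc}") from None
            if end0 <= start0:
                raise _err(path, lineno, f"empty or inverted interval {start0}-{end0}")
            intervals.append((start0 + 1, end0, depth))
    try:
        return CoverageTrack(strain_id=strain_id or path.stem, intervals=intervals)
    except RecordError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_bedgraph(track: CoverageTrack, path, chrom: str = "reference") -> None:
    rows = [f"{chrom}\t{s - 1}\t{e}\t{d:g}" for s, e, d in track.intervals]
    Path(path).write_text("\n".join(rows) + "\n")


def write_bed(intervals: Sequence, path, chrom: str = "reference") -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open) lines."""
    rows = [f"{chrom}\t{s - 1}\t{e}" for s, e in intervals]
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"{path}: invalid Newick: {exc}") from None


def parse_newick(text: str) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from None


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip()


def leaf_order(tree: dendropy.Tree) -> List[str]:
    """Leaf labels in the tree's left-to-right drawing order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Gene table export


def export_gene_table(genome: GenomeRecord, selection: Iterable[str], path,
                      sort_by: str = "start") -> None:
    """Write selected genes as a tab-delimited table, stably sorted by ``sort_by``.

    Ties on the sort column are broken by gene_id, so output is
    byte-identical across runs.
    """
    valid = {"start", "end", "gene_id", "name", "strand", "length"}
    if sort_by not in valid:
        raise ValueError(f"sort_by must be one of {sorted(valid)}")
    ids = list(selection)
    genes = [genome.gene(i) for i in ids]  # KeyError on unknown gene_id
    genes.sort(key=lambda g: (getattr(g, sort_by), g.gene_id))
    rows = ["#gene_id\tname\tstart\tend\tstrand\tproduct"]
    for g in genes:
        rows.append(f"{g.gene_id}\t{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{g.product}")
    Path(path).write_text("\n".join(rows) + "\n")
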