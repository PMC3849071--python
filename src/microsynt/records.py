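"""Core domain records shared across the engine.

All genomic coordinates in memory are 1-based and inclusive at both ends,
matching the GenBank ptt ``Location`` convention. Formats with other
conventions (bedGraph, BED) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

FORWARD = "forward"
REVERSE = "reverse"

VALID_BASES = frozenset("ACGT")
VALID_SEQ_CHARS = frozenset("ACGTN")


class RecordError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One protein-coding gene on a replicon.

    ``gene_id`` is the unique locus identifier (ptt "Synonym" column);
    ``name`` is the gene symbol, "-" when absent.
    """

    gene_id: str
    start: int
    end: int
    strand: str
    name: str = "-"
    product: str = "-"
    pid: str = "-"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise RecordError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end} "
                "(need 1 <= start <= end)"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise RecordError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeRecord:
    """A reference or target replicon: ordered gene annotations, optional sequence."""

    genome_id: str
    genes: List[GeneAnnotation] = field(default_factory=list)
    length: int = 0
    sequence: Optional[str] = None
    description: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise RecordError(f"duplicate gene_id {g.gene_id!r} in {self.genome_id}")
            seen.add(g.gene_id)
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            bad = set(self.sequence) - VALID_SEQ_CHARS
            if bad:
                raise RecordError(
                    f"{self.genome_id}: sequence contains invalid characters {sorted(bad)}"
                )
            if self.length == 0:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise RecordError(
                    f"{self.genome_id}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        if self.length == 0 and self.genes:
            self.length = max(g.end for g in self.genes)
        for g in self.genes:
            if g.end > self.length:
                raise RecordError(
                    f"gene {g.gene_id} ends at {g.end}, beyond genome length {self.length}"
                )

    def gene(self, gene_id: str) -> GeneAnnotation:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"unknown gene_id {gene_id!r} in genome {self.genome_id}")

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def gene_index(self, gene_id: str) -> int:
        """Rank of a gene in chromosomal (start-coordinate) order."""
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(f"unknown gene_id {gene_id!r} in genome {self.genome_id}")


@dataclass(frozen=True)
class SimilarityHit:
    """One row of an all-against-all protein similarity report."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    bit_score: float
    e_value: float
    query_cov: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise RecordError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if not (0.0 <= self.query_cov <= 1.0):
            raise RecordError(f"query_cov {self.query_cov} outside [0, 1]")
        if self.e_value < 0:
            raise RecordError(f"negative e-value {self.e_value}")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best protein correspondence between a reference gene and a target gene."""

    ref_gene_id: str
    target_genome_id: str
    target_gene_id: str
    pct_identity: float = 100.0
    query_cov: float = 1.0
    bit_score: float = 0.0
    e_value: float = 0.0


@dataclass(frozen=True)
class SnpRecord:
    """A strain's single-nucleotide difference from the reference."""

    strain_id: str
    position: int
    ref_allele: str
    alt_allele: str
    coverage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise RecordError(
                f"SNP {self.strain_id}@{self.position}: alleles must be A/C/G/T, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise RecordError(
                f"SNP {self.strain_id}@{self.position}: ref and alt alleles are identical"
            )
        if self.position < 1:
            raise RecordError(f"SNP position {self.position} < 1")


@dataclass(frozen=True)
class StrainMetadata:
    strain_id: str
    attributes: Tuple[Tuple[str, str], ...]

    def get(self, attribute: str, default: Optional[str] = None) -> Optional[str]:
        return dict(self.attributes).get(attribute, default)


@dataclass
class CoverageTrack:
    """Per-strain read-depth intervals, 1-based inclusive, sorted, non-overlapping."""

    strain_id: str
    intervals: List[Tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals)
        prev_end = 0
        for start, end, depth in self.intervals:
            if start <= prev_end:
                raise RecordError(
                    f"coverage track {self.strain_id}: overlapping interval at {start}"
                )
            if start > end:
                raise RecordError(
                    f"coverage track {self.strain_id}: inverted interval {start}..{end}"
                )
            if depth < 0:
                raise RecordError(f"coverage track {self.strain_id}: negative depth at {start}")
            prev_end = end


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
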