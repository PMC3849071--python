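"""SNP location and coding-effect annotation.

Each SNP is located relative to the reference annotation (inside a gene or
intergenic) and, for genic positions, classified by its effect on the
encoded protein under the bacterial/archaeal genetic code (NCBI translation
table 11): synonymous, nonsynonymous or stop_gained. Stop-loss is folded
into nonsynonymous; the raw codons and amino acids are carried in the
output so users can re-bin. SNPs inside overlapping genes are annotated
once per gene.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple

from Bio.Seq import Seq

from .records import FORWARD, GeneAnnotation, GenomeRecord, SnpRecord, reverse_complement

logger = logging.getLogger(__name__)

GENIC = "genic"
INTERGENIC = "intergenic"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
STOP_GAINED = "stop_gained"
EFFECT_INTERGENIC = "intergenic"
UNKNOWN = "unknown"

TRANSLATION_TABLE = 11


@dataclass(frozen=True)
class SnpAnnotation:
    """A SNP's location class and per-gene coding effect."""

    snp: SnpRecord
    location: str
    gene_id: Optional[str] = None
    effect: str = EFFECT_INTERGENIC
    codon_index: Optional[int] = None
    codon_position: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None


def locate(snp: SnpRecord, genome: GenomeRecord) -> Tuple[str, List[str]]:
    """All genes overlapping the SNP position (interval stabbing by binary search).

    Returns ``(location, gene_ids)``; genic iff at least one gene overlaps.
    """
    if not (1 <= snp.position <= genome.length):
        raise ValueError(
            f"SNP position {snp.position} outside reference [1, {genome.length}]"
        )
    starts = [g.start for g in genome.genes]
    hi = bisect.bisect_right(starts, snp.position)
    # genes start-sorted; scan left while earlier genes might still span the position
    hits = []
    max_len = max((g.length for g in genome.genes), default=0)
    lo = bisect.bisect_left(starts, snp.position - max_len)
    for g in genome.genes[lo:hi]:
        if g.start <= snp.position <= g.end:
            hits.append(g.gene_id)
    return (GENIC, hits) if hits else (INTERGENIC, [])


def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=TRANSLATION_TABLE))


def classify(snp: SnpRecord, gene: GeneAnnotation, sequence: str) -> SnpAnnotation:
    """Codon-level effect of a genic SNP on one gene.

    The reading frame is anchored at the gene's start codon (its 5' end on
    its own strand). For reverse-strand genes, offsets are measured from the
    gene end and both codons are reverse-complemented before translation.
    Positions past the last full codon of a length-not-divisible-by-3 gene,
    and codons containing N, are classified ``unknown`` and logged.
    """
    if not (gene.start <= snp.position <= gene.end):
        raise ValueError(
            f"SNP at {snp.position} is outside gene {gene.gene_id} "
            f"({gene.start}..{gene.end})"
        )
    ref_base = sequence[snp.position - 1]
    if ref_base != snp.ref_allele:
        raise ValueError(
            f"SNP ref allele {snp.ref_allele} at {snp.position} disagrees with "
            f"reference base {ref_base}"
        )
    if gene.length % 3 != 0:
        logger.warning(
            "gene %s length %d not divisible by 3; reading frame anchored at start codon",
            gene.gene_id, gene.length,
        )
    if gene.strand == FORWARD:
        offset = snp.position - gene.start  # 0-based within gene, 5'->3'
    else:
        offset = gene.end - snp.position
    codon_index = offset // 3 + 1
    codon_position = offset % 3 + 1

    if codon_index * 3 > gene.length:  # past the last full codon (frame artefact)
        logger.warning(
            "SNP at %d falls past the last full codon of gene %s; effect unknown",
            snp.position, gene.gene_id,
        )
        return SnpAnnotation(
            snp=snp, location=GENIC, gene_id=gene.gene_id, effect=UNKNOWN,
            codon_index=codon_index, codon_position=codon_position,
        )

    if gene.strand == FORWARD:
        cstart = gene.start + (codon_index - 1) * 3
        ref_codon = sequence[cstart - 1 : cstart + 2]
        within = codon_position - 1
        alt_codon = ref_codon[:within] + snp.alt_allele + ref_codon[within + 1 :]
    else:
        cend = gene.end - (codon_index - 1) * 3
        genomic = sequence[cend - 3 : cend]
        ref_codon = reverse_complement(genomic)
        within = codon_position - 1
        alt_genomic = (
            genomic[: 3 - within - 1] + snp.alt_allele + genomic[3 - within :]
        )
        alt_codon = reverse_complement(alt_genomic)

    if "N" in ref_codon or "N" in alt_codon:
        logger.warning("ambiguous base in codon at SNP %d (gene %s)", snp.position, gene.gene_id)
        return SnpAnnotation(
            snp=snp, location=GENIC, gene_id=gene.gene_id, effect=UNKNOWN,
            codon_index=codon_index, codon_position=codon_position,
            ref_codon=ref_codon, alt_codon=alt_codon,
        )

    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    if alt_aa == "*" and ref_aa != "*":
        effect = STOP_GAINED
    elif ref_aa == alt_aa:
        effect = SYNONYMOUS
    else:
        effect = NONSYNONYMOUS  # includes stop-loss
    return SnpAnnotation(
        snp=snp, location=GENIC, gene_id=gene.gene_id, effect=effect,
        codon_index=codon_index, codon_position=codon_position,
        ref_codon=ref_codon, alt_codon=alt_codon, ref_aa=ref_aa, alt_aa=alt_aa,
    )


def annotate_all(snps: Iterable[SnpRecord], genome: GenomeRecord) -> List[SnpAnnotation]:
    """One annotation per (SNP x overlapping gene), plus one intergenic
    annotation for non-genic SNPs, ordered by (position, strain, gene)."""
    if genome.sequence is None:
        raise ValueError("effect annotation requires the reference sequence")
    out: List[SnpAnnotation] = []
    for snp in snps:
        location, gene_ids = locate(snp, genome)
        if location == INTERGENIC:
            out.append(SnpAnnotation(snp=snp, location=INTERGENIC))
        else:
            for gid in gene_ids:
                out.append(classify(snp, genome.gene(gid), genome.sequence))
    out.sort(key=lambda a: (a.snp.position, a.snp.strain_id, a.gene_id or ""))
    return out


def write_annotations(annotations: Iterable[SnpAnnotation], path) -> None:
    rows = [
        "#strain_id\tposition\tref_allele\talt_allele\tlocation\tgene_id\t"
        "codon_index\tcodon_position\tref_codon\talt_codon\tref_aa\talt_aa\teffect"
    ]
    for a in annotations:
        s = a.snp
        rows.append(
            "\t".join(
                str(x) if x is not None else "-"
                for x in (
                    s.strain_id, s.position, s.ref_allele, s.alt_allele, a.location,
                    a.gene_id, a.codon_index, a.codon_position, a.ref_codon,
                    a.alt_codon, a.ref_aa, a.alt_aa, a.effect,
                )
            )
        )
    from pathlib import Path

    Path(path).write_text("\n".join(rows) + "\n")
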