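# microsynt

A scriptable engine for comparative microbial genomics. It reproduces, as
plain data products, the computations behind interactive multi-genome
browsers: one **reference** genome is compared with *n* related genomes
(orthology, synteny, phylogenetic profiles) and with *n* re-sequenced
strains (SNP annotation, density maps, frequency spectra, SNP phylogenies).
It is aimed at bioinformaticians analysing bacterial strain collections who
want the numbers and tables behind the pictures — every result is a
tab-delimited file, FASTA, BED or Newick tree that downstream tools can
consume.

## What it computes

- **Orthology** by bi-directional best hits (BDBH): genes *a* (reference)
  and *b* (target) are orthologs iff *b* = argmax score(*a*, ·) and
  *a* = argmax score(·, *b*) in an all-against-all protein similarity
  search. Ties are broken deterministically (bit score, then E-value, then
  % identity, then subject id).
- **Synteny blocks**: maximal chains of ortholog pairs whose reference gene
  indices increase and whose target indices move monotonically in one
  direction (collinear or inverted), with at most `max_gap` skipped genes;
  plus dot-plot points, line-plot segments, local alignment offsets and
  rectangular region selections (gene baskets).
- **Phylogenetic profiles**: reference-gene × genome matrices of
  (% identity, query coverage), columns ordered by a phylogeny, with
  keyword / threshold / basket filters. Orphan genes are absent cells.
- **SNP annotation**: location (genic/intergenic by interval stabbing) and
  coding effect under the bacterial genetic code (translation table 11) —
  synonymous, nonsynonymous or stop_gained, with codon index/position and
  both codons reported; reverse-strand genes handled by mirroring.
- **Population summaries**: per-gene and per-kb SNP density,
  metadata-grouped differential counts, per-position frequency spectra.
- **SNP phylogenies**: the *artificial sequence* of each strain
  (concatenated alleles at all polymorphic positions), p-distances
  (*p* = mismatched columns / columns) or Jukes–Cantor distances
  (*d* = −¾ ln(1 − 4*p*/3)), and neighbor-joining trees with a documented
  deterministic tie-break.
- **Coverage heterogeneity**: maximal low-coverage intervals from bedGraph
  tracks (candidate absent regions / genomic islands), exported as BED.
- **A simulator** that generates all of the above inputs with recorded
  ground truth: ORF-valid genomes, rearranged derivatives with a planted
  segment structure, similarity tables with a planted mutual-best map, and
  SNPs dropped down a known tree under a Jukes–Cantor process.

Formats: GenBank ptt for annotation, FASTA for sequence, 12-column tabular
similarity reports, tab-delimited correspondence/SNP/metadata tables,
bedGraph (0-based half-open, converted to the engine's 1-based inclusive
coordinates) and Newick. SNPs are inputs — they must be called upstream.

## Worked example

```sh
microsynt simulate --demo --seed 1 --out demo
microsynt synteny --pairs demo/target1.corr.tsv --ref-ptt demo/ref.ptt \
    --target-ptt demo/target1.ptt --target-id target1 --out out_syn
microsynt annotate --snps demo/snps.tsv --ref-ptt demo/ref.ptt \
    --ref-fasta demo/ref.fasta --out out_ann
microsynt coverage --bedgraph demo/s01.bedgraph --low-threshold 5 \
    --min-span 1000 --out out_cov
```

prints

```
demo dataset written to demo
4 blocks, 0 unchained pairs
intergenic=2337, nonsynonymous=6566, stop_gained=380, synonymous=2076
1 low-coverage intervals
```

The demo reference has 60 genes; `target1` was built by cutting it into 4
oriented segments, so the chainer reports exactly 4 synteny blocks (see
`out_syn/blocks.tsv` for spans and orientations) and no ortholog pair is
left unchained. The annotation line tallies effect classes over all
(SNP × overlapping gene) records from the 20 simulated strains: most coding
changes are nonsynonymous, a fraction synonymous, and 353 introduce a
premature stop (380 rows). The coverage scan finds the single low-coverage island
planted in the demo track (`out_cov/low_coverage.bed` shows it at
20000–23000 in BED coordinates). Every output directory also contains a
`manifest.json` with parameters and sha256 checksums of the products.

The same operations are importable (`from microsynt import bdbh,
detect_blocks, annotate_all, artificial_alignment, distances, build_tree,
...`) for use in notebooks and pipelines.

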