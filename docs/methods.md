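# Methods

This note documents the models, conventions and design choices behind the
engine, in the order data flows through it.

## Coordinates and formats

All in-memory coordinates are 1-based and inclusive at both ends, the
native convention of the ptt `Location` field. The two external formats
with other conventions are converted at the I/O boundary and unit-tested:
bedGraph rows `(start0, end0)` become `(start0 + 1, end0)`, and BED output
reverses the mapping. Sequences are uppercased on load; characters outside
`ACGTN` are rejected. Origin-wrapping genes (`start > end`) are rejected at
parse time because ptt cannot represent them unambiguously. The ptt
`Length` column holds the protein length in amino acids, so a protein-coding
gene satisfies `end − start + 1 = (Length + 1) × 3` (the stop codon is not
counted); the writer emits that relation and a property test enforces it.

The correspondence, SNP and metadata tables are tab-delimited dialects
defined by this package (columns listed in the reader docstrings), since
only "tab-delimited" is fixed by convention in the source ecosystem.
Loading enforces every record invariant (allele ≠ reference allele,
positions in range, reference-base agreement when the sequence is loaded,
unique strain ids); nothing is silently dropped — every rejection is an
error naming the line number.

## Orthology (BDBH)

`best_hits` selects, per query, the hit with maximal bit score; ties fall
through E-value (lower), % identity (higher) and finally subject id
(lexicographic), making the call fully deterministic. Self-hits are
discarded. `bdbh` keeps (a, b) iff each is the other's best hit, and the
pair carries the forward (reference → target) metrics. The orthology call
itself is threshold-free: identity/coverage cut-offs are applied only in
`filter_profile`, mirroring an interactive display filter, so the base
orthology is reproducible and all subjectivity is an explicit, logged step.
Query coverage is `(qend − qstart + 1) / query length`, clamped to [0, 1].

## Synteny chaining

No canonical chaining rule exists for gene-order synteny at this
granularity, so the engine uses the simplest rule that reproduces local
alignment and rupture detection and is checkable against a brute-force
maximal-run scanner: greedy left-to-right chaining over pairs sorted by
reference gene index. A pair extends the chain when its reference index
advances by ≤ `max_gap + 1`, its target index steps by ≤ `max_gap + 1` in
the chain's direction, and the direction (ascending = collinear,
descending = inverted) is consistent; the direction of a 1-pair chain is
fixed by its second member. Chains shorter than `min_pairs` are discarded
but reported (`unchained_pairs`). Defaults `max_gap=3`, `min_pairs=2` are
permissive enough to bridge small insertions while keeping blocks local.
Chaining does not cross the origin of circular genomes unless `wrap=True`,
because wrapping is ambiguous in linear output coordinates; the wrap merge
requires both genomes circular and gap/direction compatibility across the
origin.

`local_offset` anchors the shift-into-alignment view on a single clicked
gene: offset = reference anchor midpoint − target ortholog midpoint, the
translation to add to target coordinates so the two genes coincide; it is
absent for orphans.

## SNP effects

Location is interval stabbing over start-sorted genes (binary search with a
max-gene-length look-back, brute-force-verified); a SNP under several
overlapping genes is annotated once per gene — lossless, no primary-gene
heuristic. Effects use NCBI translation table 11 (bacterial/archaeal).
For a forward gene, `codon_index = offset // 3 + 1` and
`codon_position = offset % 3 + 1` with `offset = position − start`;
reverse genes measure the offset from the gene end and both codons are
reverse-complemented before translation. Classes are synonymous /
nonsynonymous / stop_gained / intergenic; stop-loss is folded into
nonsynonymous (the raw amino acids are in the output so users can re-bin);
start-codon positions get no special handling. Genes whose length is not a
multiple of 3 are warned about, the frame stays anchored at the start
codon, and positions past the last full codon — like codons containing N —
are classified `unknown` and logged. The classifier is validated against an
independent oracle: translating the whole gene before and after the
substitution and comparing proteins.

## Population summaries

- Frequency: per polymorphic position, the count and fraction of analysed
  strains with a recorded SNP there.
- Density: `per_gene` counts genic SNPs per gene (shared SNPs count once
  per overlapping gene); `per_kb` tiles `[1, L]` with fixed windows
  anchored at position 1 (last window short). Both are additive over any
  partition of strains, which `group_density` exploits; strains without the
  grouping attribute go to an explicit `unassigned` category.
- Artificial alignment: columns are the sorted union of SNP positions over
  the chosen strains; a cell is the strain's alternate allele there, else
  the reference base. The reference is included as the first row, and a
  strain absent from the SNP table gets a pure-reference row — the input
  dialect has no missing-data symbol, so absence of a call is taken as
  identity with the reference. This is the main caveat when feeding real
  data: uncalled ≠ reference in low-coverage regions.
- Distances: p-distance is the fraction of mismatching columns;
  Jukes–Cantor is −¾ ln(1 − 4p/3), an error at p ≥ ¾. Note both are
  computed **over segregating sites only**, so they are relative
  divergences within the analysed set, not per-genome-site rates; JC can
  saturate quickly on small strain sets where most columns separate some
  pair.
- Neighbor joining is implemented in-package so the tie-break is
  documented: among equal Q-criterion minima, the smallest (row, column)
  position in the current label order is joined. The final edge is split
  evenly between the last two nodes, which preserves all leaf-to-leaf path
  lengths. Negative branch lengths (possible on non-additive inputs) are
  left as computed. The implementation is cross-checked in the tests
  against an independent NJ (scikit-bio) and against additive matrices with
  known topology.
- "Autoscore" strain ordering sorts strains by ascending p-distance to the
  reference row of the artificial alignment (ties lexicographic). This is
  this package's interpretation of a score-based ordering — it reproduces
  the visible behaviour that reference-like strains sort first, and is
  deterministic — not a reconstruction of any particular prior tool's
  formula.
- Coverage anomalies are maximal runs of bases with depth below the
  threshold, spanning at least `min_span` bp; bases not covered by any
  interval count as depth 0. Defaults (threshold 5×, span 1 kb) suit
  detecting multi-kb absent regions in typical short-read depth (~50×).

## Simulator

The generator is the test bed for every consumer and makes these choices:

- Genomes: genes are clean ORFs — ATG, non-stop codons, one stop — with
  lengths ≈ N(mean/3, mean/12) codons and uniform intergenic spacers of
  0.5–2× the nominal length, alternating strands. This gives every gene a
  valid reading frame on a realistic ~85% coding fraction. It does not
  emulate codon bias, operons, overlapping genes or horizontal transfer.
- Rearrangement cuts the gene order into contiguous segments (each ≥ 2
  genes), permutes and optionally inverts them, and rebuilds sequence and
  annotation; intergenic DNA travels with the downstream segment so the
  segments partition the genome. The sampled layout is redrawn until no two
  adjacently placed segments continue each other's original run — otherwise
  the planted segmentation would not be the maximal-run structure and
  "recover exactly k blocks" would be ill-posed.
- SNPs: a Jukes–Cantor process down a supplied tree — per branch a Poisson
  (rate × branch length × L) number of events at uniform positions, each
  substituting a uniformly chosen different base. Multiple hits are allowed
  (last event wins, counted and logged); no selection, recombination or
  indels. True per-SNP effects are recorded by whole-gene translation,
  which is deliberately a different code path from the codon-arithmetic
  classifier it validates.
- Random trees join uniformly chosen pairs with uniform branch lengths in a
  configurable range. Everything is deterministic per seed
  (`numpy.random.default_rng`).

Consequently, passing tests demonstrate algorithmic correctness on data
satisfying the engine's invariants; they do not certify behaviour on real
data with annotation errors, uncalled regions or recombination.

## Problem sizes in the verification script

`scripts/acceptance.py` uses: 1,000-gene genomes × 10 seeds × k ∈
{1, 3, 5, 8} planted segments for synteny recovery; 100 random similarity
instances (≤ 200 genes/side) for the BDBH oracle; 10,000 genic SNPs on a
300-gene genome for the effect oracle; 20 replicates of 20-leaf trees with
several thousand segregating sites (rate 1.0 sub/site per unit branch
length, branch lengths 0.002–0.01, ~36 kb genome) for topology recovery;
and the full 12-subcommand demo pipeline. These sizes exercise every code
path at the scale of a small bacterial comparison while completing in
seconds.
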