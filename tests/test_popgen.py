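"""Population summaries: spectra, densities, artificial alignments, distances,
NJ trees, sequence export, coverage anomalies and strain ordering."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from microsynt import io as mio
from microsynt import simulate as sim
from microsynt import (
    artificial_alignment,
    build_tree,
    coverage_anomalies,
    density,
    distances,
    frequency,
    group_density,
    mutate_sequence,
    order_strains,
)
from microsynt.popgen import (
    JUKES_CANTOR,
    P_DISTANCE,
    PER_GENE,
    PER_KB,
    REFERENCE_ROW,
    diff_sequences,
)
from microsynt.records import CoverageTrack, GenomeRecord, SnpRecord, StrainMetadata


def _snp(strain, pos, ref="A", alt="T"):
    return SnpRecord(strain, pos, ref, alt)


class TestFrequency:
    def test_single_carrier_fraction(self):
        spec = frequency([_snp("a", 10)], ["a", "b", "c", "d"])
        assert spec[10] == (1, 0.25)

    def test_all_strains_fraction_one(self):
        snps = [_snp(s, 10) for s in "abcd"]
        assert frequency(snps, list("abcd"))[10] == (4, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_position_tally(self, seed):
        rng = np.random.default_rng(seed)
        strains = [f"s{i}" for i in range(6)]
        snps = [
            _snp(strains[rng.integers(0, 6)], int(rng.integers(1, 50)))
            for _ in range(100)
        ]
        spec = frequency(snps, strains)
        for pos in {s.position for s in snps}:
            carriers = {s.strain_id for s in snps if s.position == pos}
            assert spec[pos] == (len(carriers), len(carriers) / 6)


class TestDensity:
    def test_no_snps_all_zero(self, small_genome):
        dm = density([], small_genome, mode=PER_GENE)
        assert all(c == 0 for _, c in dm.bins)

    def test_per_kb_tiling(self):
        genome = GenomeRecord("g", [], length=2500)
        dm = density([], genome, mode=PER_KB, window_kb=1)
        assert [k for k, _ in dm.bins] == ["1-1000", "1001-2000", "2001-2500"]

    def test_per_kb_counts_sum_to_total(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        dm = density(snps, genome, mode=PER_KB)
        assert dm.total == len(snps)

    @pytest.mark.parametrize("mode", [PER_GENE, PER_KB])
    def test_matches_brute_force_recount(self, snp_setup, mode):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        dm = density(snps, genome, mode=mode)
        counts = dm.as_dict()
        if mode == PER_GENE:
            for g in genome.genes:
                expected = sum(1 for s in snps if g.start <= s.position <= g.end)
                assert counts[g.gene_id] == expected
        else:
            for key, count in dm.bins:
                lo, hi = map(int, key.split("-"))
                assert count == sum(1 for s in snps if lo <= s.position <= hi)

    def test_unknown_group_strain_rejected(self, small_genome):
        with pytest.raises(ValueError, match="unknown"):
            density([], small_genome, group={"ghost"}, known_strains={"a"})


class TestGroupDensity:
    def _metadata(self, strains, attr_values):
        return [
            StrainMetadata(s, (("group", v),)) for s, v in zip(strains, attr_values)
        ]

    def test_groups_sum_to_global(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        meta = self._metadata(strains, ["A", "B"] * 4)
        grouped = group_density(snps, meta, "group", genome)
        global_map = density(snps, genome).as_dict()
        summed = {}
        for dm in grouped.values():
            for k, c in dm.bins:
                summed[k] = summed.get(k, 0) + c
        assert summed == global_map

    def test_single_group_equals_ungrouped(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        meta = self._metadata(strains, ["only"] * len(strains))
        grouped = group_density(snps, meta, "group", genome)
        assert list(grouped) == ["only"]
        assert grouped["only"].as_dict() == density(snps, genome).as_dict()

    def test_missing_attribute_goes_to_unassigned(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        meta = self._metadata(strains, ["A"] * 4 + [""] * 4)
        grouped = group_density(snps, meta, "group", genome)
        assert set(grouped) == {"A", "unassigned"}

    @pytest.mark.parametrize("seed", range(3))
    def test_random_partition_additivity(self, snp_setup, seed):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        rng = np.random.default_rng(seed)
        labels = [str(rng.integers(0, 3)) for _ in strains]
        meta = self._metadata(strains, labels)
        grouped = group_density(snps, meta, "group", genome, mode=PER_KB)
        total = sum(dm.total for dm in grouped.values())
        assert total == density(snps, genome, mode=PER_KB).total


class TestArtificialAlignment:
    def test_fill_rule(self):
        genome = GenomeRecord("g", [], sequence="A" * 30)
        snps = [_snp("s1", 10, "A", "G"), _snp("s2", 10, "A", "G"), _snp("s2", 20, "A", "C")]
        aln = artificial_alignment(snps, ["s1", "s2"], genome)
        assert aln.positions == [10, 20]
        assert aln.row(REFERENCE_ROW) == "AA"
        assert aln.row("s1") == "GA"
        assert aln.row("s2") == "GC"

    def test_no_snps_zero_columns_rows_present(self):
        genome = GenomeRecord("g", [], sequence="ACGT" * 5)
        aln = artificial_alignment([], ["s1", "s2"], genome)
        assert aln.positions == [] and aln.strains == [REFERENCE_ROW, "s1", "s2"]

    def test_matches_simulated_haplotypes(self, snp_setup):
        genome, strains, _, snp_tables, truth = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        aln = artificial_alignment(snps, strains, genome)
        for strain in strains:
            hap = truth.haplotypes[strain]
            expected = "".join(hap[p - 1] for p in aln.positions)
            assert aln.row(strain) == expected

    def test_gene_subset_restricts_positions(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        gene = genome.genes[0]
        aln = artificial_alignment(snps, strains, genome, gene_subset=[gene.gene_id])
        assert all(gene.start <= p <= gene.end for p in aln.positions)

    def test_distances_invariant_to_strain_order(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        d1 = distances(artificial_alignment(snps, strains, genome))
        d2 = distances(artificial_alignment(snps, list(reversed(strains)), genome))
        d2 = d2.loc[d1.index, d1.columns]
        assert np.allclose(d1.to_numpy(), d2.to_numpy())


class TestDistances:
    def _aln(self, rows):
        genome = GenomeRecord("g", [], sequence="A" * 100)
        n = len(rows[0])
        aln = artificial_alignment([], [f"s{i}" for i in range(len(rows))], genome,
                                   include_reference=False)
        aln.positions = list(range(1, n + 1))
        aln.alleles = np.array([list(r) for r in rows], dtype="<U1")
        return aln

    def test_identical_rows_zero(self):
        d = distances(self._aln(["ACGT", "ACGT"]))
        assert d.iloc[0, 1] == 0.0

    def test_quarter_mismatch_and_jc(self):
        aln = self._aln(["ACGT", "ACGA"])
        assert distances(aln, P_DISTANCE).iloc[0, 1] == 0.25
        jc = distances(aln, JUKES_CANTOR).iloc[0, 1]
        assert jc == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-9)
        assert jc == pytest.approx(0.30410, abs=1e-5)

    def test_jc_undefined_at_saturation(self):
        with pytest.raises(ValueError, match="3/4"):
            distances(self._aln(["AAAA", "CCCC"]), JUKES_CANTOR)

    def test_zero_columns_rejected(self):
        genome = GenomeRecord("g", [], sequence="A" * 10)
        aln = artificial_alignment([], ["s1", "s2"], genome)
        with pytest.raises(ValueError, match="zero-column"):
            distances(aln)

    def test_symmetry_and_diagonal(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        d = distances(artificial_alignment(snps, strains, genome)).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1)).all()


def _rf(t1, t2):
    tns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=mio.tree_to_newick(t1) + "\n", schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    b = dendropy.Tree.get(data=mio.tree_to_newick(t2) + "\n", schema="newick",
                          taxon_namespace=tns, preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(a, b)


class TestBuildTree:
    def test_three_taxa_branch_lengths(self):
        # three-point formulas: la = (dab+dac-dbc)/2 etc.
        d = pd.DataFrame(
            [[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = build_tree(d)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        assert pdm.distance(taxa["A"], taxa["B"]) == pytest.approx(0.4, abs=1e-9)
        assert pdm.distance(taxa["A"], taxa["C"]) == pytest.approx(0.6, abs=1e-9)
        assert pdm.distance(taxa["B"], taxa["C"]) == pytest.approx(0.8, abs=1e-9)

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)); distances are additive path lengths
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = build_tree(d)
        truth = mio.parse_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert _rf(tree, truth) == 0
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for x in "ABCD":
            for y in "ABCD":
                if x < y:
                    assert pdm.distance(taxa[x], taxa[y]) == pytest.approx(
                        d.loc[x, y], abs=1e-9)

    def test_matches_reference_nj_topology(self, snp_setup):
        """Cross-check against scikit-bio's independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        aln = artificial_alignment(snps, strains, genome, include_reference=False)
        d = distances(aln)
        ours = build_tree(d)
        dm = skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index))
        theirs = mio.parse_newick(str(skbio.tree.nj(dm)))
        assert _rf(ours, theirs) == 0

    def test_too_few_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="at least 3"):
            build_tree(d)

    def test_deterministic(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        d = distances(artificial_alignment(snps, strains, genome))
        assert mio.tree_to_newick(build_tree(d)) == mio.tree_to_newick(build_tree(d))


class TestMutateSequence:
    def test_no_snps_identity(self):
        assert mutate_sequence("ACGT", []) == "ACGT"

    def test_single_snp(self):
        out = mutate_sequence("ACGT", [_snp("s", 2, "C", "T")])
        assert out == "ATGT"

    def test_conflicting_snps_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            mutate_sequence("ACGT", [_snp("s", 2, "C", "T"), _snp("s", 2, "C", "G")])

    def test_roundtrip_recovers_snp_set(self, snp_setup):
        """mutate then diff against the reference gives back the exact SNP set."""
        genome, strains, _, snp_tables, _ = snp_setup
        for strain in strains[:4]:
            snps = snp_tables[strain]
            mutated = mutate_sequence(genome.sequence, snps)
            called = diff_sequences(genome.sequence, mutated)
            assert called == [(s.position, s.ref_allele, s.alt_allele) for s in snps]

    def test_matches_simulated_haplotype(self, snp_setup):
        genome, strains, _, snp_tables, truth = snp_setup
        s = strains[0]
        assert mutate_sequence(genome.sequence, snp_tables[s]) == truth.haplotypes[s]


class TestCoverageAnomalies:
    def test_uniform_high_coverage_clean(self):
        track = CoverageTrack("s", [(1, 10000, 50.0)])
        assert coverage_anomalies(track, 10, 1000) == []

    def test_planted_zero_segment_found_exactly(self):
        track = CoverageTrack("s", [(1, 4999, 50.0), (5000, 9999, 0.0),
                                    (10000, 20000, 50.0)])
        assert coverage_anomalies(track, 10, 1000) == [(5000, 9999)]

    def test_uncovered_gap_counts_as_zero(self):
        track = CoverageTrack("s", [(1, 1000, 50.0), (3001, 4000, 50.0)])
        assert coverage_anomalies(track, 10, 500) == [(1001, 3000)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_base_scan(self, seed):
        rng = np.random.default_rng(seed)
        length = 2000
        # random piecewise track with gaps
        intervals = []
        pos = 1
        while pos < length:
            span = int(rng.integers(50, 300))
            end = min(pos + span - 1, length)
            if rng.random() < 0.8:
                intervals.append((pos, end, float(rng.integers(0, 30))))
            pos = end + 1
        track = CoverageTrack("s", intervals)
        threshold = float(rng.integers(1, 25))
        min_span = int(rng.integers(1, 400))
        got = coverage_anomalies(track, threshold, min_span, genome_length=length)
        depth = np.zeros(length + 1)
        for s, e, d in intervals:
            depth[s : e + 1] = d
        low = depth[1:] < threshold
        expected = []
        i = 0
        while i < length:
            if low[i]:
                j = i
                while j + 1 < length and low[j + 1]:
                    j += 1
                if j - i + 1 >= min_span:
                    expected.append((i + 1, j + 1))
                i = j + 1
            else:
                i += 1
        assert got == expected


class TestOrderStrains:
    def test_tree_leaf_order(self):
        tree = mio.parse_newick("((s2,s3),s1);")
        assert order_strains(["s1", "s2", "s3"], by="tree", tree=tree) == \
            ["s2", "s3", "s1"]

    def test_tree_missing_strain_rejected(self):
        tree = mio.parse_newick("(s1,s2);")
        with pytest.raises(ValueError, match="missing"):
            order_strains(["s1", "s3"], by="tree", tree=tree)

    def test_autoscore_reference_identical_first(self):
        genome = GenomeRecord("g", [], sequence="A" * 50)
        snps = [_snp("far", p, "A", "G") for p in (5, 10, 15)]
        aln = artificial_alignment(snps, ["near", "far"], genome)
        assert order_strains(["near", "far"], by="autoscore", alignment=aln) == \
            ["near", "far"]

    def test_autoscore_matches_sort_key(self, snp_setup):
        genome, strains, _, snp_tables, _ = snp_setup
        snps = [s for strain in strains for s in snp_tables[strain]]
        aln = artificial_alignment(snps, strains, genome)
        got = order_strains(strains, by="autoscore", alignment=aln)
        from microsynt.popgen import p_distance_to_reference
        score = p_distance_to_reference(aln)
        assert got == sorted(strains, key=lambda s: (score[s], s))
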