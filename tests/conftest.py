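import pytest

from microsynt import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """12 ORFs on alternating strands, with sequence."""
    return sim.make_genome(12, mean_gene_len=300, intergenic_len=60, seed=7,
                           genome_id="ref")


@pytest.fixture(scope="session")
def snp_setup():
    """A genome plus SNPs simulated down a known 8-leaf tree."""
    genome = sim.make_genome(30, mean_gene_len=450, intergenic_len=90, seed=11,
                             genome_id="ref")
    strains = [f"s{i:02d}" for i in range(1, 9)]
    tree = sim.random_tree(strains, seed=5, bl_range=(0.002, 0.008))
    snp_tables, truth = sim.simulate_snps(genome, tree, subs_per_site_per_branch=0.5,
                                          seed=13)
    return genome, strains, tree, snp_tables, truth


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo")
    sim.write_demo_dataset(out, seed=1)
    return out
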