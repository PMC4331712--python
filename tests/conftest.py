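import pytest

from miremap import synthetic_data as synth


@pytest.fixture(scope="session")
def paper_tables():
    """The packaged printed result tables (65 rows each)."""
    return synth.load_paper_fixtures()


@pytest.fixture
def small_config():
    """A fast synthetic instance with all planted structures present."""
    return synth.SyntheticConfig(
        n_mirnas=60,
        n_genes=400,
        n_up_mirnas=12,
        n_down_mirnas=5,
        cluster_spec=("chr12", 109_500_000, 109_750_000, 8),
        hub_spec=((0, 20),),
        cotarget_spec=(10, 3),
        seq_depth=200_000,
        n_extra_de_genes=20,
        seed=11,
    )


@pytest.fixture
def small_instance(small_config):
    loci = synth.generate_mirna_annotation(small_config)
    truth = synth.generate_truth(small_config, loci)
    return small_config, loci, truth
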