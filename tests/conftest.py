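import pytest

from homeoscan import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimConfig:
    """One 150-kb chromosome, 30 genes, a few of each event type."""
    return sd.SimConfig(
        n_chromosomes=1,
        chromosome_length=150_000,
        n_genes=30,
        conversion_genes=2,
        deletion_genes=2,
        silenced_genes=3,
        seed=7,
    )


@pytest.fixture(scope="session")
def truth(small_config) -> sd.TruthSet:
    return sd.simulate_truth(small_config)


@pytest.fixture(scope="session")
def dna_obs(truth, small_config):
    return sd.emit_dna_observations(truth, small_config)


@pytest.fixture(scope="session")
def rna_obs(truth, small_config) -> sd.RnaObservations:
    return sd.emit_rna_observations(truth, small_config)


@pytest.fixture(scope="session")
def bundle(truth, small_config, tmp_path_factory) -> sd.ObservedBundle:
    outdir = tmp_path_factory.mktemp("bundle")
    return sd.write_bundle(truth, small_config, outdir)
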