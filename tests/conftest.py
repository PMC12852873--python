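import pytest

from bafkit.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study (300 genes, zero flip/track noise)."""
    return simulate(SimulationConfig(seed=11), with_sequence=False)


@pytest.fixture(scope="session")
def seq_sim():
    """A smaller genome including FASTA sequence, for GC tests."""
    cfg = SimulationConfig(seed=12, n_genes=80, chrom_length=4_000_000)
    return simulate(cfg, with_sequence=True)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale config for fast end-to-end runs with sequence."""
    return SimulationConfig(seed=13, n_genes=60, chrom_length=3_000_000,
                            gradient_noise=0.0)
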