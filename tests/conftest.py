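import pytest

from rnacall.simdata import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated dataset shared across tests."""
    return simulate(SimConfig(seed=1, contig_length=20_000, n_genes=3))


@pytest.fixture(scope="session")
def sim_files(small_sim, tmp_path_factory):
    """The same dataset written out in standard file formats."""
    outdir = tmp_path_factory.mktemp("simdata")
    return small_sim.write(str(outdir))
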