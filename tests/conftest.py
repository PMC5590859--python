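import pytest

from ssrarch import MotifFamily, SimConfig
from ssrarch.synthetic_data import simulate

FAMILY_MOTIFS = ("CAG", "CAT", "CAA")


@pytest.fixture(scope="session")
def family():
    return MotifFamily(FAMILY_MOTIFS)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One synthetic dataset (2 parents, 10 hybrid strains, 4 ecotypes) at
    zero mutation, shared across tests."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(seed=7)
    truth = simulate(cfg, outdir)
    return cfg, truth, outdir
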