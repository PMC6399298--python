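import numpy as np
import pytest

from somanet.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A 30 kb tumor/normal pair shared across read-level tests."""
    cfg = SimConfig(ref_length=30_000, n_germline=45, n_somatic_snv=45,
                    n_somatic_indel=15, seed=3)
    outdir = tmp_path_factory.mktemp("small_sim")
    return simulate(cfg, str(outdir))


@pytest.fixture(scope="session")
def mixed_purity_sim(tmp_path_factory):
    """A 20 kb pair with 25% tumor purity and contaminated normal."""
    cfg = SimConfig(ref_length=20_000, n_germline=30, n_somatic_snv=30,
                    n_somatic_indel=10, tumor_purity=0.25, normal_purity=0.95,
                    seed=11)
    outdir = tmp_path_factory.mktemp("mixed_sim")
    return simulate(cfg, str(outdir))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
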