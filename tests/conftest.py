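import numpy as np
import pytest

from bipimpute import ScenarioSpec, build_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """One small outbred scenario replicate shared by read-only tests."""
    spec = ScenarioSpec(
        parentA_inbred=False,
        parentA_genotyping="ld",
        n_crosses=2,
        n_hd_descendants_per_cross=5,
        n_f2_per_cross=30,
        n_hd_snps=400,
        n_ld_snps=20,
        n_replicates=1,
        seed=7,
        n_base_sites=4000,
    )
    return build_scenario(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
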