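import numpy as np
import pytest

from medtwas.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A fully mediated two-gene cohort shared by pipeline-level tests."""
    cfg = SimConfig(n_genes=2, n_mediators=2, n_train=300, n_gwas=3000,
                    n_ref=400, mediation_fraction=1.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
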