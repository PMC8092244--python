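import numpy as np
import pytest

from predsip import GeneratorConfig


@pytest.fixture(scope="session")
def null_substrate():
    return {"none": 0.0}


@pytest.fixture(scope="session")
def effect_config(null_substrate):
    """Effect-level config at the scale of the full survey (~400 effects)."""
    return GeneratorConfig(
        effect_obligate=0.231,
        effect_facultative=0.231,
        substrate_effects=null_substrate,
        seed=1,
    )


@pytest.fixture(scope="session")
def fine_gradient_config(null_substrate):
    """Noise-free fraction-level config with a gradient fine enough that
    bin discretization is below machine precision."""
    return GeneratorConfig(
        n_sites=1,
        experiments_per_site=1,
        taxa_per_experiment=40,
        qpcr_cv=0.0,
        reads_per_sample=0,
        n_fractions=72,
        density_range=(1.60, 1.82),
        n_replicates=1,
        substrate_effects=null_substrate,
        seed=7,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
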