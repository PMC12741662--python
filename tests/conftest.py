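import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xylemscale import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noisy_tree():
    """One default-parameter synthetic sapling (58 segments, all noise on)."""
    return syn.generate_tree(syn.TreeGenParams(seed=11))


@pytest.fixture(scope="session")
def noisefree_tree():
    """Same structure with every noise source disabled: truth is exact."""
    return syn.generate_tree(
        syn.TreeGenParams(
            seed=11, diameter_cv=0.0, pneumatron_noise_cv=0.0, f_c_sd=0.0, f_pf_sd=0.0
        )
    )


@pytest.fixture(scope="session")
def planted_tree():
    """Noise-free sapling with K_W == K_H planted at k0 = 1e-18 m2."""
    return syn.generate_tree(syn.planted_params(k0=1e-18, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
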