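import numpy as np
import pytest

from dermseg import PhantomSpec, generate_phantom, generate_suite


@pytest.fixture(scope="session")
def clean_case():
    """Lesion + dark corners, no hairs/bubbles."""
    return generate_phantom(PhantomSpec(corner_radius=48, seed=5))


@pytest.fixture(scope="session")
def hairy_case():
    """Lesion + hairs + bubbles + corners: the hard case."""
    return generate_phantom(PhantomSpec(n_hairs=8, n_bubbles=4, corner_radius=48, seed=5))


@pytest.fixture(scope="session")
def bare_case():
    """Lesion only, no artifacts, no noise: the analytic reference."""
    return generate_phantom(PhantomSpec(noise_sd=0, edge_softness=0))


@pytest.fixture(scope="session")
def clean_suite():
    """Jittered 10-case suite without artifacts (corners only)."""
    return generate_suite(10, PhantomSpec(corner_radius=48), seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
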