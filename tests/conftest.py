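import numpy as np
import pytest

from medopt import (
    SyntheticExperimentSpec,
    generate_bbd,
    simulate_bbd_responses,
)
from medopt import reference as ref


@pytest.fixture(scope="session")
def bbd27():
    """The 27-run four-factor design with three center replicates."""
    return generate_bbd(ref.FACTORS, center_replicates=3, seed=101)


@pytest.fixture(scope="session")
def noise_free_design(bbd27):
    """27-run design with exact surface responses (both isolates)."""
    return simulate_bbd_responses(
        SyntheticExperimentSpec(
            design=bbd27, models=dict(ref.REFERENCE_MODELS), noise_sd=0.0, seed=7
        )
    )


@pytest.fixture(scope="session")
def noisy_design(bbd27):
    """27-run design with 0.5 mm replicate noise, the default study regime."""
    return simulate_bbd_responses(
        SyntheticExperimentSpec(
            design=bbd27, models=dict(ref.REFERENCE_MODELS), noise_sd=0.5, seed=7
        )
    )


@pytest.fixture(scope="session")
def rank4_manifold():
    """1,000 points on a 4-dim affine manifold inside the 6-dim unit cube.

    Exactly representable by a 4-neuron embedding, so a converged
    autoencoder should reconstruct it almost perfectly.
    """
    rng = np.random.default_rng(42)
    latent = rng.uniform(-1.0, 1.0, size=(1000, 4))
    mix = rng.uniform(-0.5, 0.5, size=(4, 6))
    X = 0.5 + latent @ mix * 0.4
    X = np.clip(X, 0.02, 0.98)
    return X
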