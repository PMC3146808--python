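import numpy as np
import pytest

from pathsig.core_data import ExpressionMatrix
from pathsig.synthetic_data import DegradationConfig, GeneratorConfig


@pytest.fixture
def small_config():
    """A compact universe: quick to generate, still structured."""
    return GeneratorConfig(n_probes=600, n_signature_probes_per_pathway=60, seed=11)


@pytest.fixture
def default_config():
    return GeneratorConfig(seed=11)


@pytest.fixture
def degradation():
    return DegradationConfig(seed=99)


@pytest.fixture
def identity_degradation():
    """Degradation with every component switched off (output == input)."""
    return DegradationConfig(
        attenuation_log2_mean=0.0,
        attenuation_log2_sd=0.0,
        dropout_rate=0.0,
        extra_noise_sd=0.0,
        five_prime_extra_attenuation=0.0,
        sample_severity_sd=0.0,
        signal_compression=1.0,
        seed=99,
    )


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        ["P1", "P2", "P3"],
        ["s1", "s2"],
        np.array([[10.0, 20.0], [30.0, 40.5], [1.25e2, 3.5e-1]]),
    )
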