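"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

import stckit as sk


@pytest.fixture(scope="session")
def white_cov():
    return sk.build_population_covariance("white", 32)


@pytest.fixture(scope="session")
def spiked_cov():
    return sk.build_population_covariance("spiked", 48, lambda1=50.0,
                                          lambda2=5.0, bulk=1.0)


@pytest.fixture(scope="session")
def white_or2_data(white_cov):
    """White-noise ensemble with an or2 neuron and a generous spike count."""
    ens = sk.sample_stimuli(white_cov, 10_000, seed=11)
    rng = np.random.default_rng(12)
    k1 = sk.orthogonalize_feature(rng.standard_normal(32), white_cov.coherent_mode)
    k2 = sk.orthogonalize_feature(rng.standard_normal(32), white_cov.coherent_mode, k1)
    features = np.vstack([k1, k2])
    neuron = sk.ModelNeuron("or2", features, w=0.5).calibrate(ens)
    neuron.theta = sk.match_firing_rate(neuron, ens, 0.2)
    spikes = sk.generate_spike_train(neuron, ens, seed=13)
    return ens, spikes, features


@pytest.fixture(scope="session")
def correlated_mono1_data(spiked_cov):
    """Spiked (coherent-mode) ensemble with a mono1 neuron, feature in the
    subspace orthogonal to the coherent mode."""
    ens = sk.sample_stimuli(spiked_cov, 20_000, seed=21)
    rng = np.random.default_rng(22)
    k = sk.orthogonalize_feature(rng.standard_normal(48), spiked_cov.coherent_mode)
    neuron = sk.ModelNeuron("mono1", k[None, :], w=0.5).calibrate(ens)
    neuron.theta = sk.match_firing_rate(neuron, ens, 0.3)
    spikes = sk.generate_spike_train(neuron, ens, seed=23)
    return ens, spikes, k
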