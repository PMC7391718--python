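import numpy as np
import pytest

from phaselag import (PopulationConfig, SpectralCoefficients, cut_epochs,
                      fourier_coefficients, make_population, sample_epochs,
                      session_seed, simulate_session)


@pytest.fixture
def small_config():
    """A fast 8-channel cohort with short sessions for unit tests."""
    return PopulationConfig(n_subjects=4, n_channels=8,
                            segment_lengths=(30, 24, 12), seed=11)


@pytest.fixture
def noiseless_pair_config():
    """Two perfectly coupled channels at quadrature lag, no noise."""
    return PopulationConfig(n_subjects=1, n_channels=2, coupling_mean=1.0,
                            coupling_sd_between=0.0, session_noise_sd=0.0,
                            sensor_noise_sd=0.0, channel_texture_sd=0.0,
                            mixing_strength=0.0, segment_lengths=(30, 30),
                            seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_coefficients(rng, n_epochs, n_channels=2,
                        bin_freqs=(6.0, 7.0, 8.0), epoch_length=1.0):
    """Independent complex-Gaussian Fourier coefficients (null channels)."""
    shape = (n_epochs, n_channels, len(bin_freqs))
    coeffs = rng.normal(size=shape) + 1j * rng.normal(size=shape)
    return SpectralCoefficients(coefficients=coeffs,
                                bin_frequencies=np.asarray(bin_freqs),
                                epoch_length=epoch_length)


def session_epochs(config, subject, session_id, epoch_length=1.0):
    """Simulate one session and cut it into epochs."""
    rec = simulate_session(
        subject, config, session_id,
        seed=session_seed(config, subject.subject_id, session_id))
    return cut_epochs(rec, epoch_length)


def whole_brain_table(config, n_epochs, epoch_length, matrix_func,
                      reduce_func):
    """(n_subjects x 2) table of a connectivity summary for ICC tests."""
    subjects = make_population(config)
    table = np.zeros((len(subjects), 2))
    for model in subjects:
        for session_id in (1, 2):
            es = session_epochs(config, model, session_id, epoch_length)
            sel = sample_epochs(es, n_epochs,
                                seed=1000 + 7 * model.subject_id + session_id)
            m = matrix_func(fourier_coefficients(sel))
            table[model.subject_id, session_id - 1] = reduce_func(m)
    return table
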