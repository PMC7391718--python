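"""Synthetic two-session multichannel recordings with known phase-lag coupling.

The generator emulates the data properties of a two-session infant EEG
study — a 32-channel montage, an alpha-range oscillation near 7 Hz,
subject-specific coupling strength with between-subject spread, a
session-specific perturbation of that strength, broadband sensor noise,
optional instantaneous mixing (abstracted volume conduction), and clean
segments of mixed durations — so that the true connectivity structure and
the design-level reliability ratio are known by construction.

Coupling model
--------------
All channels ride a common oscillator.  Channel ``i`` carries phase

    2*pi*f*t + theta_i + xi_i(t)

where ``theta_i`` are fixed per-channel offsets (pair lag = theta_i -
theta_j, antisymmetric by construction) and ``xi_i`` is wrapped-Gaussian
phase jitter, piecewise constant over short blocks so that phase relations
decorrelate across epochs.  With per-channel jitter variance ``v_i``, the
pairwise phase consistency is ``exp(-(v_i+v_j)/2) = r_i * r_j``; inverting
this gives analytic control: per-channel consistencies are ``r_i =
sqrt(g) * m_i`` with a subject-level coupling strength ``g`` (drawn around
``coupling_mean`` with SD ``coupling_sd_between``, shifted per session by
``session_noise_sd``) and fixed channel texture ``m_i``.  The implied true
coupling matrix is ``c_ij = r_i * r_j``.

Pairwise lags of a common-oscillator model are additive (lag_ij = theta_i
- theta_j), so arbitrary independent per-pair lags are not realisable;
offsets are instead spread evenly over [0, 3*pi/4] with sub-spacing
jitter, which keeps every pair's lag strictly away from 0 and pi and the
imaginary cross-spectrum informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import derive_seed
from .config import ConfigurationError, PopulationConfig

__all__ = [
    "SubjectModel",
    "ContinuousRecording",
    "make_population",
    "simulate_session",
]

#: Span of the per-channel phase offsets (radians); pair lags fall in
#: (0, LAG_SPAN], bounded away from both 0 and pi.
LAG_SPAN = 0.75 * np.pi

# Per-channel consistency r lies in [0, 1]; at r = 1 the jitter variance is
# exactly 0 (deterministic lag).  When drawing jitter, r is floored at R_MIN,
# which maps coupling ~0 to effectively uniform phase (jitter SD ~ 6 rad).
_R_MAX = 1.0
_R_MIN = 1e-8


@dataclass(frozen=True)
class SubjectModel:
    """Ground-truth coupling structure of one simulated subject."""

    subject_id: int
    true_coupling: np.ndarray   # (C, C) symmetric, zero diagonal, in [0, 1]
    pair_lags: np.ndarray       # (C, C) antisymmetric phase offsets (rad)
    coupling_level: float       # subject-level coupling strength g
    channel_texture: np.ndarray  # (C,) fixed consistency multipliers m_i
    channel_offsets: np.ndarray  # (C,) phase offsets theta_i (rad)

    def __post_init__(self):
        c = np.asarray(self.true_coupling)
        if not np.allclose(c, c.T):
            raise ValueError("true_coupling must be symmetric")
        if np.any(np.diag(c) != 0):
            raise ValueError("true_coupling must have a zero diagonal")
        lags = np.asarray(self.pair_lags)
        if not np.allclose(lags, -lags.T):
            raise ValueError("pair_lags must be antisymmetric")


@dataclass(frozen=True)
class ContinuousRecording:
    """Clean, artefact-free segments of one subject's session."""

    subject_id: int
    session_id: int
    segments: list               # list of (C, samples) arrays
    sampling_rate: float

    def __post_init__(self):
        if self.session_id not in (1, 2):
            raise ValueError("session_id must be 1 or 2")
        n_ch = {s.shape[0] for s in self.segments}
        if len(n_ch) > 1:
            raise ValueError("all segments must have the same channel count")

    @property
    def n_channels(self) -> int:
        return self.segments[0].shape[0]

    @property
    def total_duration(self) -> float:
        return sum(s.shape[1] for s in self.segments) / self.sampling_rate


def _channel_consistency(coupling_level: float,
                         texture: np.ndarray) -> np.ndarray:
    g = np.clip(coupling_level, 0.0, 1.0)
    return np.clip(np.sqrt(g) * texture, 0.0, _R_MAX)


def _coupling_matrix(r: np.ndarray) -> np.ndarray:
    c = np.clip(np.outer(r, r), 0.0, 1.0)
    np.fill_diagonal(c, 0.0)
    return c


def _population_profile(config: PopulationConfig, rng: np.random.Generator):
    """Fixed channel texture and phase offsets shared by the whole cohort.

    Sharing the pair-level structure across subjects keeps the designed
    between-subject variance confined to the subject-level coupling
    strength, which is what the reliability-recovery bookkeeping relies on.
    """
    n = config.n_channels
    sd = config.channel_texture_sd
    # lognormal multipliers, normalised to max 1 so that r_i = sqrt(g)*m_i
    # never exceeds 1 and the coupling matrix g*m_i*m_j never clips: the
    # subject-level strength g then maps linearly onto every pair.
    texture = np.exp(rng.normal(size=n) * sd)
    texture = texture / texture.max()
    if n == 2:
        base = np.array([0.0, 0.5 * np.pi])  # a single pair: quadrature lag
        jitter = np.zeros(2)
    else:
        spacing = LAG_SPAN / (n - 1)
        base = np.arange(n) * spacing
        jitter = rng.uniform(-0.25 * spacing, 0.25 * spacing, size=n)
    offsets = rng.permutation(base) + jitter
    return texture, offsets


def make_population(config: PopulationConfig) -> list:
    """Draw the cohort's ground-truth subject models.

    Subject-level coupling strengths are Gaussian around ``coupling_mean``
    with SD ``coupling_sd_between``, clipped to [0, 1]; the per-pair
    structure (texture, lags) is a fixed population profile, so with
    ``coupling_sd_between = 0`` all subjects share an identical coupling
    matrix.  Reproducible bit-for-bit from ``config.seed``.
    """
    if not isinstance(config, PopulationConfig):
        raise ConfigurationError("make_population expects a PopulationConfig")
    profile_rng = np.random.default_rng(derive_seed(config.seed, 0))
    texture, offsets = _population_profile(config, profile_rng)
    lags = offsets[:, None] - offsets[None, :]

    subjects = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(derive_seed(config.seed, 1, i))
        g = float(np.clip(
            rng.normal(config.coupling_mean, config.coupling_sd_between)
            if config.coupling_sd_between > 0 else config.coupling_mean,
            0.0, 1.0))
        r = _channel_consistency(g, texture)
        subjects.append(SubjectModel(
            subject_id=i,
            true_coupling=_coupling_matrix(r),
            pair_lags=lags.copy(),
            coupling_level=g,
            channel_texture=texture.copy(),
            channel_offsets=offsets.copy(),
        ))
    return subjects


def session_seed(config: PopulationConfig, subject_id: int,
                 session_id: int) -> int:
    """Stable per-subject, per-session seed derived from the global seed."""
    return derive_seed(config.seed, 2, subject_id, session_id)


def _pink_filter(noise: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shape white noise to a 1/f amplitude spectrum (per channel row)."""
    spectrum = np.fft.rfft(noise, axis=-1)
    freqs = np.fft.rfftfreq(noise.shape[-1])
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum *= scale
    shaped = np.fft.irfft(spectrum, n=noise.shape[-1], axis=-1)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def simulate_session(model: SubjectModel, config: PopulationConfig,
                     session_id: int, seed: int) -> ContinuousRecording:
    """Simulate one session's clean segments for one subject.

    The subject's coupling level is perturbed by a session-specific shift
    (SD ``session_noise_sd``); channels carry the common oscillation with
    per-channel offsets and block-wise wrapped-Gaussian phase jitter whose
    variance encodes the session coupling; independent broadband noise is
    added per channel; optional instantaneous mixing spreads each sample
    across channels with off-diagonal weight ``mixing_strength``; the
    continuous signal is cut into the configured segment durations.
    """
    if session_id not in (1, 2):
        raise ValueError("session_id must be 1 or 2")
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    n_ch = config.n_channels

    shift = (rng.normal(0.0, config.session_noise_sd)
             if config.session_noise_sd > 0 else 0.0)
    g_session = float(np.clip(model.coupling_level + shift, 0.0, 1.0))
    r = _channel_consistency(g_session, model.channel_texture)
    jitter_sd = np.sqrt(-2.0 * np.log(np.maximum(r, _R_MIN)))

    seg_samples = [int(round(d * fs)) for d in config.segment_lengths]
    total = int(np.sum(seg_samples))
    t = np.arange(total) / fs

    block_len = max(1, int(round(config.phase_jitter_interval * fs)))
    n_blocks = int(np.ceil(total / block_len))
    jitter_blocks = rng.normal(size=(n_ch, n_blocks)) * jitter_sd[:, None]
    jitter = np.repeat(jitter_blocks, block_len, axis=1)[:, :total]

    phase = (2.0 * np.pi * config.oscillation_freq * t)[None, :] \
        + model.channel_offsets[:, None] + jitter
    x = np.sin(phase)

    if config.sensor_noise_sd > 0:
        noise = rng.normal(size=(n_ch, total))
        if config.pink_noise:
            noise = _pink_filter(noise, rng)
        x = x + config.sensor_noise_sd * noise

    mu = config.mixing_strength
    if mu > 0:
        mix = np.full((n_ch, n_ch), mu / (n_ch - 1))
        np.fill_diagonal(mix, 1.0 - mu)
        x = mix @ x

    segments = []
    start = 0
    for ns in seg_samples:
        segments.append(x[:, start:start + ns])
        start += ns
    return ContinuousRecording(subject_id=model.subject_id,
                               session_id=session_id,
                               segments=segments, sampling_rate=fs)
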