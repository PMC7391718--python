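"""Population configuration for the synthetic two-session EEG generator.

The configuration fixes everything about a simulated cohort: cohort size,
montage size, sampling rate, the frequency of the alpha-range oscillation,
the coupling-strength distribution across subjects, the session-to-session
perturbation of coupling, sensor noise, instantaneous (volume-conduction
style) mixing, and the clean-segment durations available per session.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a population configuration is internally inconsistent."""


#: Clean-segment durations (seconds) available in each session.  A mixture of
#: 12-30 s blocks totalling 348 s, enough for every segmentation scheme
#: (the most demanding need 300 s: 60 x 5 s and 150 x 2 s) even after
#: per-segment remainder loss when cutting epochs.
DEFAULT_SEGMENT_LENGTHS = (30, 30, 24, 30, 18, 30, 30, 12, 30, 30, 24, 30, 12)


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of a simulated two-session infant-EEG cohort.

    Parameters
    ----------
    n_subjects
        Number of subjects in the cohort.
    n_channels
        Number of EEG channels (electrodes); at least 2.
    sampling_rate
        Sampling rate in Hz.  Must exceed twice ``oscillation_freq``.
    oscillation_freq
        Frequency (Hz) of the alpha-range oscillation carried by every
        channel; 7 Hz sits inside the infant alpha band (6-8 Hz).
    coupling_mean
        Population mean of the subject-level phase-lag coupling strength,
        dimensionless in [0, 1].
    coupling_sd_between
        Between-subject SD of the coupling strength (the trait component).
    session_noise_sd
        SD of the session-specific shift of the coupling strength (the
        state, within-subject between-session component).
    sensor_noise_sd
        SD of the additive broadband sensor noise per sample, relative to
        the unit oscillation amplitude.  The default (10.0, i.e. per-bin
        alpha SNR near 1) emulates the high noise levels of infant EEG,
        where phase-lag estimates are strongly epoch-count limited.
    mixing_strength
        Instantaneous (zero-lag) linear leakage between channels in [0, 1);
        abstracts volume conduction.
    segment_lengths
        Durations (seconds) of the clean data segments per session.
    seed
        Global seed; identical seed => bit-identical population.
    channel_texture_sd
        Log-scale SD of the fixed per-channel consistency multipliers that
        give the coupling matrix its pairwise structure.
    phase_jitter_interval
        Duration (seconds) of the piecewise-constant phase-jitter blocks;
        sets the timescale on which phase relations decorrelate.
    pink_noise
        If True, shape the sensor noise to a 1/f amplitude spectrum instead
        of white.  Secondary for a 6-8 Hz band-limited analysis.
    """

    n_subjects: int
    n_channels: int = 32
    sampling_rate: float = 512.0
    oscillation_freq: float = 7.0
    coupling_mean: float = 0.35
    coupling_sd_between: float = 0.1
    session_noise_sd: float = 0.065
    sensor_noise_sd: float = 10.0
    mixing_strength: float = 0.0
    segment_lengths: tuple = field(default=DEFAULT_SEGMENT_LENGTHS)
    seed: int = 0
    channel_texture_sd: float = 0.1
    phase_jitter_interval: float = 0.5
    pink_noise: bool = False

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_channels < 2:
            raise ConfigurationError("n_channels must be >= 2")
        if self.sampling_rate <= 2.0 * self.oscillation_freq:
            raise ConfigurationError(
                "sampling_rate must exceed twice oscillation_freq (Nyquist)"
            )
        for name in ("coupling_sd_between", "session_noise_sd",
                     "sensor_noise_sd", "channel_texture_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.coupling_mean <= 1.0:
            raise ConfigurationError("coupling_mean must lie in [0, 1]")
        if not 0.0 <= self.mixing_strength < 1.0:
            raise ConfigurationError("mixing_strength must lie in [0, 1)")
        if self.phase_jitter_interval <= 0:
            raise ConfigurationError("phase_jitter_interval must be positive")
        segs = tuple(float(s) for s in self.segment_lengths)
        if not segs or any(s < 1.0 for s in segs):
            raise ConfigurationError("every segment must last >= 1 s")
        object.__setattr__(self, "segment_lengths", segs)

    @property
    def variance_ratio(self) -> float:
        """Designed reliability ratio rho = sigma^2_between / (sigma^2_between + sigma^2_within).

        This is the ceiling a consistency ICC on subject-level connectivity
        approaches once epoch-sampling noise becomes negligible.
        """
        b = self.coupling_sd_between ** 2
        w = self.session_noise_sd ** 2
        if b + w == 0.0:
            return 1.0
        return b / (b + w)

    def replace(self, **changes) -> "PopulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segment_lengths"] = list(d["segment_lengths"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PopulationConfig":
        """Load a configuration from a YAML or JSON file."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))

    def to_file(self, path) -> None:
        path = Path(path)
        if str(path).endswith(".json"):
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def config_for_variance_ratio(rho: float, coupling_sd_between: float = 0.1,
                              **kwargs) -> PopulationConfig:
    """Build a config whose designed reliability ratio equals ``rho``.

    Keeps ``coupling_sd_between`` fixed and solves for the session noise SD:
    sigma_within = sigma_between * sqrt(1/rho - 1).
    """
    if not 0.0 < rho <= 1.0:
        raise ConfigurationError("rho must lie in (0, 1]")
    sw = coupling_sd_between * (1.0 / rho - 1.0) ** 0.5
    return PopulationConfig(coupling_sd_between=coupling_sd_between,
                            session_noise_sd=sw, **kwargs)
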