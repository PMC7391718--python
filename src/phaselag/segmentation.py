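"""Epoch cutting, random epoch selection, and the three segmentation designs.

Clean segments are cut into fixed-length non-overlapping epochs from the
start of each segment (remainder samples discarded).  Three designs probe
the epoch number/length trade-off:

``long_epochs``
    low numbers of longer epochs: {20, 30, 40, 50, 60} x {1..5} s;
``short_epochs``
    high numbers of shorter epochs: {30, 60, 90, 120, 150} x {1, 2} s;
``constant_amount``
    a constant 120 s of data: 120 x 1 s, 60 x 2 s, 40 x 3 s and 20 x 6 s,
    where the shorter epochs are obtained by re-segmenting the same 20
    randomly selected 6-s epochs, so every combination uses identical
    underlying samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .synthetic import ContinuousRecording

__all__ = [
    "EpochSet",
    "SegmentationScheme",
    "InsufficientDataError",
    "cut_epochs",
    "sample_epochs",
    "nested_resegment",
    "table_schemes",
    "LONG_EPOCH_COMBOS",
    "SHORT_EPOCH_COMBOS",
    "CONSTANT_AMOUNT_COMBOS",
    "CONSTANT_AMOUNT_PARENTS",
]

LONG_EPOCH_COMBOS = tuple((n, l) for n in (20, 30, 40, 50, 60)
                          for l in (1, 2, 3, 4, 5))
SHORT_EPOCH_COMBOS = tuple((n, l) for n in (30, 60, 90, 120, 150)
                           for l in (1, 2))
CONSTANT_AMOUNT_COMBOS = ((120, 1), (60, 2), (40, 3), (20, 6))
#: Number of 6-s parent epochs for the constant-amount design (20 x 6 s = 120 s).
CONSTANT_AMOUNT_PARENTS = 20

APPROACHES = ("long_epochs", "short_epochs", "constant_amount")


class InsufficientDataError(RuntimeError):
    """A subject/session lacks enough epochs for the requested selection."""


@dataclass(frozen=True)
class EpochSet:
    """Fixed-length epochs of multichannel signal entering spectral analysis."""

    subject_id: int
    session_id: int
    epoch_length: float          # seconds
    epochs: np.ndarray           # (n_epochs, channels, samples)
    sampling_rate: float
    selection_seed: Optional[int] = None

    def __post_init__(self):
        e = np.asarray(self.epochs)
        if e.ndim != 3:
            raise ValueError("epochs must be a (n, channels, samples) array")
        expected = int(round(self.epoch_length * self.sampling_rate))
        if e.shape[0] and e.shape[2] != expected:
            raise ValueError(
                f"epochs have {e.shape[2]} samples, expected {expected}")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass(frozen=True)
class SegmentationScheme:
    """One of the three epoch-selection approaches and its (n, length) grid."""

    approach: str
    combos: tuple

    def __post_init__(self):
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        object.__setattr__(self, "combos",
                           tuple((int(n), int(l)) for n, l in self.combos))

    @property
    def epoch_lengths(self) -> tuple:
        return tuple(sorted({l for _, l in self.combos}))


def table_schemes() -> dict:
    """The full scheme grid, keyed by approach name."""
    return {
        "long_epochs": SegmentationScheme("long_epochs", LONG_EPOCH_COMBOS),
        "short_epochs": SegmentationScheme("short_epochs", SHORT_EPOCH_COMBOS),
        "constant_amount": SegmentationScheme("constant_amount",
                                              CONSTANT_AMOUNT_COMBOS),
    }


def cut_epochs(recording: ContinuousRecording,
               epoch_length: float) -> EpochSet:
    """Cut each clean segment into maximal whole non-overlapping epochs.

    Epochs start at the beginning of each segment; trailing samples that do
    not fill a whole epoch are discarded.  A recording with no segment long
    enough yields an empty :class:`EpochSet` (the caller decides whether to
    exclude the subject).
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    fs = recording.sampling_rate
    samples = int(round(epoch_length * fs))
    blocks = []
    for seg in recording.segments:
        n = seg.shape[1] // samples
        if n:
            blocks.append(
                seg[:, :n * samples].reshape(seg.shape[0], n, samples)
                .transpose(1, 0, 2))
    if blocks:
        epochs = np.concatenate(blocks, axis=0)
    else:
        epochs = np.empty((0, recording.n_channels, samples))
    return EpochSet(subject_id=recording.subject_id,
                    session_id=recording.session_id,
                    epoch_length=float(epoch_length),
                    epochs=epochs, sampling_rate=fs)


def sample_epochs(epoch_set: EpochSet, n_epochs: int, seed: int) -> EpochSet:
    """Select ``n_epochs`` epochs uniformly without replacement.

    Selected epochs keep their temporal order.  Deterministic given
    ``seed`` (the selection stream is independent of the data-generation
    stream).  Raises :class:`InsufficientDataError` when fewer epochs are
    available, mirroring per-approach subject exclusion.
    """
    if n_epochs > epoch_set.n_epochs:
        raise InsufficientDataError(
            f"requested {n_epochs} epochs, only {epoch_set.n_epochs} available")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(epoch_set.n_epochs, size=n_epochs,
                             replace=False))
    return EpochSet(subject_id=epoch_set.subject_id,
                    session_id=epoch_set.session_id,
                    epoch_length=epoch_set.epoch_length,
                    epochs=epoch_set.epochs[idx],
                    sampling_rate=epoch_set.sampling_rate,
                    selection_seed=int(seed))


def nested_resegment(six_second_set: EpochSet,
                     target_length: int) -> EpochSet:
    """Re-segment 6-s epochs into contiguous sub-epochs of ``target_length`` s.

    Output order preserves parent order, then within-parent order, so the
    concatenation of sub-epochs reproduces each parent exactly and all
    constant-amount combinations are computed on identical samples.
    """
    if round(six_second_set.epoch_length) != 6:
        raise ValueError("nested_resegment expects 6-s parent epochs")
    if target_length not in (1, 2, 3, 6):
        raise ValueError("target_length must divide 6 s")
    parent = six_second_set.epochs
    n, c, s = parent.shape
    factor = 6 // target_length
    sub = s // factor
    epochs = parent.reshape(n, c, factor, sub).transpose(0, 2, 1, 3) \
        .reshape(n * factor, c, sub)
    return EpochSet(subject_id=six_second_set.subject_id,
                    session_id=six_second_set.session_id,
                    epoch_length=float(target_length),
                    epochs=epochs,
                    sampling_rate=six_second_set.sampling_rate,
                    selection_seed=six_second_set.selection_seed)
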