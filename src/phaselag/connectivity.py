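"""Phase-lag connectivity from Hanning-tapered Fourier coefficients.

The phase lag index (PLI) of a channel pair is the absolute mean, over
epochs, of the sign of the imaginary part of the cross-spectrum
``X = c_i * conj(c_j)``; it measures how consistently one signal leads the
other and is blind to instantaneous (zero-lag) coupling, but is positively
biased when few epochs are available: for independent signals
``E[PLI] ~ sqrt(2/(pi*n))``.

The debiased weighted PLI (dbWPLI) magnitude-weights each epoch's
imaginary cross-spectrum and removes the small-sample inflation via
pairwise products of distinct epochs:

    dbWPLI = ((sum_e y_e)^2 - sum_e y_e^2) / ((sum_e |y_e|)^2 - sum_e y_e^2)

with ``y_e = Im(X_e)``.  It estimates the squared weighted PLI, is ~0 in
expectation for independent signals at any epoch count, and down-weights
near-zero lags that volume conduction and noise produce.  The plain
(biased) WPLI, ``|E y| / E|y|``, is provided separately.

Connectivity is computed per frequency bin inside the analysis band
(endpoints inclusive), then the per-bin matrices are averaged — here over
the infant alpha band, 6-8 Hz by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .segmentation import EpochSet

__all__ = [
    "SpectralCoefficients",
    "ConnectivityMatrix",
    "ALPHA_BAND",
    "fourier_coefficients",
    "pli_matrix",
    "wpli_matrix",
    "dbwpli_matrix",
    "whole_brain",
    "pli_null_mean",
]

#: Infant alpha band (Hz), inclusive endpoints.
ALPHA_BAND = (6.0, 8.0)


@dataclass(frozen=True)
class SpectralCoefficients:
    """Complex Fourier coefficients per (epoch, channel, frequency bin)."""

    coefficients: np.ndarray     # (n_epochs, n_channels, n_bins) complex
    bin_frequencies: np.ndarray  # (n_bins,) Hz
    epoch_length: float          # seconds; bin spacing = 1/epoch_length

    def __post_init__(self):
        c = np.asarray(self.coefficients)
        if c.ndim != 3:
            raise ValueError(
                "coefficients must be (epochs, channels, bins)")
        if c.shape[2] != len(self.bin_frequencies):
            raise ValueError("bin count does not match bin_frequencies")

    @property
    def n_epochs(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric channel x channel weights for one method and band."""

    weights: np.ndarray
    method: str                  # "pli", "wpli" or "dbwpli"
    band: Tuple[float, float]
    n_epochs_used: int

    def __post_init__(self):
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def fourier_coefficients(epoch_set: EpochSet) -> SpectralCoefficients:
    """One complex coefficient per epoch x channel x bin.

    Each epoch is demeaned per channel, tapered with a Hanning window and
    Fourier transformed (single taper).  Bin spacing is 1/epoch_length Hz.
    """
    if epoch_set.n_epochs == 0:
        raise ValueError("cannot compute Fourier coefficients of an empty epoch set")
    x = np.asarray(epoch_set.epochs, dtype=float)
    x = x - x.mean(axis=2, keepdims=True)
    window = np.hanning(x.shape[2])
    coeffs = np.fft.rfft(x * window, axis=2)
    freqs = np.fft.rfftfreq(x.shape[2], d=1.0 / epoch_set.sampling_rate)
    return SpectralCoefficients(coefficients=coeffs, bin_frequencies=freqs,
                                epoch_length=epoch_set.epoch_length)


def _band_coefficients(coeffs: SpectralCoefficients,
                       band: Tuple[float, float]) -> np.ndarray:
    low, high = band
    f = np.asarray(coeffs.bin_frequencies)
    mask = (f >= low - 1e-9) & (f <= high + 1e-9)
    if not mask.any():
        raise ValueError(f"no frequency bin inside band {band}")
    return np.asarray(coeffs.coefficients)[:, :, mask]


def _imag_cross_spectrum(c: np.ndarray) -> np.ndarray:
    """Imaginary cross-spectra, shape (epochs, C, C, bins)."""
    return np.einsum("ecb,edb->ecdb", c, np.conj(c)).imag


def pli_matrix(coeffs: SpectralCoefficients,
               band: Tuple[float, float] = ALPHA_BAND) -> ConnectivityMatrix:
    """Phase lag index, band-averaged over bins inside ``band``.

    Per bin and pair: ``|mean_e sgn(Im X_e)|``, with sgn(0) contributing 0.
    """
    c = _band_coefficients(coeffs, band)
    signs = np.sign(_imag_cross_spectrum(c))
    pli = np.abs(signs.mean(axis=0)).mean(axis=-1)
    np.fill_diagonal(pli, 0.0)
    return ConnectivityMatrix(weights=pli, method="pli", band=tuple(band),
                              n_epochs_used=coeffs.n_epochs)


def wpli_matrix(coeffs: SpectralCoefficients,
                band: Tuple[float, float] = ALPHA_BAND) -> ConnectivityMatrix:
    """Plain (biased) weighted PLI: ``|sum_e y_e| / sum_e |y_e|`` per bin."""
    c = _band_coefficients(coeffs, band)
    y = _imag_cross_spectrum(c)
    num = np.abs(y.sum(axis=0))
    den = np.abs(y).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    w = w.mean(axis=-1)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, method="wpli", band=tuple(band),
                              n_epochs_used=coeffs.n_epochs)


def dbwpli_matrix(coeffs: SpectralCoefficients,
                  band: Tuple[float, float] = ALPHA_BAND) -> ConnectivityMatrix:
    """Debiased (squared) weighted PLI, band-averaged.

    Per bin and pair, with ``y_e = Im(X_e)``:
    ``((sum y)^2 - sum y^2) / ((sum |y|)^2 - sum y^2)``; a degenerate
    denominator (all ``y_e`` zero, e.g. purely instantaneous coupling)
    yields 0.  Requires at least 2 epochs.
    """
    if coeffs.n_epochs < 2:
        raise ValueError("dbWPLI debiasing requires >= 2 epochs")
    c = _band_coefficients(coeffs, band)
    y = _imag_cross_spectrum(c)
    s1 = y.sum(axis=0)
    s2 = (y * y).sum(axis=0)
    sa = np.abs(y).sum(axis=0)
    num = s1 * s1 - s2
    den = sa * sa - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    w = w.mean(axis=-1)
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, method="dbwpli", band=tuple(band),
                              n_epochs_used=coeffs.n_epochs)


def whole_brain(matrix: Union[ConnectivityMatrix, np.ndarray]) -> float:
    """Mean connectivity across all distinct channel pairs.

    The strict upper triangle is averaged; dbWPLI values enter signed
    (absolute values are taken only for graph metrics).
    """
    w = matrix.weights if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    iu = np.triu_indices(w.shape[0], k=1)
    return float(w[iu].mean())


def pli_null_mean(n_epochs: int) -> float:
    """Exact E[PLI] for an independent pair observed over ``n_epochs`` epochs.

    The per-epoch signs are i.i.d. +/-1, so E|mean| has the closed form
    ``2^(1-n) * C(n-1, floor((n-1)/2))``, asymptotically sqrt(2/(pi*n)) —
    the small-sample inflation of the PLI.
    """
    from scipy.special import comb
    n = int(n_epochs)
    return float(2.0 ** (1 - n) * comb(n - 1, (n - 1) // 2, exact=True))
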