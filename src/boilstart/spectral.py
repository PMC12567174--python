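"""Spectral preprocessing: raw AE waveform -> 1 kHz sub-band PSD vector.

One acquisition (10 s at 1 MHz by default) is split into 80 contiguous
segments.  Each segment is mean-centered and its power spectral density
estimated with a Hann-windowed periodogram,

    P(f) = (1 / (fs * N)) * | sum_n h(n) x(n) exp(-j 2 pi f n / fs) |^2 ,

folded to a one-sided spectrum (interior bins doubled).  The 80 per-segment
periodograms are averaged, and the averaged fine-grid PSD is compressed into
1-kHz sub-bands (the arithmetic mean of the fine bins falling in each band),
giving a 500-element spectrum vector over 0-500 kHz at the default rate.
The 75-100 kHz slice of that vector is the feature vector monitored by the
multivariate control charts.

The sub-band value is the *mean* (not the sum) of the fine bins, so it stays
on the PSD scale (V^2/Hz) and is invariant to the segment length.  The Hann
window is the symmetric form h(n) = 0.5 * (1 - cos(2 pi n / (N - 1))); no
window-power renormalization is applied beyond the 1/(fs N) factor of the
periodogram formula.  All downstream monitoring statistics are computed on
standardized variables, so any fixed spectral scale factor cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionSegment
from .errors import (
    BandRangeError,
    ConfigError,
    GridMismatchError,
    NonFiniteSignalError,
)

__all__ = [
    "SpectrumVector",
    "FeatureVector",
    "segment_and_center",
    "hann_window",
    "periodogram_psd",
    "average_psd",
    "bin_to_subbands",
    "extract_band",
    "acquisition_to_spectrum",
    "acquisition_to_features",
]

SUBBAND_WIDTH_HZ = 1000.0


@dataclass(frozen=True)
class SpectrumVector:
    """Sub-band-compressed PSD of one acquisition (1 kHz bands from 0 Hz up)."""

    band_edges_khz: np.ndarray  # n_bands + 1 ascending edges: 0, 1, ..., n
    psd: np.ndarray             # n_bands non-negative values, V^2/Hz
    index: int = 1
    time_min: float = 0.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.band_edges_khz, dtype=np.float64)
        psd = np.asarray(self.psd, dtype=np.float64)
        object.__setattr__(self, "band_edges_khz", edges)
        object.__setattr__(self, "psd", psd)
        if edges.size != psd.size + 1 or not np.all(np.diff(edges) > 0):
            raise ConfigError("band edges must be ascending and bracket psd")
        if not np.all(np.isfinite(psd)) or np.any(psd < 0):
            raise NonFiniteSignalError("psd values must be finite and >= 0")

    @property
    def n_bands(self) -> int:
        return self.psd.size


@dataclass(frozen=True)
class FeatureVector:
    """The monitored sub-band slice of one acquisition (default 75-100 kHz)."""

    values: np.ndarray
    band_lo_khz: float = 75.0
    band_hi_khz: float = 100.0
    index: int = 1
    time_min: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ConfigError("feature vector must be 1-D and non-empty")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise NonFiniteSignalError("feature values must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size


def segment_and_center(segment: AcquisitionSegment) -> np.ndarray:
    """Split a waveform into ``n_segments`` contiguous blocks, each mean-centered.

    Returns an array of shape ``(n_segments, N)`` with ``N = total /
    n_segments`` (125 000 at defaults).  Centering removes the per-block DC
    bias before windowing.
    """
    cfg = segment.config
    blocks = segment.waveform.reshape(cfg.n_segments, cfg.segment_length)
    return blocks - blocks.mean(axis=1, keepdims=True)


def hann_window(n: int) -> np.ndarray:
    """Symmetric Hann window h(k) = 0.5 (1 - cos(2 pi k / (n-1)))."""
    if n == 1:
        return np.ones(1)
    k = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (n - 1)))


def periodogram_psd(block: np.ndarray, sampling_rate_hz: float,
                    window: str = "hann") -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann periodogram of one zero-mean block.

    Returns ``(freqs, psd)`` on the grid ``f_k = k * fs / N`` for
    ``k = 0 ... N/2``.  Interior bins are doubled in the one-sided fold; DC
    and Nyquist are not.
    """
    block = np.asarray(block, dtype=np.float64)
    n = block.size
    if n % 2 != 0:
        raise ConfigError("periodogram blocks must have even length")
    if not np.all(np.isfinite(block)):
        raise NonFiniteSignalError("block contains non-finite samples")
    if window == "hann":
        h = hann_window(n)
    elif window in ("boxcar", "rect", None):
        h = np.ones(n)
    else:
        raise ConfigError(f"unsupported window {window!r}")
    spec = np.fft.rfft(h * block)
    psd = (np.abs(spec) ** 2) / (sampling_rate_hz * n)
    psd[1:-1] *= 2.0  # fold negative frequencies onto interior bins
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    return freqs, psd


def average_psd(psds: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Element-wise arithmetic mean of per-block PSDs on a common grid."""
    psds = list(np.atleast_2d(psds)) if isinstance(psds, np.ndarray) else list(psds)
    if len(psds) == 0:
        raise GridMismatchError("no PSDs to average")
    first = np.asarray(psds[0])
    for p in psds[1:]:
        if np.asarray(p).shape != first.shape:
            raise GridMismatchError("PSDs lie on mismatched frequency grids")
    return np.mean(np.stack([np.asarray(p) for p in psds]), axis=0)


def bin_to_subbands(freqs: np.ndarray, psd: np.ndarray,
                    band_width_hz: float = SUBBAND_WIDTH_HZ,
                    index: int = 1, time_min: float = 0.0) -> SpectrumVector:
    """Compress a fine-grid one-sided PSD into contiguous fixed-width sub-bands.

    Band ``k`` covers ``[k, k+1) * band_width_hz`` and takes the arithmetic
    mean of the fine bins inside it; the Nyquist bin is assigned to the last
    band.  At the default rate (Nyquist 500 kHz, 1 kHz bands) this yields the
    500-element spectrum vector with 125 fine bins per interior band.
    """
    freqs = np.asarray(freqs, dtype=np.float64)
    psd = np.asarray(psd, dtype=np.float64)
    if freqs.shape != psd.shape or freqs.size < 2:
        raise GridMismatchError("freqs and psd must be equal-length vectors")
    nyquist = freqs[-1]
    n_bands = int(round(nyquist / band_width_hz))
    if n_bands < 1 or abs(nyquist - n_bands * band_width_hz) > 1e-6 * band_width_hz:
        raise GridMismatchError(
            f"Nyquist {nyquist} Hz is not a whole number of "
            f"{band_width_hz} Hz bands")
    idx = np.floor(freqs / band_width_hz).astype(int)
    idx = np.minimum(idx, n_bands - 1)  # Nyquist bin -> last band
    sums = np.bincount(idx, weights=psd, minlength=n_bands)
    counts = np.bincount(idx, minlength=n_bands)
    edges_khz = np.arange(n_bands + 1) * band_width_hz / 1000.0
    return SpectrumVector(band_edges_khz=edges_khz, psd=sums / counts,
                          index=index, time_min=time_min)


def extract_band(spectrum: SpectrumVector, lo_khz: float = 75.0,
                 hi_khz: float = 100.0) -> FeatureVector:
    """Slice the contiguous sub-bands covering ``[lo, hi)`` kHz (default 25 bands)."""
    edges = spectrum.band_edges_khz
    if not (0 <= lo_khz < hi_khz <= edges[-1]):
        raise BandRangeError(
            f"band [{lo_khz}, {hi_khz}) kHz outside spectrum "
            f"[0, {edges[-1]}) kHz or inverted")
    lo_i = int(np.searchsorted(edges, lo_khz, side="left"))
    hi_i = int(np.searchsorted(edges, hi_khz, side="left"))
    return FeatureVector(values=spectrum.psd[lo_i:hi_i],
                         band_lo_khz=lo_khz, band_hi_khz=hi_khz,
                         index=spectrum.index, time_min=spectrum.time_min)


def acquisition_to_spectrum(segment: AcquisitionSegment,
                            window: str = "hann") -> SpectrumVector:
    """Full preprocessing pipeline for one acquisition.

    segment_and_center -> per-block periodogram -> average -> sub-band
    compression.
    """
    blocks = segment_and_center(segment)
    fs = segment.config.sampling_rate_hz
    freqs = None
    psds = np.empty((blocks.shape[0], blocks.shape[1] // 2 + 1))
    for i, block in enumerate(blocks):
        freqs, psds[i] = periodogram_psd(block, fs, window=window)
    avg = average_psd(psds)
    return bin_to_subbands(freqs, avg, index=segment.index,
                           time_min=segment.time_min)


def acquisition_to_features(segment: AcquisitionSegment,
                            lo_khz: float = 75.0, hi_khz: float = 100.0,
                            window: str = "hann") -> FeatureVector:
    """Preprocess one acquisition and slice the monitored band."""
    return extract_band(acquisition_to_spectrum(segment, window=window),
                        lo_khz, hi_khz)
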