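"""Spectral pipeline: periodogram, averaging, sub-band compression.

The independent oracle throughout is a brute-force O(N^2) evaluation of the
windowed discrete-Fourier power-spectral-density formula, written directly
from its definition.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boilstart import (
    AcquisitionConfig,
    AcquisitionSegment,
    acquisition_to_features,
    acquisition_to_spectrum,
    average_psd,
    bin_to_subbands,
    extract_band,
    periodogram_psd,
    segment_and_center,
)
from boilstart.errors import BandRangeError, ConfigError, GridMismatchError
from boilstart.spectral import hann_window


def brute_force_psd(block, fs):
    """One-sided PSD by direct summation of the DFT definition (oracle)."""
    n = block.size
    h = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / (n - 1)))
    w = h * block
    freqs = np.arange(n // 2 + 1) * fs / n
    psd = np.empty(freqs.size)
    for k, f in enumerate(freqs):
        s = np.sum(w * np.exp(-2j * np.pi * f * np.arange(n) / fs))
        psd[k] = np.abs(s) ** 2 / (fs * n)
    psd[1:-1] *= 2.0
    return freqs, psd


class TestSegmentAndCenter:
    def test_constant_waveform_centers_to_zero(self, small_config):
        seg = AcquisitionSegment(index=1,
                                 waveform=np.full(small_config.n_samples, 3.7),
                                 config=small_config)
        blocks = segment_and_center(seg)
        assert blocks.shape == (4, 200)
        np.testing.assert_allclose(blocks, 0.0, atol=1e-12)

    def test_blocks_are_zero_mean(self, rng):
        cfg = AcquisitionConfig(sampling_rate_hz=8000.0,
                                collection_duration_s=0.1,
                                acquisition_period_s=30.0, n_segments=8)
        seg = AcquisitionSegment(index=1,
                                 waveform=rng.normal(size=800) + 5.0,
                                 config=cfg)
        blocks = segment_and_center(seg)
        assert blocks.shape == (8, 100)
        np.testing.assert_allclose(blocks.mean(axis=1), 0.0, atol=1e-12)

    def test_default_profile_gives_80_blocks_of_125000(self):
        cfg = AcquisitionConfig()
        seg = AcquisitionSegment(index=1,
                                 waveform=np.zeros(cfg.n_samples), config=cfg)
        blocks = segment_and_center(seg)
        assert blocks.shape == (80, 125_000)


class TestPeriodogram:
    def test_zero_block_gives_zero_psd(self):
        _, psd = periodogram_psd(np.zeros(256), 8000.0)
        np.testing.assert_array_equal(psd, 0.0)

    def test_odd_length_rejected(self):
        with pytest.raises(ConfigError):
            periodogram_psd(np.zeros(255), 8000.0)

    def test_matches_brute_force_oracle(self, rng):
        fs = 8000.0
        for n in (64, 256, 1024):
            block = rng.normal(size=n)
            block -= block.mean()
            f1, p1 = periodogram_psd(block, fs)
            f2, p2 = brute_force_psd(block, fs)
            np.testing.assert_allclose(f1, f2, rtol=1e-12)
            np.testing.assert_allclose(p1, p2, rtol=1e-6,
                                       atol=1e-6 * p2.max())

    def test_exact_bin_sinusoid_concentrates_power(self):
        # 80 kHz tone at fs=1 MHz, N=1000: exact bin 80; symmetric-Hann
        # leakage confines all but ~1e-8 of the peak within +-2 bins.
        fs, n = 1e6, 1000
        x = np.sin(2 * np.pi * 80e3 * np.arange(n) / fs)
        _, psd = periodogram_psd(x, fs)
        k = int(psd.argmax())
        assert k == 80
        off = np.ones(psd.size, bool)
        off[k - 2:k + 3] = False
        assert psd[off].max() < 1e-7 * psd[k]

    def test_parseval_identity(self, rng):
        # sum_k P(f_k) df == (1/N) sum_n h(n)^2 x(n)^2
        fs, n = 8000.0, 512
        x = rng.normal(size=n)
        x -= x.mean()
        _, psd = periodogram_psd(x, fs)
        lhs = psd.sum() * fs / n
        rhs = np.sum((hann_window(n) * x) ** 2) / n
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestAveragePsd:
    def test_identical_blocks(self, rng):
        p = rng.random(100)
        np.testing.assert_allclose(average_psd([p, p, p]), p)

    def test_linearity(self, rng):
        p = rng.random(100)
        np.testing.assert_allclose(average_psd([p, 3 * p]), 2 * p)

    def test_empty_list_rejected(self):
        with pytest.raises(GridMismatchError):
            average_psd([])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GridMismatchError):
            average_psd([np.zeros(10), np.zeros(11)])

    def test_averaging_reduces_variance_by_block_count(self, rng):
        # per-bin variance of an 80-block average ~ 1/80 of a single block
        fs, n, n_blocks, reps = 8000.0, 256, 80, 60
        single, avg = [], []
        for _ in range(reps):
            psds = [periodogram_psd(rng.normal(size=n) - 0.0, fs)[1]
                    for _ in range(n_blocks)]
            single.append(psds[0])
            avg.append(average_psd(psds))
        ratio = (np.var(np.array(avg), axis=0)[1:-1].mean()
                 / np.var(np.array(single), axis=0)[1:-1].mean())
        assert ratio == pytest.approx(1 / n_blocks, rel=0.5)


class TestSubbands:
    def test_flat_psd_maps_to_flat_bands(self):
        freqs = np.fft.rfftfreq(1000, d=1e-6)  # fs = 1 MHz
        sv = bin_to_subbands(freqs, np.full(freqs.size, 2.5))
        assert sv.n_bands == 500
        np.testing.assert_allclose(sv.psd, 2.5)

    def test_default_grid_has_125_fine_bins_per_interior_band(self):
        freqs = np.fft.rfftfreq(125_000, d=1e-6)
        assert freqs.size == 62_501
        sv = bin_to_subbands(freqs, np.arange(freqs.size, dtype=float))
        counts = np.bincount(
            np.minimum((freqs // 1000).astype(int), 499), minlength=500)
        assert counts[1] == 125
        assert sv.n_bands == 500

    def test_band_centered_tone_power_stays_in_its_band(self):
        # tone at 80.5 kHz (center of band [80, 81)) through the periodogram
        fs, n = 1e6, 125_000
        x = np.sin(2 * np.pi * 80.5e3 * np.arange(n) / fs)
        freqs, psd = periodogram_psd(x, fs)
        sv = bin_to_subbands(freqs, psd)
        assert sv.psd[80] * 1 / sv.psd.sum() > 0.99  # equal-width bands

    def test_grid_not_whole_bands_rejected(self):
        freqs = np.linspace(0, 1234.5, 100)
        with pytest.raises(GridMismatchError):
            bin_to_subbands(freqs, np.zeros(100))


class TestExtractBand:
    def test_default_band_has_25_values(self):
        freqs = np.fft.rfftfreq(1000, d=1e-6)
        sv = bin_to_subbands(freqs, np.ones(freqs.size))
        fv = extract_band(sv)
        assert len(fv) == 25
        assert fv.band_lo_khz == 75 and fv.band_hi_khz == 100

    def test_full_range_is_identity_slice(self):
        freqs = np.fft.rfftfreq(1000, d=1e-6)
        sv = bin_to_subbands(freqs, np.ones(freqs.size))
        np.testing.assert_array_equal(extract_band(sv, 0, 500).values, sv.psd)

    def test_inverted_band_rejected(self):
        freqs = np.fft.rfftfreq(1000, d=1e-6)
        sv = bin_to_subbands(freqs, np.ones(freqs.size))
        with pytest.raises(BandRangeError):
            extract_band(sv, 100, 75)


class TestPipelineProperties:
    def _segment(self, waveform, fs=8000.0, n_segments=4):
        cfg = AcquisitionConfig(sampling_rate_hz=fs,
                                collection_duration_s=waveform.size / fs,
                                acquisition_period_s=30.0,
                                n_segments=n_segments)
        return AcquisitionSegment(index=1, waveform=waveform, config=cfg)

    def test_pipeline_matches_single_shot_oracle_per_block(self, rng):
        # averaged pipeline == mean of brute-force per-block PSDs, binned
        fs = 8000.0
        wf = rng.normal(size=1024)
        seg = self._segment(wf, fs=fs, n_segments=2)
        sv = acquisition_to_spectrum(seg)
        blocks = segment_and_center(seg)
        oracle_psds = [brute_force_psd(b, fs)[1] for b in blocks]
        freqs = brute_force_psd(blocks[0], fs)[0]
        oracle = bin_to_subbands(freqs, np.mean(oracle_psds, axis=0))
        np.testing.assert_allclose(sv.psd, oracle.psd, rtol=1e-6,
                                   atol=1e-6 * oracle.psd.max())

    def test_dc_offset_invariance(self, rng):
        wf = rng.normal(size=800)
        s1 = acquisition_to_spectrum(self._segment(wf))
        s2 = acquisition_to_spectrum(self._segment(wf + 11.3))
        np.testing.assert_allclose(s1.psd, s2.psd, rtol=1e-9,
                                   atol=1e-12 * s1.psd.max())

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(0.1, 50.0))
    def test_amplitude_scaling_squares_psd(self, c):
        rng = np.random.default_rng(7)
        wf = rng.normal(size=800)
        s1 = acquisition_to_spectrum(self._segment(wf))
        s2 = acquisition_to_spectrum(self._segment(c * wf))
        np.testing.assert_allclose(s2.psd, c ** 2 * s1.psd, rtol=1e-9)

    def test_acquisition_to_features_slices_requested_band(self, rng):
        wf = rng.normal(size=800)
        fv = acquisition_to_features(self._segment(wf), 1.0, 3.0)
        assert len(fv) == 2
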