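"""Welch band power, DFT phases, preferred phase angle, feature assembly.

The independent oracle here is a direct O(n^2) DFT summation evaluated on
the smallest geometry the 1-100 Hz feature grid admits; the module's FFT
path must agree with it to 1e-10.
"""

import numpy as np
import pytest

from ppafuse import (
    DEFAULT_BANDS,
    FREQ_GRID,
    BandScheme,
    Recording,
    SpectrumSet,
    band_psd_features,
    extract_feature_matrix,
    fft_phases,
    make_layout,
    preferred_phase_angle,
    welch_segment_length,
    welch_spectrum,
)

from conftest import tone_recording


def direct_dft(x, fs, freqs):
    """Brute-force DFT summation at integer frequencies (the oracle)."""
    n = len(x)
    T = n / fs
    out = np.empty(len(freqs), dtype=complex)
    for i, f in enumerate(freqs):
        k = int(round(f * T))
        out[i] = sum(x[m] * np.exp(-2j * np.pi * k * m / n) for m in range(n))
    return out


class TestDftOracle:
    def test_phases_match_bruteforce_summation(self, rng):
        # smallest geometry covering the 1-100 Hz grid: 1 s at 202 Hz
        x = rng.normal(size=202)
        rec = Recording("s", x[None, :], 202.0)
        expected = np.angle(direct_dft(x, 202.0, FREQ_GRID))
        got = fft_phases(rec).phase[0]
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_single_segment_power_matches_bruteforce(self, rng):
        x = rng.normal(size=202)
        rec = Recording("s", x[None, :], 202.0)
        got = welch_spectrum(rec, n_segments=1, overlap=0.0, window="boxcar").power[0]
        # one rectangular segment: density = |X(f)|^2 * 2 / (fs * n)
        mags = np.abs(direct_dft(x, 202.0, FREQ_GRID)) ** 2
        expected = 2 * mags / (202.0 * 202)
        expected[FREQ_GRID == 101] /= 2  # no doubling at Nyquist (not on grid)
        np.testing.assert_allclose(got, expected, rtol=1e-10)


class TestWelch:
    def test_paper_segment_geometry(self):
        # 180 s in 8 half-overlapping segments -> 40 s segments
        assert welch_segment_length(180.0, 8, 0.5) == pytest.approx(40.0)

    def test_pure_tone_power_concentration(self):
        rec = tone_recording(10, fs=250, duration=9)
        p = welch_spectrum(rec).power[0]
        assert p[9] == p.max()
        assert p[19] < 1e-6 * p[9]

    def test_white_noise_total_power_parseval(self, rng):
        # integrated one-sided density over [0, fs/2] recovers the variance
        sigma2 = 4.0
        totals = []
        for _ in range(10):
            rec = Recording("n", rng.normal(0, np.sqrt(sigma2), (1, 2250)), 250.0)
            spec = welch_spectrum(rec)
            # grid covers 1..100 of the 0..125 Hz support: integrate the grid
            # band and compare with the matching fraction of the variance
            totals.append(np.sum(spec.power[0]) * 1.0)
        band_fraction = (100 - 0.5) / 125  # grid band vs full one-sided support
        assert np.mean(totals) == pytest.approx(sigma2 * band_fraction, rel=0.10)

    def test_too_short_recording_rejected(self):
        rec = tone_recording(10, fs=250, duration=2)  # segments < 1 s
        with pytest.raises(ValueError, match="too short"):
            welch_spectrum(rec)

    def test_invalid_overlap_rejected(self):
        rec = tone_recording(10, fs=250, duration=9)
        with pytest.raises(ValueError, match="overlap"):
            welch_spectrum(rec, overlap=1.0)

    def test_circular_shift_invariance_stationary(self, rng):
        x = rng.normal(size=(1, 2250))
        a = welch_spectrum(Recording("a", x, 250.0)).power
        b = welch_spectrum(Recording("b", np.roll(x, 625, axis=1), 250.0)).power
        # band-averaged power barely moves under a circular time shift
        pa = band_psd_features(SpectrumSet(power=a))
        pb = band_psd_features(SpectrumSet(power=b))
        assert np.max(np.abs(pa - pb)) < 0.5  # dB


class TestBandPsd:
    def test_unit_flat_spectrum_is_zero_db(self):
        spec = SpectrumSet(power=np.ones((2, 100)))
        feats = band_psd_features(spec)
        np.testing.assert_allclose(feats, 0.0, atol=1e-12)

    def test_tenfold_spectrum_is_ten_db(self):
        spec = SpectrumSet(power=np.full((1, 100), 10.0))
        feats = band_psd_features(spec)
        np.testing.assert_allclose(feats, 10.0, atol=1e-12)

    def test_alpha_band_has_six_inclusive_bins(self):
        assert DEFAULT_BANDS.n_bins("alpha") == 6
        np.testing.assert_array_equal(DEFAULT_BANDS.bins("alpha"), [8, 9, 10, 11, 12, 13])

    def test_band_outside_grid_rejected(self):
        scheme = BandScheme((("uhf", 90, 120),))
        spec = SpectrumSet(power=np.ones((1, 100)))
        with pytest.raises(ValueError, match="grid"):
            band_psd_features(spec, scheme)


class TestFftPhases:
    def test_cosine_has_zero_phase(self):
        rec = tone_recording(10, fs=250, duration=9)
        assert fft_phases(rec).phase[0, 9] == pytest.approx(0.0, abs=1e-9)

    def test_sine_lags_cosine_by_half_pi(self):
        rec = tone_recording(10, fs=250, duration=9, phase=-np.pi / 2)  # sin
        assert fft_phases(rec).phase[0, 9] == pytest.approx(-np.pi / 2, abs=1e-9)

    def test_shift_theorem(self, rng):
        # delaying x by dt rotates theta(f) by -2 pi f dt (mod 2 pi)
        x = rng.normal(size=2250)
        fs, shift = 250.0, 50  # dt = 0.2 s
        a = fft_phases(Recording("a", x[None, :], fs)).phase[0]
        b = fft_phases(Recording("b", np.roll(x, shift)[None, :], fs)).phase[0]
        expected = -2 * np.pi * FREQ_GRID * (shift / fs)
        delta = np.angle(np.exp(1j * (b - a - expected)))
        np.testing.assert_allclose(delta, 0.0, atol=1e-9)

    def test_non_integer_second_duration_rejected(self):
        rec = Recording("s", np.zeros((1, 2375)), 250.0)  # 9.5 s
        with pytest.raises(ValueError, match="integer number of seconds"):
            fft_phases(rec)


class TestPreferredPhaseAngle:
    def test_identical_phasors(self):
        ppa, cons = preferred_phase_angle(np.full(6, 1.2))
        assert ppa == pytest.approx(1.2)
        assert cons == pytest.approx(1.0)

    def test_two_symmetric_bins(self):
        ppa, cons = preferred_phase_angle(np.array([np.pi / 3, -np.pi / 3]))
        assert ppa == pytest.approx(0.0, abs=1e-12)
        assert cons == pytest.approx(0.5)

    def test_uniform_circle_degenerate(self):
        phases = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ppa, cons = preferred_phase_angle(phases)
        assert cons < 1e-12
        assert ppa == 0.0  # degeneracy convention, never an exception

    def test_consistency_bounds_and_equality_case(self, rng):
        for _ in range(50):
            phases = rng.uniform(-np.pi, np.pi, size=rng.integers(2, 20))
            _, cons = preferred_phase_angle(phases)
            assert 0.0 <= cons <= 1.0 + 1e-12
        # equality only when all phasors align
        _, cons = preferred_phase_angle(np.full(5, -2.7))
        assert cons == pytest.approx(1.0)

    def test_rotation_equivariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=6)
        c = 0.9
        ppa0, cons0 = preferred_phase_angle(phases)
        ppa1, cons1 = preferred_phase_angle(phases + c)
        assert np.angle(np.exp(1j * (ppa1 - ppa0 - c))) == pytest.approx(0.0, abs=1e-9)
        assert cons1 == pytest.approx(cons0)

    def test_band_selection_from_full_grid(self, rng):
        grid = rng.uniform(-np.pi, np.pi, size=(2, 100))
        ppa, cons = preferred_phase_angle(grid, band=(8, 13))
        expect, _ = preferred_phase_angle(grid[:, 7:13])
        np.testing.assert_allclose(ppa, expect)


class TestAmplitudeInvariance:
    def test_scaling_moves_psd_not_ppa(self, rng):
        data = rng.normal(size=(2, 2250))
        rec = Recording("s", data, 250.0)
        scaled = Recording("s", 7.5 * data, 250.0)
        # PPA identical under positive scaling
        np.testing.assert_allclose(
            fft_phases(rec).phase, fft_phases(scaled).phase, atol=1e-9
        )
        # PSD shifts uniformly by 20 log10(scale) dB
        pa = band_psd_features(welch_spectrum(rec))
        pb = band_psd_features(welch_spectrum(scaled))
        np.testing.assert_allclose(pb - pa, 20 * np.log10(7.5), atol=1e-9)


class TestExtractFeatureMatrix:
    def test_single_channel_six_bands(self):
        rec = tone_recording(10, fs=250, duration=9, label="TD")
        fm = extract_feature_matrix([rec], "PSD")
        assert fm.values.shape == (1, 6)
        assert list(fm.descriptors["band"]) == DEFAULT_BANDS.names

    def test_column_order_channel_major(self, rng):
        recs = [
            Recording(f"s{i}", rng.normal(size=(3, 2250)), 250.0,
                      ["c1", "c2", "c3"], label="TD")
            for i in range(2)
        ]
        fm = extract_feature_matrix(recs, "PPA")
        assert fm.values.shape == (2, 18)
        assert list(fm.descriptors["channel"][:6]) == ["c1"] * 6
        assert list(fm.descriptors["band"][:6]) == DEFAULT_BANDS.names

    def test_hemisphere_subset_dimensions(self, rng):
        layout = make_layout(4, 2, 4)
        recs = [
            Recording(f"s{i}", rng.normal(size=(10, 2250)), 250.0,
                      list(layout.channel_names), label="ASD")
            for i in range(3)
        ]
        fm = extract_feature_matrix(recs, "PSD", layout=layout, subset="left")
        assert fm.values.shape == (3, 4 * 6)

    def test_heterogeneous_cohort_rejected(self, rng):
        a = Recording("a", rng.normal(size=(2, 2250)), 250.0)
        b = Recording("b", rng.normal(size=(2, 2500)), 250.0)
        with pytest.raises(ValueError, match="share"):
            extract_feature_matrix([a, b], "PSD")

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            extract_feature_matrix([tone_recording(10)], "PAC")
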