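import numpy as np
import pytest
import scipy.fft

from dyadiarize import (
    AudioRecording,
    FEATURE_NAMES,
    compute_chroma,
    compute_f0,
    compute_harmonic_ratio,
    compute_hf500,
    compute_mfcc,
    featurize_recording,
    make_frame_grid,
)
from dyadiarize.features import hz_to_mel, mel_to_hz, mel_filterbank, power_spectra

from conftest import SR, tone


def featurize(samples, sr=SR):
    rec = AudioRecording(np.asarray(samples, dtype=float), sr)
    grid = make_frame_grid(rec, 0.1)
    return featurize_recording(rec, grid)


class TestDegenerateFrames:
    def test_all_zero_frame_is_finite_and_silent_valued(self):
        samples = np.concatenate([np.zeros(1600), tone(300.0, 0.1)])
        fm = featurize(samples)
        assert np.all(np.isfinite(fm.values))
        row = dict(zip(FEATURE_NAMES, fm.values[0]))
        assert row["energy"] == 0.0
        assert row["zero_crossing_rate"] == 0.0
        assert row["hf500"] == 0.0
        assert row["harmonic_ratio"] == 0.0
        assert row["f0"] == 0.0


class TestSpectralShape:
    def test_tone_centroid_within_one_bin(self):
        fm = featurize(tone(1000.0))
        bin_hz = SR / 1600  # 10 Hz for the 0.1 s frame
        assert np.all(np.abs(fm.column("spectral_centroid") - 1000.0) <= bin_hz)

    def test_tone_f0_within_5pct(self):
        fm = featurize(tone(1000.0))
        assert np.all(np.abs(fm.column("f0") - 1000.0) <= 50.0)

    def test_white_noise_entropy_near_max(self):
        rng = np.random.default_rng(11)
        fm = featurize(rng.normal(0, 0.2, SR))
        # normalized spectral entropy: flat spectrum -> close to 1
        assert np.all(fm.column("spectral_entropy") > 0.9)

    def test_white_noise_harmonic_ratio_low(self):
        rng = np.random.default_rng(12)
        hr = compute_harmonic_ratio(rng.normal(size=1600), SR)
        assert hr < 0.3

    def test_flux_zero_on_first_frame_only_for_stationary_tone(self):
        fm = featurize(tone(500.0, 0.5))
        assert fm.column("spectral_flux")[0] == 0.0


class TestMfcc:
    def test_unit_mel_outputs_give_zero_coefficients(self):
        # identity filterbank + all-ones spectrum => log mel outputs all 0
        n_bins = 64
        coeffs = compute_mfcc(
            np.ones(n_bins), SR, n_coeffs=13, filterbank=np.eye(n_bins)
        )
        np.testing.assert_allclose(coeffs, 0.0, atol=1e-12)

    def test_spectrum_scaling_shifts_only_first_coefficient(self):
        rng = np.random.default_rng(3)
        spectrum = rng.uniform(0.5, 2.0, 801)
        c = 7.5
        base = compute_mfcc(spectrum, SR)
        scaled = compute_mfcc(c * spectrum, SR)
        delta = scaled - base
        np.testing.assert_allclose(delta[1:], 0.0, atol=1e-9)
        # additive term proportional to log c: ortho DCT coefficient 0 of a
        # constant vector v is sqrt(n_filters) * v
        assert delta[0] == pytest.approx(np.sqrt(40) * np.log(c), rel=1e-9)

    def test_tone_matches_independent_reference(self):
        """Loop-based mel-filterbank + DCT reference, written independently
        of the vectorized implementation."""
        frame = tone(1000.0, 0.1)
        spectrum = np.abs(scipy.fft.rfft(frame * np.hamming(frame.size))) ** 2
        got = compute_mfcc(spectrum, SR)

        n_filters, n_bins = 40, spectrum.size
        freqs = np.linspace(0.0, SR / 2.0, n_bins)
        edges = mel_to_hz(np.linspace(hz_to_mel(0.0), hz_to_mel(SR / 2.0), n_filters + 2))
        mel_out = np.zeros(n_filters)
        for i in range(n_filters):
            lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
            for b, f in enumerate(freqs):
                if lo <= f <= ctr:
                    w = (f - lo) / (ctr - lo)
                elif ctr < f <= hi:
                    w = (hi - f) / (hi - ctr)
                else:
                    w = 0.0
                mel_out[i] += w * (2.0 / (hi - lo)) * spectrum[b]
        log_mel = np.log(np.maximum(mel_out, 1e-10))
        expected = np.zeros(13)
        for k in range(13):
            scale = np.sqrt(1.0 / n_filters) if k == 0 else np.sqrt(2.0 / n_filters)
            expected[k] = scale * np.sum(
                log_mel * np.cos(np.pi * k * (2 * np.arange(n_filters) + 1) / (2 * n_filters))
            )
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-9)

    def test_all_zero_spectrum_finite(self):
        coeffs = compute_mfcc(np.zeros(801), SR)
        assert np.all(np.isfinite(coeffs))


class TestHf500:
    def test_low_tone_near_zero(self):
        fm = featurize(tone(200.0))
        assert np.all(fm.column("hf500") < 0.01)

    def test_high_tone_very_large(self):
        fm = featurize(tone(1000.0))
        assert np.all(fm.column("hf500") > 1e3)

    def test_symmetric_two_bin_spectrum_is_one(self):
        n_bins = 801
        freqs = np.linspace(0.0, SR / 2.0, n_bins)
        spectrum = np.zeros(n_bins)
        spectrum[np.argmin(np.abs(freqs - 300.0))] = 5.0
        spectrum[np.argmin(np.abs(freqs - 2000.0))] = 5.0
        assert compute_hf500(spectrum, SR) == pytest.approx(1.0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(Exception):
            compute_hf500(np.ones(100), 6000)


class TestChromaF0:
    def test_a440_concentrates_in_class_a(self):
        frame = tone(440.0, 0.1)
        spectrum = np.abs(scipy.fft.rfft(frame * np.hamming(frame.size))) ** 2
        chroma = compute_chroma(spectrum, SR)
        assert np.argmax(chroma) == 0  # class 0 = pitch class of the 440 Hz reference
        assert chroma[0] > 0.5

    def test_a440_f0(self):
        assert compute_f0(tone(440.0, 0.1), SR) == pytest.approx(440.0, rel=0.05)

    def test_zero_frame(self):
        assert compute_harmonic_ratio(np.zeros(1600), SR) == 0.0
        assert compute_f0(np.zeros(1600), SR) == 0.0


class TestInvariants:
    def test_gain_invariance(self):
        rng = np.random.default_rng(5)
        samples = tone(180.0, 0.5, amp=0.05) + rng.normal(0, 0.01, 8000)
        a = featurize(samples)
        b = featurize(3.7 * samples)
        invariant = [
            "zero_crossing_rate",
            "spectral_centroid",
            "spectral_entropy",
            "spectral_rolloff",
            "harmonic_ratio",
            "f0",
            "hf500",
        ] + [f"chroma_{i}" for i in range(1, 13)]
        for name in invariant:
            np.testing.assert_allclose(
                a.column(name), b.column(name), rtol=1e-6, atol=1e-9, err_msg=name
            )
        np.testing.assert_allclose(b.column("energy"), 3.7**2 * a.column("energy"), rtol=1e-9)

    def test_concatenation_equals_blockwise_except_flux_seam(self):
        rng = np.random.default_rng(6)
        x1 = rng.normal(0, 0.1, 4800)
        x2 = tone(250.0, 0.3)
        whole = featurize(np.concatenate([x1, x2]))
        part1, part2 = featurize(x1), featurize(x2)
        stacked = np.vstack([part1.values, part2.values])
        flux_col = FEATURE_NAMES.index("spectral_flux")
        seam = part1.n_frames
        np.testing.assert_allclose(
            np.delete(whole.values, seam, axis=0),
            np.delete(stacked, seam, axis=0),
            rtol=1e-9,
            atol=1e-12,
        )
        # the seam frame differs only in spectral flux
        diff = np.abs(whole.values[seam] - stacked[seam])
        diff[flux_col] = 0.0
        np.testing.assert_allclose(diff, 0.0, atol=1e-12)

    def test_filterbank_shape_and_coverage(self):
        fb = mel_filterbank(40, 801, SR)
        assert fb.shape == (40, 801)
        assert np.all(fb >= 0)
        # every interior frequency is covered by at least one filter
        assert np.all(fb[:, 5:-5].sum(axis=0) > 0)
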