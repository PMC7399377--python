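"""Short-term audio features on the non-overlapping 0.1 s frame grid.

Each frame yields a 36-dimensional vector: eight time/spectral-shape
features, 13 MFCCs, 12 chroma components, harmonic ratio, fundamental
frequency, and HF500 (the high/low spectral energy ratio used as a vocal
arousal correlate).

Conventions
-----------
* The DFT of a frame is computed over exactly that frame's samples after a
  Hamming window; temporal features (energy, zero crossings, autocorrelation
  for harmonic ratio / f0) use the raw frame.
* Degenerate (all-zero) frames map to finite values — never NaN/Inf.
  Log arguments and ratio denominators are floored at ``log_floor``.
* Spectral flux of frame 0 is defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .audio_io import AudioRecording, FrameGrid, ValidationError

#: canonical feature order; column schema of every FeatureMatrix
FEATURE_NAMES: tuple[str, ...] = (
    "energy",
    "zero_crossing_rate",
    "entropy_of_energy",
    "spectral_centroid",
    "spectral_spread",
    "spectral_entropy",
    "spectral_flux",
    "spectral_rolloff",
    *[f"mfcc_{i}" for i in range(1, 14)],
    *[f"chroma_{i}" for i in range(1, 13)],
    "harmonic_ratio",
    "f0",
    "hf500",
)

N_FEATURES = len(FEATURE_NAMES)  # 36


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the short-term feature extractor."""

    n_mfcc: int = 13
    n_mel_filters: int = 40
    chroma_ref_hz: float = 440.0  # A4 reference for pitch classes
    hf500_low_hz: tuple[float, float] = (80.0, 500.0)  # inclusive band
    hf500_high_hz: tuple[float, float] = (500.0, 3500.0)  # (low, high] band
    f0_min_hz: float = 50.0
    f0_max_hz: float = 1100.0
    rolloff_fraction: float = 0.90
    energy_entropy_blocks: int = 10
    log_floor: float = 1e-10


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class FeatureMatrix:
    """Per-frame feature values, one row per grid frame, 36 columns."""

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    source_id: str = ""
    window_s: float = 0.1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValidationError(
                f"feature matrix must be n_frames x {len(self.feature_names)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature matrix contains NaN/Inf")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=list(self.feature_names))


# ---------------------------------------------------------------------------
# Mel filterbank (Slaney convention: linear below 1 kHz, log above,
# area-normalized triangles)
# ---------------------------------------------------------------------------


def hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    linear = f / (200.0 / 3.0)
    log_region = f >= 1000.0
    logstep = np.log(6.4) / 27.0
    return np.where(log_region, 15.0 + np.log(np.maximum(f, 1e-12) / 1000.0) / logstep, linear)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    m = np.asarray(m, dtype=np.float64)
    logstep = np.log(6.4) / 27.0
    return np.where(m >= 15.0, 1000.0 * np.exp(logstep * (m - 15.0)), m * (200.0 / 3.0))


def mel_filterbank(
    n_filters: int, n_fft_bins: int, sample_rate: float
) -> np.ndarray:
    """Triangular mel filterbank weights, shape (n_filters, n_fft_bins).

    Filter edges are linearly spaced on the mel scale between 0 Hz and
    Nyquist; each triangle is normalized to unit area (Slaney).
    """
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_fft_bins)
    mel_edges = np.linspace(hz_to_mel(0.0), hz_to_mel(sample_rate / 2.0), n_filters + 2)
    hz_edges = mel_to_hz(mel_edges)
    fb = np.zeros((n_filters, n_fft_bins))
    for i in range(n_filters):
        lo, ctr, hi = hz_edges[i], hz_edges[i + 1], hz_edges[i + 2]
        rising = (fft_freqs - lo) / max(ctr - lo, 1e-12)
        falling = (hi - fft_freqs) / max(hi - ctr, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(rising, falling))
        fb[i] *= 2.0 / (hi - lo)  # area normalization
    return fb


# ---------------------------------------------------------------------------
# Single-spectrum / single-frame primitives
# ---------------------------------------------------------------------------


def compute_mfcc(
    power_spectrum: np.ndarray,
    sample_rate: float,
    n_coeffs: int = 13,
    n_filters: int = 40,
    log_floor: float = 1e-10,
    filterbank: np.ndarray | None = None,
) -> np.ndarray:
    """MFCCs of one frame: DCT-II (orthonormal) of the log mel-filtered
    power spectrum, first ``n_coeffs`` coefficients.

    Zero filter outputs are floored before the log, so all-zero spectra give
    finite coefficients.
    """
    spectrum = np.atleast_2d(np.asarray(power_spectrum, dtype=np.float64))
    if filterbank is None:
        filterbank = mel_filterbank(n_filters, spectrum.shape[1], sample_rate)
    mel_energies = spectrum @ filterbank.T
    log_mel = np.log(np.maximum(mel_energies, log_floor))
    coeffs = scipy.fft.dct(log_mel, type=2, norm="ortho", axis=1)[:, :n_coeffs]
    return coeffs[0] if np.asarray(power_spectrum).ndim == 1 else coeffs


def compute_hf500(
    power_spectrum: np.ndarray,
    sample_rate: float,
    low_band: tuple[float, float] = DEFAULT_CONFIG.hf500_low_hz,
    high_band: tuple[float, float] = DEFAULT_CONFIG.hf500_high_hz,
    log_floor: float = 1e-10,
) -> float | np.ndarray:
    """HF500: power in (500, 3500] Hz over power in [80, 500] Hz.

    Band membership is by FFT bin center frequency; the denominator is
    floored at ``log_floor`` so all-zero low bands give a large finite ratio
    (and all-zero frames give 0).
    """
    if sample_rate < 2 * high_band[1]:
        raise ValidationError(
            f"sample_rate {sample_rate} too low for the {high_band[1]} Hz band"
        )
    spectrum = np.atleast_2d(np.asarray(power_spectrum, dtype=np.float64))
    freqs = np.linspace(0.0, sample_rate / 2.0, spectrum.shape[1])
    low_mask = (freqs >= low_band[0]) & (freqs <= low_band[1])
    high_mask = (freqs > high_band[0]) & (freqs <= high_band[1])
    ratio = spectrum[:, high_mask].sum(axis=1) / np.maximum(
        spectrum[:, low_mask].sum(axis=1), log_floor
    )
    return float(ratio[0]) if np.asarray(power_spectrum).ndim == 1 else ratio


def compute_chroma(
    power_spectrum: np.ndarray,
    sample_rate: float,
    ref_hz: float = 440.0,
    log_floor: float = 1e-10,
) -> np.ndarray:
    """12-dimensional chroma: spectral power folded into pitch classes.

    Class 0 is the pitch class of ``ref_hz`` (A for the 440 Hz default).
    The vector is normalized to sum 1 (gain invariant); all-zero frames give
    the zero vector.
    """
    spectrum = np.atleast_2d(np.asarray(power_spectrum, dtype=np.float64))
    n_bins = spectrum.shape[1]
    freqs = np.linspace(0.0, sample_rate / 2.0, n_bins)
    valid = freqs > 27.5  # ignore DC/sub-audio bins
    classes = np.zeros(n_bins, dtype=int)
    classes[valid] = np.round(12.0 * np.log2(freqs[valid] / ref_hz)).astype(int) % 12
    chroma = np.zeros((spectrum.shape[0], 12))
    for c in range(12):
        mask = valid & (classes == c)
        chroma[:, c] = spectrum[:, mask].sum(axis=1)
    total = chroma.sum(axis=1, keepdims=True)
    chroma = np.where(total > log_floor, chroma / np.maximum(total, log_floor), 0.0)
    return chroma[0] if np.asarray(power_spectrum).ndim == 1 else chroma


def _autocorr_peaks(
    frames: np.ndarray,
    sample_rate: float,
    f0_min: float,
    f0_max: float,
    log_floor: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Harmonic ratio and f0 per frame via the normalized autocorrelation.

    frames: (n_frames, n_samples). Returns (harmonic_ratio, f0_hz).
    """
    n = frames.shape[1]
    nfft = scipy.fft.next_fast_len(2 * n)
    spec = np.abs(scipy.fft.rfft(frames, n=nfft, axis=1)) ** 2
    acf = scipy.fft.irfft(spec, n=nfft, axis=1)[:, :n]
    r0 = acf[:, 0]
    lag_min = max(2, int(np.floor(sample_rate / f0_max)))
    lag_max = min(n - 2, int(np.ceil(sample_rate / f0_min)))
    window = acf[:, lag_min : lag_max + 1]
    best = np.argmax(window, axis=1)
    idx = np.arange(frames.shape[0])
    peak = window[idx, best]
    hr = np.clip(peak / np.maximum(r0, log_floor), 0.0, 1.0)
    # parabolic refinement of the peak lag for sub-sample f0 precision
    lag = (lag_min + best).astype(np.float64)
    interior = (best > 0) & (best < window.shape[1] - 1)
    if np.any(interior):
        left = window[idx, np.maximum(best - 1, 0)]
        right = window[idx, np.minimum(best + 1, window.shape[1] - 1)]
        denom = left - 2 * peak + right
        shift = np.where(
            interior & (np.abs(denom) > log_floor), 0.5 * (left - right) / np.minimum(denom, -log_floor), 0.0
        )
        lag = lag + np.clip(shift, -1.0, 1.0)
    degenerate = r0 <= log_floor
    hr = np.where(degenerate, 0.0, hr)
    f0 = np.where(degenerate | (hr < 0.1), 0.0, sample_rate / lag)
    return hr, f0


def compute_harmonic_ratio(frame: np.ndarray, sample_rate: float) -> float:
    """Maximum normalized autocorrelation in the admissible pitch lag range."""
    hr, _ = _autocorr_peaks(
        np.atleast_2d(np.asarray(frame, dtype=np.float64)),
        sample_rate,
        DEFAULT_CONFIG.f0_min_hz,
        DEFAULT_CONFIG.f0_max_hz,
    )
    return float(hr[0])


def compute_f0(frame: np.ndarray, sample_rate: float) -> float:
    """Fundamental frequency (Hz) of the autocorrelation peak; 0 if unvoiced."""
    _, f0 = _autocorr_peaks(
        np.atleast_2d(np.asarray(frame, dtype=np.float64)),
        sample_rate,
        DEFAULT_CONFIG.f0_min_hz,
        DEFAULT_CONFIG.f0_max_hz,
    )
    return float(f0[0])


# ---------------------------------------------------------------------------
# Full per-recording extraction
# ---------------------------------------------------------------------------


def frame_signal(rec: AudioRecording, grid: FrameGrid) -> np.ndarray:
    """Samples reshaped to (n_frames, samples_per_frame); tail dropped."""
    spf = grid.samples_per_frame
    return rec.samples[: grid.n_frames * spf].reshape(grid.n_frames, spf)


def power_spectra(rec: AudioRecording, grid: FrameGrid) -> np.ndarray:
    """Hamming-windowed per-frame power spectra, shape (n_frames, spf//2 + 1)."""
    frames = frame_signal(rec, grid)
    window = np.hamming(frames.shape[1])
    return np.abs(scipy.fft.rfft(frames * window, axis=1)) ** 2


def featurize_recording(
    rec: AudioRecording, grid: FrameGrid, config: FeatureConfig = DEFAULT_CONFIG
) -> FeatureMatrix:
    """Compute the full 36-feature matrix for a recording on its grid."""
    frames = frame_signal(rec, grid)
    n_frames, spf = frames.shape
    floor = config.log_floor

    spectra = power_spectra(rec, grid)
    n_bins = spectra.shape[1]
    freqs = np.linspace(0.0, rec.sample_rate / 2.0, n_bins)
    total_power = spectra.sum(axis=1)
    safe_power = np.maximum(total_power, floor)
    nonzero = total_power > floor

    energy = np.mean(frames**2, axis=1)

    signs = np.sign(frames)
    signs[signs == 0] = 1
    zcr = np.mean(np.abs(np.diff(signs, axis=1)) / 2.0, axis=1)

    # entropy of energy over equal sub-blocks of the frame
    n_blocks = config.energy_entropy_blocks
    usable = (spf // n_blocks) * n_blocks
    block_e = (frames[:, :usable] ** 2).reshape(n_frames, n_blocks, -1).sum(axis=2)
    block_total = block_e.sum(axis=1, keepdims=True)
    p = block_e / np.maximum(block_total, floor)
    ent_energy = -np.sum(p * np.log2(np.maximum(p, floor)), axis=1)
    ent_energy = np.where(block_total[:, 0] > floor, ent_energy, 0.0)

    centroid = (spectra * freqs).sum(axis=1) / safe_power
    spread = np.sqrt(
        np.maximum((spectra * (freqs - centroid[:, None]) ** 2).sum(axis=1) / safe_power, 0.0)
    )
    centroid = np.where(nonzero, centroid, 0.0)
    spread = np.where(nonzero, spread, 0.0)

    p_spec = spectra / safe_power[:, None]
    spec_entropy = -np.sum(p_spec * np.log(np.maximum(p_spec, floor)), axis=1) / np.log(n_bins)
    spec_entropy = np.where(nonzero, spec_entropy, 0.0)

    flux = np.zeros(n_frames)
    if n_frames > 1:
        flux[1:] = np.sum((p_spec[1:] - p_spec[:-1]) ** 2, axis=1)

    cum = np.cumsum(spectra, axis=1)
    threshold = config.rolloff_fraction * total_power
    roll_idx = np.argmax(cum >= threshold[:, None], axis=1)
    rolloff = np.where(nonzero, freqs[roll_idx], 0.0)

    fb = mel_filterbank(config.n_mel_filters, n_bins, rec.sample_rate)
    mfcc = compute_mfcc(
        spectra, rec.sample_rate, config.n_mfcc, filterbank=fb, log_floor=floor
    )

    chroma = compute_chroma(spectra, rec.sample_rate, config.chroma_ref_hz, floor)

    hr, f0 = _autocorr_peaks(frames, rec.sample_rate, config.f0_min_hz, config.f0_max_hz, floor)

    hf500 = compute_hf500(
        spectra, rec.sample_rate, config.hf500_low_hz, config.hf500_high_hz, floor
    )
    hf500 = np.where(nonzero, hf500, 0.0)

    values = np.column_stack(
        [energy, zcr, ent_energy, centroid, spread, spec_entropy, flux, rolloff]
        + [mfcc, chroma]
        + [hr, f0, hf500]
    )
    return FeatureMatrix(values, FEATURE_NAMES, rec.source_id, grid.window_s)
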