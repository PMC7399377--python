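"""Per-recording adaptive silence detection and voice-activity detection.

Silence detection fits an individual intensity threshold to every recording:
a two-class minimum-intra-class-variance (Otsu) split of the log frame
energies. Working in the log domain makes the split gain invariant: scaling
the recording shifts all log energies by a constant, moving the threshold
with them and leaving the SIL/NONSIL stream unchanged.

Voice-activity detection distinguishes voiced speech from non-speech noise
inside the non-silent portions. The original pipeline delegated this to an
external MLP-based system; here the detector is a pluggable contract
(:class:`VadDetector`) with a lightweight default built on harmonicity,
spectral flatness, and energy cues, calibrated on the synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np

from .audio_io import (
    SIL,
    NONSIL,
    VOICED,
    UNVOICED,
    AudioRecording,
    FrameGrid,
    LabelStream,
    ValidationError,
)
from .features import FeatureMatrix, featurize_recording, frame_signal


@dataclass
class SilenceResult:
    stream: LabelStream  # over {SIL, NONSIL}
    threshold: float  # in frame-energy units
    degenerate: bool = False  # constant-intensity input, everything NONSIL


@dataclass
class VadResult:
    stream: LabelStream  # over {VOICED, UNVOICED}
    detector_id: str


# ---------------------------------------------------------------------------
# Silence detection
# ---------------------------------------------------------------------------

_LOG_FLOOR = 1e-12
#: log10-energy range below which the intensity distribution is treated as
#: single-class (no silent mode to separate)
_DEGENERATE_RANGE = 0.1


def _otsu_split(values: np.ndarray, n_bins: int = 128) -> float:
    """Threshold minimizing intra-class variance of a 1-D sample.

    Returns a value strictly inside (min, max); assumes max > min.
    """
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(np.float64)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    mu_total = cum_mu[-1] / total
    # between-class variance for every split point (maximizing it minimizes
    # the intra-class variance)
    w0 = cum_w / total
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(valid, cum_mu / np.maximum(cum_w, 1), 0.0)
    mu1 = np.where(valid, (cum_mu[-1] - cum_mu) / np.maximum(total - cum_w, 1), 0.0)
    between = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(between))
    return float(edges[k + 1])


def estimate_silence_threshold(intensity: np.ndarray) -> tuple[float, bool]:
    """Per-recording intensity threshold from the per-frame intensity vector.

    Returns ``(threshold, degenerate)``; the threshold is in the intensity
    units of the input. With a (near-)constant intensity vector the
    distribution has no silent mode: the minimum is returned with the
    degenerate flag set, which classifies every frame as non-silent.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.size < 10:
        raise ValidationError("need at least 10 frames to estimate a silence threshold")
    log_i = np.log10(np.maximum(intensity, _LOG_FLOOR))
    if log_i.max() - log_i.min() < _DEGENERATE_RANGE:
        return float(intensity.min()), True
    split = _otsu_split(log_i)
    split = float(np.clip(split, log_i.min(), log_i.max()))
    return float(10.0**split), False


def frame_intensity(rec: AudioRecording, grid: FrameGrid) -> np.ndarray:
    """Mean-square energy per frame — the intensity measure thresholded."""
    frames = frame_signal(rec, grid)
    return np.mean(frames**2, axis=1)


def detect_silence(rec: AudioRecording, grid: FrameGrid) -> SilenceResult:
    """SIL/NONSIL stream: a frame is SIL iff its intensity falls below the
    recording's adaptive threshold."""
    intensity = frame_intensity(rec, grid)
    threshold, degenerate = estimate_silence_threshold(intensity)
    if degenerate:
        labels = np.full(grid.n_frames, NONSIL, dtype=object)
    else:
        labels = np.where(intensity < threshold, SIL, NONSIL).astype(object)
    return SilenceResult(
        LabelStream(labels, (SIL, NONSIL), grid.frame_rate), threshold, degenerate
    )


# ---------------------------------------------------------------------------
# Voice activity detection
# ---------------------------------------------------------------------------


class VadDetector(Protocol):
    """Plug-in contract for voice-activity detectors.

    A detector maps the per-frame feature matrix to a boolean voiced mask of
    the same length. Implementations may use temporal context across rows.
    """

    detector_id: str

    def __call__(self, features: FeatureMatrix) -> np.ndarray: ...


@dataclass
class DefaultVad:
    """Rule-based voiced/unvoiced detector on harmonicity + spectral flatness
    + energy cues.

    A frame is voiced when it is harmonically structured (autocorrelation
    peak above ``hr_min``), spectrally peaked rather than flat (normalized
    spectral entropy below ``entropy_max``), and carries non-negligible
    energy relative to the recording's loud frames. Thresholds are fixed;
    they were calibrated once on the synthetic harmonic-vs-noise fixtures.
    """

    hr_min: float = 0.35
    entropy_max: float = 0.85
    energy_rel_floor: float = 1e-6  # relative to the 95th-percentile frame energy
    detector_id: str = "default-harmonicity-vad"

    def __call__(self, features: FeatureMatrix) -> np.ndarray:
        hr = features.column("harmonic_ratio")
        entropy = features.column("spectral_entropy")
        energy = features.column("energy")
        e_ref = np.percentile(energy, 95)
        energetic = energy > self.energy_rel_floor * max(e_ref, 1e-300)
        return (hr >= self.hr_min) & (entropy <= self.entropy_max) & energetic


def detect_voice_activity(
    rec: AudioRecording,
    grid: FrameGrid,
    detector: VadDetector | None = None,
    features: FeatureMatrix | None = None,
) -> VadResult:
    """VOICED/UNVOICED stream over the whole recording.

    VAD runs on every frame (not only non-silent ones); precedence against
    silence detection is resolved downstream in aggregation. A precomputed
    feature matrix can be passed to avoid recomputation.
    """
    if detector is None:
        detector = DefaultVad()
    if features is None:
        features = featurize_recording(rec, grid)
    try:
        voiced = np.asarray(detector(features), dtype=bool)
    except Exception as exc:
        raise RuntimeError(f"VAD detector '{detector.detector_id}' failed: {exc}") from exc
    if voiced.shape != (grid.n_frames,):
        raise ValidationError(
            f"detector '{detector.detector_id}' returned {voiced.shape}, "
            f"expected ({grid.n_frames},)"
        )
    labels = np.where(voiced, VOICED, UNVOICED).astype(object)
    return VadResult(LabelStream(labels, (VOICED, UNVOICED), grid.frame_rate), detector.detector_id)


def close_short_gaps(stream: LabelStream, max_gap_s: float = 0.3) -> LabelStream:
    """Optional morphological smoothing: relabel SIL runs shorter than
    ``max_gap_s`` as NONSIL. Off by default in the pipeline."""
    labels = stream.labels.copy()
    max_frames = int(round(max_gap_s * stream.frame_rate))
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == SIL:
            j = i
            while j < n and labels[j] == SIL:
                j += 1
            interior = i > 0 and j < n
            if interior and (j - i) < max_frames:
                labels[i:j] = NONSIL
            i = j
        else:
            i += 1
    return LabelStream(labels, stream.alphabet, stream.frame_rate)
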