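"""Audio and label artifact I/O, the canonical frame grid, and label encodings.

Every downstream stage (silence detection, VAD, feature extraction,
classification, aggregation, scoring) operates on the same non-overlapping
frame grid and on categorical label streams defined here.

Label alphabets
---------------
``SIL``/``NONSIL``     silence-detection stream
``VOICED``/``UNVOICED`` voice-activity stream
``P1``/``P2``          speaker stream (classifier output, speech frames only)
``NS``/``P1``/``P2``   final diarization stream and reference ground truth
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

# Canonical labels
NS = "NS"
P1 = "P1"
P2 = "P2"
SIL = "SIL"
NONSIL = "NONSIL"
VOICED = "VOICED"
UNVOICED = "UNVOICED"

SPEAKER_LABELS = (P1, P2)
DIAR_ALPHABET = (NS, P1, P2)

#: default analysis window width in seconds
DEFAULT_WINDOW_S = 0.1

MIN_SAMPLE_RATE = 8000


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class AudioRecording:
    """A mono audio signal with amplitudes in [-1, 1].

    Parameters
    ----------
    samples : np.ndarray
        1-D float array of amplitudes.
    sample_rate : int
        Sampling rate in Hz; must be >= 8000.
    source_id : str
        Identifier used in RTTM output and cache keys.
    """

    samples: np.ndarray
    sample_rate: int
    source_id: str = "recording"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("AudioRecording must be mono (1-D samples)")
        if self.samples.size == 0:
            raise ValidationError("AudioRecording must be non-empty")
        if self.sample_rate < MIN_SAMPLE_RATE:
            raise ValidationError(
                f"sample_rate must be >= {MIN_SAMPLE_RATE} Hz, got {self.sample_rate}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def scaled(self, gain: float) -> "AudioRecording":
        return AudioRecording(self.samples * gain, self.sample_rate, self.source_id)


@dataclass(frozen=True)
class FrameGrid:
    """Non-overlapping, contiguous analysis frames.

    Frame ``k`` covers ``[k * window_s, (k + 1) * window_s)`` seconds,
    0-based and half-open. A trailing partial window is dropped.
    """

    window_s: float
    n_frames: int
    sample_rate: int

    @property
    def samples_per_frame(self) -> int:
        return int(round(self.window_s * self.sample_rate))

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.window_s

    def frame_starts_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.window_s

    def frame_of_time(self, t_s: float) -> int:
        return int(np.floor(t_s / self.window_s))


@dataclass
class Annotation:
    """Human-made utterance annotation: (start_s, stop_s, speaker) triples.

    Utterances must be non-overlapping (dyadic non-overlap assumption) and are
    kept sorted by start time.
    """

    utterances: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        utts = [(float(a), float(b), str(s)) for a, b, s in self.utterances]
        for a, b, s in utts:
            if not a < b:
                raise ValidationError(f"utterance start {a} must precede stop {b}")
            if s not in SPEAKER_LABELS:
                raise ValidationError(f"speaker must be one of {SPEAKER_LABELS}, got {s!r}")
        utts.sort(key=lambda u: u[0])
        for (a0, b0, _), (a1, _, _) in zip(utts, utts[1:]):
            if a1 < b0:
                raise ValidationError(
                    f"utterances overlap at {a1:.3f}s (dyadic non-overlap assumption)"
                )
        self.utterances = utts

    @property
    def speakers(self) -> set[str]:
        return {s for _, _, s in self.utterances}

    def span(self) -> tuple[float, float]:
        if not self.utterances:
            return (0.0, 0.0)
        return (self.utterances[0][0], max(b for _, b, _ in self.utterances))

    def restricted(self, start_s: float, stop_s: float) -> "Annotation":
        """Utterances clipped to [start_s, stop_s]; partially covered ones are cut."""
        out = []
        for a, b, s in self.utterances:
            lo, hi = max(a, start_s), min(b, stop_s)
            if lo < hi:
                out.append((lo, hi, s))
        return Annotation(out)


@dataclass
class LabelStream:
    """A categorical per-frame stream at a fixed frame rate."""

    labels: np.ndarray
    alphabet: tuple[str, ...]
    frame_rate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        extra = set(self.labels) - set(self.alphabet)
        if extra:
            raise ValidationError(f"labels {extra} outside alphabet {self.alphabet}")

    def __len__(self) -> int:
        return self.labels.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelStream):
            return NotImplemented
        return (
            self.alphabet == other.alphabet
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.labels, other.labels)
        )


# ---------------------------------------------------------------------------
# Audio I/O
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31, np.dtype(np.uint8): 2**7}


def read_audio(path: str | os.PathLike, source_id: str | None = None) -> AudioRecording:
    """Read a PCM WAV file as a mono :class:`AudioRecording` in [-1, 1].

    Multi-channel input is averaged down to mono; integer PCM is rescaled by
    its full-scale value.
    """
    try:
        sample_rate, data = wavfile.read(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValidationError(f"zero-length audio in {path}")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        offset = scale if data.dtype == np.dtype(np.uint8) else 0
        samples = (data.astype(np.float64) - offset) / scale
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    if source_id is None:
        source_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return AudioRecording(samples, int(sample_rate), source_id)


def write_audio(path: str | os.PathLike, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM WAV (values clipped to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * (2**15 - 1)).astype(np.int16)
    wavfile.write(os.fspath(path), rec.sample_rate, pcm)


# ---------------------------------------------------------------------------
# Frame grid and label streams
# ---------------------------------------------------------------------------


def make_frame_grid(rec: AudioRecording, window_s: float = DEFAULT_WINDOW_S) -> FrameGrid:
    """Frame grid over ``rec``: ``floor(duration / window_s)`` frames."""
    if window_s <= 0:
        raise ValidationError("window_s must be positive")
    n_frames = rec.samples.size // int(round(window_s * rec.sample_rate))
    if n_frames < 1:
        raise ValidationError(
            f"window of {window_s}s longer than recording ({rec.duration_s:.3f}s)"
        )
    return FrameGrid(window_s=window_s, n_frames=int(n_frames), sample_rate=rec.sample_rate)


def annotation_to_stream(ann: Annotation, grid: FrameGrid) -> LabelStream:
    """Rasterize an annotation onto a grid as an {NS, P1, P2} stream.

    A frame gets a speaker label iff it lies entirely inside one utterance;
    frames only partially covered stay NS (mixed frames are never used to
    teach the classifier).
    """
    labels = np.full(grid.n_frames, NS, dtype=object)
    w = grid.window_s
    # tolerance absorbs float rounding of grid-aligned utterance boundaries
    eps = 1e-9
    for a, b, s in ann.utterances:
        first = int(np.ceil(a / w - eps))
        last = int(np.floor(b / w + eps))  # frame `last-1` is the last full frame
        first = max(first, 0)
        last = min(last, grid.n_frames)
        if first < last:
            labels[first:last] = s
    return LabelStream(labels, DIAR_ALPHABET, grid.frame_rate)


def stream_to_annotation(stream: LabelStream) -> Annotation:
    """Contiguous P1/P2 runs of a diarization stream as utterance intervals."""
    w = 1.0 / stream.frame_rate
    utts: list[tuple[float, float, str]] = []
    run_start, run_label = None, None
    for k, lab in enumerate(list(stream.labels) + [NS]):
        if lab != run_label:
            if run_label in SPEAKER_LABELS:
                utts.append((run_start * w, k * w, run_label))
            run_start, run_label = k, lab
    return Annotation(utts)


# ---------------------------------------------------------------------------
# Interchange formats: RTTM, annotation CSV, frame-label CSV
# ---------------------------------------------------------------------------


def read_rttm(path: str | os.PathLike) -> Annotation:
    """Read SPEAKER records of an RTTM file into an :class:`Annotation`."""
    utts = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] != "SPEAKER":
                continue
            tbeg, tdur, speaker = float(parts[3]), float(parts[4]), parts[7]
            utts.append((tbeg, tbeg + tdur, speaker))
    return Annotation(utts)


def write_rttm(path: str | os.PathLike, ann: Annotation, file_id: str) -> None:
    with open(path, "w") as fh:
        for a, b, s in ann.utterances:
            fh.write(f"SPEAKER {file_id} 1 {a:.3f} {b - a:.3f} <NA> <NA> {s} <NA> <NA>\n")


def read_annotation_csv(path: str | os.PathLike) -> Annotation:
    """Read a 3-column CSV (start_s, stop_s, speaker)."""
    df = pd.read_csv(path)
    cols = list(df.columns[:3])
    return Annotation([(r[cols[0]], r[cols[1]], r[cols[2]]) for _, r in df.iterrows()])


def write_annotation_csv(path: str | os.PathLike, ann: Annotation) -> None:
    pd.DataFrame(ann.utterances, columns=["start_s", "stop_s", "speaker"]).to_csv(
        path, index=False
    )


def write_label_csv(path: str | os.PathLike, stream: LabelStream) -> None:
    """Frame-level label CSV: frame_index, t_start_s, label."""
    w = 1.0 / stream.frame_rate
    pd.DataFrame(
        {
            "frame_index": np.arange(len(stream)),
            "t_start_s": np.arange(len(stream)) * w,
            "label": stream.labels,
        }
    ).to_csv(path, index=False)


def read_label_csv(path: str | os.PathLike, alphabet: Sequence[str] | None = None) -> LabelStream:
    df = pd.read_csv(path)
    labels = df["label"].astype(str).to_numpy(dtype=object)
    if len(df) > 1:
        frame_rate = 1.0 / float(df["t_start_s"].iloc[1] - df["t_start_s"].iloc[0])
    else:
        frame_rate = 10.0
    if alphabet is None:
        alphabet = tuple(sorted(set(labels)))
    return LabelStream(labels, tuple(alphabet), round(frame_rate, 6))
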