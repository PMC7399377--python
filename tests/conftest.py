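import numpy as np
import pytest

from dyadiarize import (
    AudioRecording,
    DialogueSpec,
    VoiceSpec,
    build_dialogue,
    make_frame_grid,
)

SR = 16000


def tone(freq_hz: float, duration_s: float = 1.0, sr: int = SR, amp: float = 0.5):
    t = np.arange(int(duration_s * sr)) / sr
    return amp * np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture(scope="session")
def tone_recording():
    return AudioRecording(tone(1000.0), SR, "tone1000")


@pytest.fixture(scope="session")
def easy_dialogue():
    """120 s dialogue with a 100 Hz f0 gap (well-separated speakers)."""
    return build_dialogue(
        VoiceSpec(f0_hz=110.0),
        VoiceSpec(f0_hz=210.0),
        DialogueSpec(duration_s=120.0, seed=7),
        source_id="easy",
    )


@pytest.fixture(scope="session")
def easy_grid(easy_dialogue):
    return make_frame_grid(easy_dialogue.recording, 0.1)
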