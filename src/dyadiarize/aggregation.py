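"""Merge the silence, voice-activity, and speaker streams into the final
diarization stream.

Precedence per frame: silence wins outright; among non-silent frames the
voice-activity stream decides whether the frame is noise (non-speech) or
speech; only speech frames take the classifier's speaker label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio_io import (
    DIAR_ALPHABET,
    NS,
    SIL,
    UNVOICED,
    LabelStream,
    ValidationError,
)

#: per-frame provenance tags
PROV_SILENCE = "silence"
PROV_VAD_NOISE = "vad_noise"
PROV_CLASSIFIER = "classifier"


@dataclass
class DiarizationStream:
    stream: LabelStream  # over {NS, P1, P2}
    provenance: np.ndarray  # per frame, in {silence, vad_noise, classifier}


def aggregate_streams(
    sil: LabelStream, vad: LabelStream, spk: LabelStream
) -> DiarizationStream:
    """Combine the three streams:

    ========  ==========  ======  ===========
    silence   voice act.  output  provenance
    ========  ==========  ======  ===========
    SIL       (any)       NS      silence
    NONSIL    UNVOICED    NS      vad_noise
    NONSIL    VOICED      spk     classifier
    ========  ==========  ======  ===========
    """
    n = len(sil)
    if not (len(vad) == n and len(spk) == n):
        raise ValidationError(
            f"stream length mismatch: sil={len(sil)} vad={len(vad)} spk={len(spk)}"
        )
    is_sil = sil.labels == SIL
    is_noise = ~is_sil & (vad.labels == UNVOICED)
    out = spk.labels.copy()
    out[is_sil | is_noise] = NS
    prov = np.full(n, PROV_CLASSIFIER, dtype=object)
    prov[is_noise] = PROV_VAD_NOISE
    prov[is_sil] = PROV_SILENCE
    return DiarizationStream(
        LabelStream(out, DIAR_ALPHABET, sil.frame_rate), prov
    )
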