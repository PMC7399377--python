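# dyadiarize

Supervised speaker diarization for **dyadic conversations** — "who speaks
when" in a two-person recording, such as a patient–therapist session
captured with a single microphone. The package targets behavioral and
psychotherapy process research, where diarization is today done either by
hand (accurate but slow) or with unsupervised clustering (fast but
error-prone). A *supervised* middle ground uses a small human-annotated
learning segment to train one classifier per conversation pair.

## Method

For each dyad:

1. **Learning set** — a human marks utterances (start, stop, speaker ∈
   {P1, P2}) in an initial segment of the recording (e.g., the first
   10 minutes).
2. **Silence detection** — an *individual* intensity threshold is fitted to
   every recording by a two-class minimum-intra-class-variance (Otsu) split
   of the log frame energies, yielding a SIL/NONSIL stream.
3. **Voice activity detection** — a pluggable detector separates voiced
   speech from non-speech noise; the built-in default uses harmonicity,
   spectral-flatness and energy cues.
4. **Feature extraction** — 36 features per non-overlapping 0.1 s window:
   energy, zero-crossing rate, entropy of energy, spectral centroid +
   spread, spectral entropy, spectral flux, spectral roll-off, 13 MFCCs,
   12 chroma components, harmonic ratio, fundamental frequency, and HF500
   (power in (500, 3500] Hz over power in [80, 500] Hz).
5. **Learning** — a random forest of 500 trees (Breiman: bootstrap
   bagging, √p feature subsetting, Gini) is trained on the speech frames of
   the learning segment only. The **out-of-bag (OOB) error** — each
   training frame judged only by the trees that did not sample it —
   estimates the dyad's generalization error without a test set.
6. **Prediction** — every frame of the rest of the recording receives a
   P1/P2 vote (including silent frames; see step 7).
7. **Aggregation** — per frame: silence ⇒ non-speech; non-silent ∧
   unvoiced ⇒ non-speech (noise); non-silent ∧ voiced ⇒ the classifier's
   speaker label.

Scoring uses the **diarization error rate**
`DER = SpE + MSp + FASp` (speaker error + missed speech + false alarm, as
percentages of scored frames). Reference streams at 100 frames/s are
summarized 10:1 to the prediction rate; *transitional* blocks containing
more than one reference label are excluded. Because the annotation fixes
speaker identity, no optimal speaker remapping is applied.

A fully seeded **synthetic corpus generator** builds labeled dyadic
dialogues from two harmonic voices (decaying harmonics, formant envelope,
f0 jitter) arranged sequentially with silences, with 100 fps ground truth —
so the whole pipeline is testable offline. The f0 gap between the voices is
the difficulty knob (large gap ≈ different-sex dyad, zero gap ≈
indistinguishable speakers).

## Worked example

```python
from dyadiarize import (VoiceSpec, DialogueSpec, build_dialogue, diarize_synthetic)

dlg = build_dialogue(VoiceSpec(f0_hz=110), VoiceSpec(f0_hz=210),
                     DialogueSpec(duration_s=120, seed=3))
diar, model, report = diarize_synthetic(dlg, learn_span=(0, 60),
                                        test_span=(60, 120), seed=1)
print(f"oob={model.oob_error:.3f} DER={report.der_pct:.2f}% "
      f"(SpE {report.speaker_error_pct:.2f}, MSp {report.missed_speech_pct:.2f}, "
      f"FASp {report.false_alarm_pct:.2f})")
```

prints

```
oob=0.000 DER=0.00% (SpE 0.00, MSp 0.00, FASp 0.00)
```

— with a 100 Hz fundamental gap the two synthetic voices are trivially
separable, so the forest's OOB error and every DER component on the held-out
minute are zero. Shrinking the gap raises both together: the same run with
`VoiceSpec(f0_hz=120)` for the second voice gives `oob=0.003` and
`DER=5.11%`, all of it speaker error.

The same pipeline runs from the shell:

```sh
dyadiarize synth --out-dir corpus --n-dyads 1 --duration 240 --seed 2
dyadiarize run corpus/dyad_000.wav corpus/dyad_000.rttm \
    --reference corpus/dyad_000_truth100.csv \
    --learn-span 0 120 --test-span 120 240 --out-dir out
dyadiarize run-corpus --out-dir corpus_out --n-dyads 6
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

generates a six-dyad synthetic corpus spanning f0 gaps of 100/50/10 Hz,
runs the full pipeline (2-minute learning segment, 2-minute test segment,
500 trees per dyad), prints each dyad's OOB error and DER decomposition,
and writes the results JSON.

Published corpus-scale error rates were measured on an external synthetic
speech corpus built from audiobook recordings (dialogues > 20 min, 10-min
learn / 10-min test); reproducing those numbers requires downloading that
corpus and is out of scope here. On such data the method is reported to
reach mid-single-digit mean DER; this repository validates the pipeline
property-wise on its own generator instead.
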