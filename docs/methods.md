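# Methods

## Model and assumptions

The pipeline performs supervised diarization of a two-person conversation
under three assumptions: (i) exactly two speakers, known a priori; (ii) no
overlapping speech (the scoring model carries an overlap term but it is
identically zero in scope); (iii) a per-dyad classifier need not generalize
across dyads — one forest is trained per conversation pair from its own
annotated learning segment.

All streams live on a canonical grid of non-overlapping 0.1 s windows,
0-based and half-open (`frame k = [0.1k, 0.1(k+1))`). A frame inherits a
speaker label from the human annotation only if it lies *entirely* inside
one utterance; boundary frames stay non-speech so the classifier is never
taught on acoustically mixed windows.

## Silence detection

The per-frame intensity measure is mean-square energy. The per-recording
threshold is the Otsu split (minimum intra-class variance over a 128-bin
histogram) of the log10 energies. Working on the log scale makes the split
invariant to global gain: scaling the audio by c shifts every log energy by
2·log10(c) and the threshold follows. If the log-energy range is below 0.1
(a constant-intensity recording has no silent mode to find), the detector
flags the input as degenerate and labels every frame non-silent rather than
splitting a unimodal distribution.

## Voice activity detection

The VAD is a contract (`VadDetector`: feature matrix → boolean voiced
mask), because the original procedure delegated this stage to an external
MLP-based system. The default detector is a fixed rule: voiced ⇔ harmonic
ratio ≥ 0.35 ∧ normalized spectral entropy ≤ 0.85 ∧ frame energy above
1e-6 × the 95th-percentile frame energy. The thresholds were calibrated
once on the repository's harmonic-vs-noise fixtures and are not tuned per
recording. VAD runs over the whole recording (including silent frames); the
precedence against silence detection is resolved in aggregation, where
silence wins. The published description of this stage is internally
ambiguous about whether VAD ran only on non-silent windows; running it
everywhere and letting aggregation arbitrate is the interpretation adopted
here and makes the merge a pure per-frame truth table.

## Features (36 per frame)

Spectral features use the frame's own DFT after a Hamming window; temporal
features (energy, zero crossings, autocorrelation) use the raw frame.
Columns, in order: energy; zero-crossing rate; entropy of energy (10
sub-blocks); spectral centroid and spread (Hz); normalized spectral entropy;
spectral flux (squared difference of sum-normalized spectra, 0 for frame 0);
roll-off (90% energy frequency); MFCC 1–13; chroma 1–12; harmonic ratio;
f0; HF500.

* **MFCC** — orthonormal DCT-II of the log outputs of a 40-filter
  triangular mel filterbank (Slaney convention: linear below 1 kHz,
  logarithmic above, unit-area triangles), coefficients 0–12. Log arguments
  are floored at 1e-10 so silent frames stay finite.
* **Chroma** — spectral power folded into 12 pitch classes referenced to
  A440, normalized to sum 1 (gain invariant); bins below 27.5 Hz ignored.
* **Harmonic ratio / f0** — maximum of the FFT-based autocorrelation,
  normalized by lag 0, over lags corresponding to 50–1100 Hz, with
  parabolic peak interpolation; f0 is 0 when the peak is below 0.1 or the
  frame is silent. The upper bound is deliberately above the speech range
  so pure-tone inputs up to ~1 kHz are tracked correctly.
* **HF500** — ratio of power in (500, 3500] Hz to power in [80, 500] Hz,
  bin membership by bin center, denominator floored at 1e-10 (a silent
  frame yields 0; a purely high-band frame yields a large finite value).
* The pair "centroid + spread" realizes the library convention in which the
  centroid routine returns both moments.

No feature standardization is applied: forests are insensitive to monotone
feature scaling.

## Classifier

`sklearn.ensemble.RandomForestClassifier` with 500 trees, bootstrap n-of-n
with replacement, `max_features="sqrt"` (⌊√36⌋ = 6), Gini impurity,
unlimited depth, and one integer seed per dyad recorded in the model
bundle. The OOB error is computed from the learning set alone. A
subsampling-without-replacement mode (63.2% of rows per tree) exists for
comparison but reports no OOB error, since out-of-bag semantics presuppose
the bootstrap; the with-replacement default is the configuration under
which the OOB ↔ test-error relationship is meaningful. Vote ties break
toward P1 (lexicographically smaller label), deterministically.

The learning set requires both speakers present and ≥ 100 frames; the
default protocol at corpus scale is "first half learn, second half test"
(10 min / 10 min on long recordings, 2 min / 2 min in the desk-scale
synthetic runs).

## Scoring

`DER = SpE + MSp + FASp` over N = all non-excluded summarized frames
(speech *and* non-speech). Using the common denominator makes the three
components exactly additive and `SpE + MSp + FASp + correct = 100`. A
100 fps reference is summarized 10:1; a block is kept only when unanimous,
otherwise excluded as transitional. No forgiveness collar is applied beyond
that exclusion (a configurable collar exists, default 0). Speaker mapping
is fixed by the supervision — never optimized as in unsupervised scoring —
so a globally swapped hypothesis scores 100% speaker error.

Corpus summaries report per-group mean/std of each component, the Pearson
correlation (with df = n−2) between per-dyad OOB error and speaker error,
and a Welch t between two groups' DER.

## Synthetic corpus: what it emulates, and what not

Each voice is a harmonic complex: fundamental f0, 30 harmonics decaying by
0.7 per partial, a formant envelope (Gaussian bumps at 500/1500/2500 Hz,
bandwidth 150 Hz, gain 1 + boost), per-utterance f0 jitter uniform within
±5%, and a 1% 5.5 Hz vibrato. Utterances of 1–3 s alternate (hold
probability 0.25) with 0.5–1.5 s silences, over a −50 dB white-noise floor;
edges are ramped over 10 ms. Ground truth is emitted at 100 frames/s,
sample-exact to the utterance boundaries. Both voices of a dyad share every
parameter except f0, so the f0 gap is the only systematic difficulty knob:
100 Hz emulates a different-sex dyad, 10 Hz a hard same-sex dyad, 0 Hz
statistically identical speakers (~50% speaker confusion on speech frames).
Defaults were chosen once as plausible speech-like values (male/female f0
around 110/210 Hz, conversational utterance and pause lengths); they were
not fitted to any corpus.

What a green end-to-end test establishes: the pipeline recovers known
ground truth through every stage, errors grow as voices converge, and the
OOB error tracks the test-set speaker error across difficulty. What it does
not establish: performance on real speech — the generator has no phonetic
variation, channel effects, reverberation, backchannels, or overlapping
speech, and its silences are near-digital. Synthetic dialogues run 4 min
(2 min learn / 2 min test) rather than 20+ min purely to keep the suite
fast; the protocol shape is unchanged.

## Numerical choices

* Log and ratio floors: 1e-10 (features), 1e-12 (silence log energies).
* Grid rasterization tolerance 1e-9 s so grid-aligned utterance boundaries
  are not lost to float rounding.
* WAV output is 16-bit PCM; round-trips are exact to ~1.5 LSB.
* Seeds: every stochastic step (voice synthesis, dialogue layout, forest)
  takes one integer seed; corpus builders derive per-dyad seeds as
  `(seed·100003 + i) mod (2³¹−1)`.

## Known limitations

* The default VAD is a fixed rule adequate for the synthetic fixtures; real
  recordings will want a trained detector plugged in via the contract.
* No smoothing of short speaker runs and no overlap handling.
* f0 estimation can make octave errors on strongly even-harmonic material;
  the classifier is robust to this (the error is speaker-consistent), but
  the f0 column should not be read as a calibrated pitch track.
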