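"""Diarization scoring: DER decomposition, reference summarization with
transitional-window exclusion, and corpus-level summaries.

The diarization error rate (DER) is the sum of three components, each a
percentage of the scored frames:

* speaker error (SpE)   — speech attributed to the wrong speaker,
* missed speech (MSp)   — reference speech predicted as non-speech,
* false alarm (FASp)    — reference non-speech predicted as speech.

Speaker identity is fixed by the supervision (the learning annotation names
the speakers), so no optimal relabeling is applied — unlike unsupervised DER
scoring. Reference streams at a finer frame rate (100 fps ground truth vs
the 10 fps prediction) are summarized block-wise; blocks containing more
than one reference label (transitional windows) are excluded from scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .audio_io import NS, SPEAKER_LABELS, LabelStream, ValidationError


@dataclass
class DERReport:
    """Per-dyad error decomposition, percentages of scored frames."""

    speaker_error_pct: float
    missed_speech_pct: float
    false_alarm_pct: float
    n_scored_frames: int
    n_excluded_transitional: int
    dyad_id: str = ""
    overlap_error_pct: float = 0.0  # always 0 for non-overlapping dyadic speech

    @property
    def der_pct(self) -> float:
        return (
            self.speaker_error_pct
            + self.missed_speech_pct
            + self.false_alarm_pct
            + self.overlap_error_pct
        )


@dataclass
class CorpusSummary:
    """Grouped means/stds plus the OOB-error vs speaker-error correlation."""

    group_stats: dict  # group -> {component -> (mean, std)}; std None if n<2
    group_sizes: dict
    oob_spe_r: float | None = None
    oob_spe_df: int | None = None
    oob_spe_p: float | None = None
    group_t: float | None = None  # Welch t between the two groups' DER
    group_t_df: float | None = None
    group_t_p: float | None = None
    flags: list[str] = field(default_factory=list)


def summarize_reference(
    ref: LabelStream, factor: int
) -> tuple[LabelStream, np.ndarray]:
    """Collapse blocks of ``factor`` reference frames to one frame each.

    A block keeps its label when unanimous; otherwise it is a transitional
    window and its position is flagged in the returned exclusion mask.
    Transitional blocks carry the block's first label as a placeholder but
    must not be scored. Trailing frames beyond the last full block are
    dropped.
    """
    if factor <= 0:
        raise ValidationError("summarization factor must be positive")
    n_blocks = len(ref) // factor
    if n_blocks == 0:
        raise ValidationError(f"reference shorter than one block of {factor}")
    blocks = ref.labels[: n_blocks * factor].reshape(n_blocks, factor)
    unanimous = np.all(blocks == blocks[:, :1], axis=1)
    out = blocks[:, 0].copy()
    excluded = ~unanimous
    return (
        LabelStream(out, ref.alphabet, ref.frame_rate / factor),
        excluded,
    )


def compute_der(
    ref: LabelStream,
    hyp: LabelStream,
    excluded_mask: np.ndarray | None = None,
    dyad_id: str = "",
) -> DERReport:
    """Score a hypothesis stream against a reference on the same grid.

    Percentages are over N = all non-excluded frames (speech and
    non-speech), which makes SpE + MSp + FASp + correct = 100 and the DER
    exactly the sum of its components.
    """
    if len(ref) != len(hyp):
        raise ValidationError(f"length mismatch: ref={len(ref)} hyp={len(hyp)}")
    if excluded_mask is None:
        excluded_mask = np.zeros(len(ref), dtype=bool)
    excluded_mask = np.asarray(excluded_mask, dtype=bool)
    if excluded_mask.shape != (len(ref),):
        raise ValidationError("exclusion mask length mismatch")
    scored = ~excluded_mask
    r = ref.labels[scored]
    h = hyp.labels[scored]
    n = r.size
    if n == 0:
        raise ValidationError("no scored frames after exclusion")
    ref_speech = np.isin(r, SPEAKER_LABELS)
    hyp_speech = np.isin(h, SPEAKER_LABELS)
    spe = np.sum(ref_speech & hyp_speech & (r != h))
    msp = np.sum(ref_speech & ~hyp_speech)
    fasp = np.sum(~ref_speech & hyp_speech)
    return DERReport(
        speaker_error_pct=100.0 * spe / n,
        missed_speech_pct=100.0 * msp / n,
        false_alarm_pct=100.0 * fasp / n,
        n_scored_frames=int(n),
        n_excluded_transitional=int(excluded_mask.sum()),
        dyad_id=dyad_id,
    )


_COMPONENTS = {
    "der": "der_pct",
    "speaker_error": "speaker_error_pct",
    "missed_speech": "missed_speech_pct",
    "false_alarm": "false_alarm_pct",
}


def summarize_corpus(
    reports: list[DERReport],
    oob: list[float] | None = None,
    groups: list[str] | None = None,
) -> CorpusSummary:
    """Corpus-level summary: per-group mean/std of each error component,
    Pearson correlation between per-dyad OOB error and speaker error, and a
    Welch two-sample t between the two groups' DER."""
    if len(reports) < 3:
        raise ValidationError("need >= 3 dyads for a corpus summary")
    if groups is None:
        groups = ["all"] * len(reports)
    flags: list[str] = []
    values = {
        name: np.array([getattr(rep, attr) for rep in reports])
        for name, attr in _COMPONENTS.items()
    }
    group_names = list(dict.fromkeys(groups))
    garr = np.asarray(groups)
    group_stats, group_sizes = {}, {}
    for g in group_names:
        mask = garr == g
        group_sizes[g] = int(mask.sum())
        stats_g = {}
        for name, vec in values.items():
            v = vec[mask]
            std = float(np.std(v, ddof=1)) if v.size >= 2 else None
            if std is None:
                flags.append(f"group '{g}' has < 2 dyads; std undefined")
            stats_g[name] = (float(np.mean(v)), std)
        group_stats[g] = stats_g

    summary = CorpusSummary(group_stats=group_stats, group_sizes=group_sizes, flags=flags)

    if oob is not None:
        oob_arr = np.asarray(oob, dtype=np.float64)
        spe = values["speaker_error"]
        if np.std(oob_arr) > 0 and np.std(spe) > 0:
            r, p = stats.pearsonr(oob_arr, spe)
            summary.oob_spe_r = float(r)
            summary.oob_spe_p = float(p)
        else:
            summary.oob_spe_r = 1.0 if np.array_equal(oob_arr, spe) else None
            summary.oob_spe_p = None
            flags.append("constant OOB or SpE vector; correlation degenerate")
        summary.oob_spe_df = len(reports) - 2

    if len(group_names) == 2:
        a = values["der"][garr == group_names[0]]
        b = values["der"][garr == group_names[1]]
        if a.size >= 2 and b.size >= 2:
            t_res = stats.ttest_ind(a, b, equal_var=False)
            summary.group_t = float(t_res.statistic)
            summary.group_t_p = float(t_res.pvalue)
            summary.group_t_df = float(t_res.df)
    return summary
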