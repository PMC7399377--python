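"""Per-dyad speaker classification with a 500-tree random forest.

One classifier is trained per conversation pair (dyad) from the manually
annotated learning segment. Only speech frames — labeled person-1 or
person-2, never silence — enter the learning set. The forest's out-of-bag
(OOB) error, computed on learning frames via the trees that did not sample
them, serves as a per-dyad estimate of the generalization error, so the
quality of a dyad's diarization can be judged without a separate test set.

The ensemble is Breiman's random forest (bootstrap n-of-n with replacement,
``sqrt`` feature subsetting at each split, Gini impurity, unlimited depth),
delegated to :class:`sklearn.ensemble.RandomForestClassifier`.
"""

from __future__ import annotations

import json
import os
import pickle
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .audio_io import (
    P1,
    P2,
    SPEAKER_LABELS,
    Annotation,
    FrameGrid,
    LabelStream,
    ValidationError,
    annotation_to_stream,
)
from .features import FeatureMatrix

MIN_LEARNING_FRAMES = 100
DEFAULT_N_TREES = 500


@dataclass
class LearningSet:
    """Speech frames (features + P1/P2 labels) from the learning span."""

    features: np.ndarray  # m x 36
    labels: np.ndarray  # m, over {P1, P2}
    dyad_id: str
    speech_minutes_per_speaker: dict[str, float]
    feature_schema: tuple[str, ...]

    def __post_init__(self) -> None:
        present = set(self.labels)
        if not present <= set(SPEAKER_LABELS):
            raise ValidationError(f"learning labels outside {SPEAKER_LABELS}: {present}")
        if present != set(SPEAKER_LABELS):
            missing = set(SPEAKER_LABELS) - present
            raise ValidationError(
                f"speaker(s) {missing} absent from the learning span of {self.dyad_id}"
            )
        if self.labels.size < MIN_LEARNING_FRAMES:
            raise ValidationError(
                f"learning set has {self.labels.size} frames; "
                f"need >= {MIN_LEARNING_FRAMES}"
            )


@dataclass
class DyadModel:
    """A trained per-dyad forest plus its OOB generalization estimate."""

    forest: RandomForestClassifier
    oob_error: float
    feature_schema: tuple[str, ...]
    dyad_id: str
    seed: int
    n_trees: int


def build_learning_set(
    features: FeatureMatrix,
    ann: Annotation,
    grid: FrameGrid,
    learn_span: tuple[float, float],
    dyad_id: str = "",
) -> LearningSet:
    """Assemble the learning set: frames inside ``learn_span`` that lie
    entirely within a single annotated utterance.

    Silence and partially covered boundary frames are excluded; both
    speakers must occur in the span.
    """
    start_s, stop_s = learn_span
    if not (0.0 <= start_s < stop_s):
        raise ValidationError(f"invalid learning span {learn_span}")
    if stop_s > grid.n_frames * grid.window_s + 1e-9:
        raise ValidationError(
            f"learning span {learn_span} extends beyond the recording "
            f"({grid.n_frames * grid.window_s:.1f}s)"
        )
    stream = annotation_to_stream(ann, grid)
    t = grid.frame_starts_s()
    in_span = (t >= start_s - 1e-9) & (t + grid.window_s <= stop_s + 1e-9)
    speech = np.isin(stream.labels, SPEAKER_LABELS)
    mask = in_span & speech
    labels = stream.labels[mask].astype(object)
    minutes = {
        s: float(np.sum(labels == s)) * grid.window_s / 60.0 for s in SPEAKER_LABELS
    }
    return LearningSet(
        features=features.values[mask],
        labels=labels,
        dyad_id=dyad_id or features.source_id,
        speech_minutes_per_speaker=minutes,
        feature_schema=features.feature_names,
    )


def train_dyad_model(
    ls: LearningSet,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    bootstrap_with_replacement: bool = True,
) -> DyadModel:
    """Train the dyad's forest and compute its out-of-bag error.

    With the default (Breiman) bootstrap, ``oob_error`` is the fraction of
    learning frames misclassified by the majority vote of their out-of-bag
    trees. The alternative subsampling-without-replacement mode (63.2% of
    rows per tree) has no out-of-bag frames in the same sense; it reports
    ``oob_error = nan``.
    """
    if np.allclose(ls.features.std(axis=0), 0.0):
        raise ValidationError("degenerate learning set: all features constant")
    common = dict(
        n_estimators=n_trees,
        max_features="sqrt",
        criterion="gini",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    if bootstrap_with_replacement:
        forest = RandomForestClassifier(bootstrap=True, oob_score=True, **common)
    else:
        forest = RandomForestClassifier(bootstrap=True, max_samples=0.632, **common)
    forest.fit(ls.features, ls.labels.astype(str))
    oob_error = 1.0 - forest.oob_score_ if bootstrap_with_replacement else float("nan")
    return DyadModel(
        forest=forest,
        oob_error=float(oob_error),
        feature_schema=ls.feature_schema,
        dyad_id=ls.dyad_id,
        seed=int(seed),
        n_trees=n_trees,
    )


def predict_speaker_stream(model: DyadModel, features: FeatureMatrix) -> LabelStream:
    """Predict P1/P2 for every frame (silence frames included — aggregation
    decides which predictions survive). Ties in the tree vote resolve toward
    P1, the lexicographically smaller label."""
    if features.feature_names != model.feature_schema:
        raise ValidationError("feature schema mismatch between model and input")
    proba = model.forest.predict_proba(features.values)
    classes = list(model.forest.classes_)
    # argmax prefers the earlier class on exact ties; classes_ is sorted, so
    # ties already break toward P1
    pred = np.asarray(classes, dtype=object)[np.argmax(proba, axis=1)]
    return LabelStream(pred, (P1, P2), 1.0 / features.window_s)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------


def save_model(model: DyadModel, directory: str | os.PathLike) -> None:
    """Persist a model bundle: forest pickle + JSON sidecar with metadata."""
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "forest.pkl"), "wb") as fh:
        pickle.dump(model.forest, fh)
    meta = {
        "format_version": 1,
        "dyad_id": model.dyad_id,
        "seed": model.seed,
        "n_trees": model.n_trees,
        "oob_error": model.oob_error,
        "feature_schema": list(model.feature_schema),
    }
    with open(os.path.join(directory, "model.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(directory: str | os.PathLike) -> DyadModel:
    with open(os.path.join(directory, "model.json")) as fh:
        meta = json.load(fh)
    with open(os.path.join(directory, "forest.pkl"), "rb") as fh:
        forest = pickle.load(fh)
    return DyadModel(
        forest=forest,
        oob_error=meta["oob_error"],
        feature_schema=tuple(meta["feature_schema"]),
        dyad_id=meta["dyad_id"],
        seed=meta["seed"],
        n_trees=meta["n_trees"],
    )
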