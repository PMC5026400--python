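"""RBF-SVM posture classification with leave-one-pig-out evaluation.

Each 2-s frame's feature triple {pitch, roll, activity} is mapped to one of
the five posture classes by a support vector machine with a radial basis
function kernel.  Features are z-scored with training-fold statistics and
the regularisation/kernel-width hyper-parameters are selected by an internal
stratified 3-fold grid search on macro-F1.  Generalisation to unseen animals
is estimated leave-one-pig-out (LOPO): each animal in turn is held out, the
model is trained on the rest, and predictions are pooled across folds before
computing per-class F1.

SVM fitting is quadratic in the number of frames, so training operates on a
stratified subsample (defaults: 1500 frames for the grid search, 4000 for
the final fit); prediction always uses every frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import EmptyInputError, LabelError
from .evaluation import frame_confusion
from .sensor_io import POSTURE_LABELS, AnnotationTrack

__all__ = [
    "DEFAULT_GRID",
    "LabelledFrameSet",
    "TrainedPostureModel",
    "label_frames",
    "train",
    "predict",
    "lopo_evaluate",
]

#: Hyper-parameter grid: SVM regularisation C and RBF kernel width gamma.
DEFAULT_GRID = {"svc__C": [0.1, 1.0, 10.0, 100.0], "svc__gamma": [0.01, 0.1, 1.0, 10.0]}

FEATURES = ["p", "r", "a"]


@dataclass
class LabelledFrameSet:
    """Per-frame features and posture labels for one animal."""

    animal_id: str
    features: pd.DataFrame  # columns p, r, a
    labels: np.ndarray  # posture label per frame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have equal length")
        unknown = set(np.unique(self.labels)) - set(POSTURE_LABELS)
        if unknown:
            raise LabelError(f"unknown labels {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class TrainedPostureModel:
    """Fitted scaler+SVM pipeline with training metadata."""

    pipeline: Pipeline
    selected_params: dict
    grid_searched: dict
    class_counts: dict
    seed: int


def label_frames(frames: pd.DataFrame, track: AnnotationTrack) -> LabelledFrameSet:
    """Label each frame by the posture interval containing its midpoint.

    Intervals are half-open ``[start, end)``.  Frames whose midpoint falls
    inside a transition interval are excluded; frames covered by no interval
    are dropped with a count warning.
    """
    mid = ((frames["start_s"] + frames["end_s"]) / 2.0).to_numpy(dtype=float)
    post = track.posture_intervals
    starts = np.array([iv[0] for iv in post])
    ends = np.array([iv[1] for iv in post])
    labels = np.array([iv[2] for iv in post])
    idx = np.searchsorted(starts, mid, side="right") - 1
    covered = (idx >= 0) & (mid < ends[np.clip(idx, 0, len(post) - 1)])

    in_transition = np.zeros(len(mid), dtype=bool)
    if track.transition_intervals:
        ts = np.array([iv[0] for iv in track.transition_intervals])
        te = np.array([iv[1] for iv in track.transition_intervals])
        j = np.searchsorted(ts, mid, side="right") - 1
        in_transition = (j >= 0) & (mid < te[np.clip(j, 0, len(ts) - 1)])

    keep = covered & ~in_transition
    n_uncovered = int(np.count_nonzero(~covered & ~in_transition))
    if n_uncovered:
        warnings.warn(
            f"dropped {n_uncovered} frames with midpoints outside all intervals",
            stacklevel=2,
        )
    return LabelledFrameSet(
        animal_id=track.animal_id,
        features=frames.loc[keep, FEATURES].reset_index(drop=True),
        labels=labels[idx[keep]],
    )


def _stratified_subsample(
    X: np.ndarray, y: np.ndarray, n_max: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if len(y) <= n_max:
        return X, y
    # Proportional allocation with a floor so scarce classes survive.
    idx_all = []
    classes, counts = np.unique(y, return_counts=True)
    floor = min(int(counts.min()), max(10, n_max // 20))
    alloc = np.maximum(np.round(counts / counts.sum() * n_max).astype(int), floor)
    for cls, take in zip(classes, alloc):
        pool = np.flatnonzero(y == cls)
        take = min(take, len(pool))
        idx_all.append(rng.choice(pool, size=take, replace=False))
    idx = np.sort(np.concatenate(idx_all))
    return X[idx], y[idx]


def train(
    train_set: LabelledFrameSet | list,
    grid: dict | None = None,
    seed: int = 0,
    class_weight=None,
    grid_subsample: int = 1500,
    fit_subsample: int = 4000,
) -> TrainedPostureModel:
    """Fit the scaler+RBF-SVM with internal grid search.

    ``train_set`` may be a single LabelledFrameSet or a list of them (their
    frames are concatenated).  Deterministic for a given seed.
    """
    sets = train_set if isinstance(train_set, list) else [train_set]
    X = np.concatenate([s.features[FEATURES].to_numpy(dtype=float) for s in sets])
    y = np.concatenate([s.labels for s in sets])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise EmptyInputError("training requires at least 2 posture classes")
    if counts.min() < 10:
        warnings.warn(
            f"classes with fewer than 10 frames present: "
            f"{dict(zip(classes[counts < 10], counts[counts < 10]))}",
            stacklevel=2,
        )
    grid = grid or DEFAULT_GRID
    rng = np.random.default_rng(seed)
    Xg, yg = _stratified_subsample(X, y, grid_subsample, rng)
    n_splits = min(3, int(np.unique(yg, return_counts=True)[1].min()))
    pipe = Pipeline(
        [("scaler", StandardScaler()), ("svc", SVC(kernel="rbf", class_weight=class_weight))]
    )
    if n_splits >= 2:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        search = GridSearchCV(pipe, grid, scoring="f1_macro", cv=cv, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # folds may miss scarce classes
            search.fit(Xg, yg)
        best = search.best_params_
    else:  # too little data for internal CV: mid-grid fallback
        best = {k: v[len(v) // 2] for k, v in grid.items()}
    Xf, yf = _stratified_subsample(X, y, fit_subsample, rng)
    pipe.set_params(**best)
    pipe.fit(Xf, yf)
    return TrainedPostureModel(
        pipeline=pipe,
        selected_params=best,
        grid_searched=grid,
        class_counts={c: int(n) for c, n in zip(classes, counts)},
        seed=seed,
    )


def predict(model: TrainedPostureModel, frames: pd.DataFrame) -> np.ndarray:
    """Predict one posture label per frame."""
    if len(frames) == 0:
        return np.array([], dtype=object)
    X = frames[FEATURES].to_numpy(dtype=float)
    return model.pipeline.predict(X)


def lopo_evaluate(datasets: list, grid: dict | None = None, seed: int = 0, **train_kwargs):
    """Leave-one-pig-out cross-validation.

    One fold per animal: train on all other animals, test on the held-out
    one.  Predictions are pooled across folds before computing the confusion
    matrix and per-class F1.

    Returns
    -------
    dict with keys ``confusion`` (DataFrame), ``per_class_f1`` (Series),
    ``mean_f1`` (float), ``folds`` (per-fold metadata list).
    """
    if len(datasets) < 2:
        raise EmptyInputError("LOPO needs at least 2 animals")
    pooled_true, pooled_pred, folds = [], [], []
    for k, held_out in enumerate(datasets):
        train_sets = [d for j, d in enumerate(datasets) if j != k]
        train_classes = set(np.concatenate([d.labels for d in train_sets]))
        missing = set(np.unique(held_out.labels)) - train_classes
        if missing:
            warnings.warn(
                f"fold {held_out.animal_id}: classes {sorted(missing)} absent from training",
                stacklevel=2,
            )
        model = train(train_sets, grid=grid, seed=seed, **train_kwargs)
        yhat = predict(model, held_out.features)
        pooled_true.append(held_out.labels)
        pooled_pred.append(yhat)
        folds.append(
            {
                "animal_id": held_out.animal_id,
                "n_test": len(held_out),
                "selected_params": model.selected_params,
            }
        )
    confusion, per_class, mean_f1 = frame_confusion(
        np.concatenate(pooled_true), np.concatenate(pooled_pred)
    )
    return {
        "confusion": confusion,
        "per_class_f1": per_class,
        "mean_f1": mean_f1,
        "folds": folds,
    }
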