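"""End-to-end processing pipeline with a reproducible run manifest.

``run_pipeline`` chains features -> transition detection/segmentation ->
transition kinematics -> (optional) classification against annotations ->
behaviour profile -> (optional) event evaluation, writing every intermediate
table as CSV plus a JSON report and a manifest (config hash, seed, package
versions).  Identical inputs, config and seed produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behaviour_profiles import profile
from .config import RunConfig, config_hash
from .errors import PipelineError, SowMotionError
from .evaluation import match_events, metrics_from_counts
from .posture_classification import label_frames, lopo_evaluate, predict, train
from .sensor_io import AnnotationTrack, SignalTrace, read_annotations, read_trace
from .features import extract_features
from .transition_detection import detect_and_segment, segments_to_frame
from .transition_features import featurize_all

log = logging.getLogger("sowmotion")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except SowMotionError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(
    trace_path,
    out_dir,
    cfg: RunConfig | None = None,
    annotation_path=None,
    evaluate: bool | None = None,
) -> dict:
    """Run the full workflow on one trace; returns the report dict.

    When ``annotation_path`` is given, frames are labelled from the posture
    annotations, a classifier is trained and applied (self-classification;
    use :func:`sowmotion.posture_classification.lopo_evaluate` for honest
    cross-animal scores), and detections are evaluated against the annotated
    transitions.
    """
    cfg = cfg or RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if evaluate is None:
        evaluate = annotation_path is not None
    if evaluate and annotation_path is None:
        raise PipelineError("stage 'evaluate' failed: no annotation file supplied")

    trace = _stage("read")(read_trace)(trace_path)
    track = _stage("read")(read_annotations)(annotation_path) if annotation_path else None

    frames = _stage("features")(extract_features)(trace, cfg.filter, cfg.frame)
    frames.to_csv(out_dir / "features.csv", index_label="index")

    segments = _stage("detect")(detect_and_segment)(trace, cfg.filter, cfg.frame, cfg.detect)
    segments_to_frame(segments).to_csv(out_dir / "segments.csv", index=False)

    tfeat = _stage("transition_features")(featurize_all)(segments, trace, frames)
    tfeat.to_csv(out_dir / "transition_features.csv", index=False)

    report: dict = {
        "animal_id": trace.animal_id,
        "duration_h": trace.duration_h,
        "n_frames": int(len(frames)),
        "n_detected_transitions": int(len(segments)),
    }

    labels = None
    if track is not None:
        labelled = _stage("classify")(label_frames)(frames, track)
        model = _stage("classify")(train)(
            labelled,
            seed=cfg.seed,
            class_weight=cfg.classify.class_weight,
            grid_subsample=cfg.classify.grid_subsample,
            fit_subsample=cfg.classify.fit_subsample,
        )
        labels = _stage("classify")(predict)(model, frames)
        pd.DataFrame(
            {
                "start_s": frames["start_s"],
                "end_s": frames["end_s"],
                "label": labels,
            }
        ).to_csv(out_dir / "predicted_labels.csv", index_label="index")
        report["selected_params"] = {k: float(v) for k, v in model.selected_params.items()}

    prof_labels = labels if labels is not None else np.array(["ST"])
    animal = {
        trace.animal_id
        or "trace": {
            "labels": prof_labels,
            "transition_features": tfeat,
            "span_s": trace.duration_s,
        }
    }
    profs = _stage("profile")(profile)(animal)
    prof = next(iter(profs.values()))
    prof.transition_frequency.to_csv(out_dir / "transition_frequency.csv", index=False)
    if labels is not None:
        report["time_budget"] = prof.time_budget.round(6).to_dict()

    if evaluate:
        counts = _stage("evaluate")(match_events)(
            segments, track.transition_intervals, cfg.evaluate.tolerance_s
        )
        metrics = metrics_from_counts(counts)
        report["event_counts"] = {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn}
        report["event_metrics"] = {
            "precision": round(metrics.precision, 3),
            "recall": round(metrics.recall, 3),
            "f1": round(metrics.f1, 3),
        }

    manifest = {
        "sowmotion_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "config": cfg.to_dict(),
        "inputs": {
            "trace": str(trace_path),
            "annotations": str(annotation_path) if annotation_path else None,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
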