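"""Pipeline orchestration: fuse -> detect -> extract -> featurise -> screen
-> select -> classify, with every intermediate persisted.

The two-stage procedure (detect fast-start events, then classify them as
escape or feeding) is multi-stage and partly interactive in practice —
the final variable set may be trimmed manually — so every stage writes its
output to disk and a run manifest records the configuration hash, seed and
package version, making any later manual step reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import TreeParams, cross_validate, train_tree
from .detect import (DetectionParams, detect_events, extract_routine,
                     extract_segment, magnitude_series, sliding_sd)
from .features import VariantSpec, VARIANTS, build_feature_table
from .fusion import FusionParams, fuse
from .sensor_io import (Dialect, LabelSet, LoggerSpec, SensorRecording,
                        ValidationError, read_labels, read_recording)
from .stats import cfs_select, screen_features

logger = logging.getLogger("finstart")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips through YAML unchanged."""

    recording: str = ""
    labels: str | None = None
    out_dir: str = "finstart-out"
    dialect: Dialect = field(default_factory=Dialect)
    logger_spec: LoggerSpec = field(default_factory=LoggerSpec)
    fusion: FusionParams = field(default_factory=FusionParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    metric_set: str = "both"           # axis | interaxial | both
    alpha: float = 0.05
    cv_folds: int = 10
    seed: int = 0
    include_features: list[str] = field(default_factory=list)  # manual trim
    exclude_features: list[str] = field(default_factory=list)
    tree: TreeParams = field(default_factory=TreeParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return Path(path)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for key, typ in (
            ("dialect", Dialect), ("logger_spec", LoggerSpec),
            ("fusion", FusionParams), ("detection", DetectionParams),
            ("tree", TreeParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                kwargs[key] = typ(**sub)
        return cls(**kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _label_for_centre(labels: LabelSet | None, source_id: str, centre: int,
                      tol: int) -> str:
    if labels is None:
        return "unknown"
    best, best_d = "unknown", tol + 1
    for e in labels.for_source(source_id):
        d = abs(e.centre_index - centre)
        if d <= tol and d < best_d:
            best, best_d = e.label, d
    return best


def run_pipeline(
    config: PipelineConfig, recording: SensorRecording | None = None
) -> dict:
    """Execute the full two-stage analysis and persist all intermediates.

    Returns a manifest dict (also written to ``manifest.json``) listing the
    stage outputs.  ``recording`` may be passed directly (e.g. from the
    simulator) instead of being read from ``config.recording``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    current = "read"

    def stage(name):
        nonlocal current
        current = name
        logger.info("pipeline stage: %s", name)

    try:
        stage("read")
        if recording is None:
            recording = read_recording(
                config.recording, config.dialect, config.logger_spec
            )
        labels = read_labels(config.labels) if config.labels else None

        stage("fuse")
        fused = fuse(recording, config.fusion)
        fused_df = pd.DataFrame(
            np.hstack([fused.quaternions, fused.dyn_acc,
                       fused.gravity_sensor_frame]),
            columns=["qw", "qx", "qy", "qz", "DAx", "DAy", "DAz",
                     "gravAx", "gravAy", "gravAz"],
        )
        fused_df.to_csv(out / "fused.csv", index=False)
        artifacts["fused"] = "fused.csv"

        stage("detect")
        fs = recording.spec.sampling_rate
        mags = magnitude_series(recording, fused, config.detection.use_dynamic)
        series = mags.ma if config.detection.channel == "MA" else mags.mg
        w = int(round(config.detection.window * fs))
        sd = sliding_sd(series, w, config.detection.stride)
        centres = detect_events(sd, mags.ma, config.detection, fs)
        ev_rows = []
        for c in centres:
            k = int(np.argmin(np.abs(sd.centres - c)))
            ev_rows.append((recording.source_id, c, float(sd.values[k])))
        pd.DataFrame(
            ev_rows, columns=["source_id", "centre_index", "peak_sd"]
        ).to_csv(out / "events.csv", index=False)
        artifacts["events"] = "events.csv"
        logger.info("detected %d events", len(centres))

        stage("extract")
        segments = []
        for c in centres:
            try:
                seg = extract_segment(recording, fused, c, config.detection.window)
            except IndexError:
                logger.warning("event at %d too close to recording edge", c)
                continue
            seg.label = _label_for_centre(labels, recording.source_id, c, w // 2)
            segments.append(seg)
        n_events = len(segments)
        try:
            segments += extract_routine(
                recording, fused, n_events, config.detection,
                seed=config.seed, event_centres=centres,
            )
        except ValidationError as exc:
            logger.warning("routine extraction skipped: %s", exc)

        stage("featurize")
        tables = {}
        for variant in VARIANTS:
            table = build_feature_table(
                segments, VariantSpec(variant), config.metric_set
            )
            fname = f"features-{variant}.csv"
            table.to_csv(out / fname, index=False)
            artifacts[f"features-{variant}"] = fname
            tables[variant] = table

        # classification needs labelled escape/feeding rows
        report = {}
        results_rows = []
        for variant, table in tables.items():
            binary = table[table["label"].isin(["escape", "feeding"])]
            counts = binary["label"].value_counts()
            if len(counts) < 2 or counts.min() < max(8, config.cv_folds):
                logger.warning(
                    "variant %s: not enough labelled events for "
                    "screening/classification", variant,
                )
                continue
            stage(f"screen[{variant}]")
            screening = screen_features(binary, config.alpha)
            fname = f"screening-{variant}.csv"
            screening.table.to_csv(out / fname, index=False)
            artifacts[f"screening-{variant}"] = fname

            stage(f"select[{variant}]")
            candidates = [
                f for f in screening.significant_features
                if f not in config.exclude_features
            ]
            selected = cfs_select(binary, candidates)
            for f in config.include_features:
                if f in binary.columns and f not in selected:
                    selected.append(f)
            if not selected:
                logger.warning("variant %s: empty feature selection", variant)
                continue

            stage(f"classify[{variant}]")
            subset = binary[selected + ["label"]]
            tree = train_tree(subset, config.tree)
            tree.to_json(out / f"model-{variant}.json")
            artifacts[f"model-{variant}"] = f"model-{variant}.json"
            ev = cross_validate(subset, config.cv_folds, config.seed, config.tree)
            report[variant] = {
                "selected_features": selected,
                "accuracy": ev.accuracy,
                "per_class": ev.per_class,
            }
            for cls, mets in ev.per_class.items():
                results_rows.append({
                    "variant": variant, "category": cls,
                    "accuracy": ev.accuracy, **mets,
                })

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        artifacts["report"] = "report.json"
        if results_rows:
            pd.DataFrame(results_rows).to_csv(
                out / "classification-rates.csv", index=False
            )
            artifacts["classification-rates"] = "classification-rates.csv"

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_events_detected": len(centres),
            "n_segments": len(segments),
            "artifacts": artifacts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed during stage {current!r}: {exc}"
        ) from exc


__all__ = ["PipelineConfig", "run_pipeline"]
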