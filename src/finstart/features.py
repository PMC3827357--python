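"""Axis-specific and inter-axial locomotor variables from 1-s segments.

For each body axis and each of acceleration / angular velocity, five
statistics are computed over the segment: Max (signed maximum), Range
(max − min), Mean, SD (sample, n−1) and RMS.  Inter-axial variables are the
differences of the same statistic between two axes — x−y, y−z and x−z —
which are less sensitive than absolute values to tag placement, animal
motivation and environment.

Variable names follow the established abbreviations (MaxAx, RangeGz,
DiffMaxAxAy, DiffRMSGxGz, ...) so tables cross-reference directly.

Three dataset variants control which channels feed the table:

* ``acc-only`` — raw acceleration (gravity retained), acceleration
  features only;
* ``gyro-only`` — angular velocity features only;
* ``all-combined`` — fused dynamic acceleration plus angular velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import EventSegment
from .sensor_io import ValidationError

STATS = ("Max", "Range", "Mean", "SD", "RMS")
ACC_AXES = ("Ax", "Ay", "Az")
GYRO_AXES = ("Gx", "Gy", "Gz")
#: Inter-axial pairs in their conventional order: x vs y, y vs z, x vs z.
PAIRS = ((0, 1), (1, 2), (0, 2))

VARIANTS = ("acc-only", "gyro-only", "all-combined")


@dataclass(frozen=True)
class VariantSpec:
    """Which channels a feature table is built from."""

    name: str = "all-combined"
    abs_max: bool = False   # use |max| instead of the signed maximum

    def __post_init__(self) -> None:
        if self.name not in VARIANTS:
            raise ValidationError(f"variant must be one of {VARIANTS}")

    @property
    def acc_source(self) -> str | None:
        return {"acc-only": "raw", "gyro-only": None, "all-combined": "dynamic"}[self.name]

    @property
    def use_gyro(self) -> bool:
        return self.name != "acc-only"


def axis_metrics(series: np.ndarray, abs_max: bool = False) -> dict[str, float]:
    """The five per-axis statistics of one channel over a segment."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("axis_metrics requires a non-empty series")
    mx = float(np.max(np.abs(x)) if abs_max else np.max(x))
    return {
        "Max": mx,
        "Range": float(np.max(x) - np.min(x)),
        "Mean": float(np.mean(x)),
        "SD": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "RMS": float(np.sqrt(np.mean(x**2))),
    }


def inter_axial(
    metrics_x: dict[str, float],
    metrics_y: dict[str, float],
    metrics_z: dict[str, float],
    axes: tuple[str, str, str],
) -> dict[str, float]:
    """All pairwise differences of the five statistics: x−y, y−z, x−z."""
    per_axis = (metrics_x, metrics_y, metrics_z)
    out: dict[str, float] = {}
    for stat in STATS:
        for i, j in PAIRS:
            out[f"Diff{stat}{axes[i]}{axes[j]}"] = per_axis[i][stat] - per_axis[j][stat]
    return out


def axis_feature_names(axes: tuple[str, str, str]) -> list[str]:
    return [f"{stat}{ax}" for stat in STATS for ax in axes]


def inter_axial_feature_names(axes: tuple[str, str, str]) -> list[str]:
    return [f"Diff{stat}{axes[i]}{axes[j]}" for stat in STATS for i, j in PAIRS]


def feature_names(
    variant: VariantSpec, metric_set: str = "both"
) -> list[str]:
    """Column order of a feature table for a variant.

    ``metric_set`` restricts to ``axis``, ``interaxial``, or ``both``.
    """
    names: list[str] = []
    groups = []
    if variant.acc_source is not None:
        groups.append(ACC_AXES)
    if variant.use_gyro:
        groups.append(GYRO_AXES)
    if metric_set in ("axis", "both"):
        for axes in groups:
            names += axis_feature_names(axes)
    if metric_set in ("interaxial", "both"):
        for axes in groups:
            names += inter_axial_feature_names(axes)
    if metric_set not in ("axis", "interaxial", "both"):
        raise ValidationError("metric_set must be axis|interaxial|both")
    return names


def segment_features(
    segment: EventSegment, variant: VariantSpec, metric_set: str = "both"
) -> dict[str, float]:
    """One feature row for a segment under a dataset variant."""
    channels: list[tuple[np.ndarray, tuple[str, str, str]]] = []
    if variant.acc_source == "raw":
        channels.append((segment.acc_raw, ACC_AXES))
    elif variant.acc_source == "dynamic":
        if segment.acc_dyn is None:
            raise ValidationError(
                f"variant {variant.name!r} needs dynamic acceleration but the "
                "segment carries none (run fusion first)"
            )
        channels.append((segment.acc_dyn, ACC_AXES))
    if variant.use_gyro:
        channels.append((segment.gyro, GYRO_AXES))

    row: dict[str, float] = {}
    axis_rows: dict[str, float] = {}
    inter_rows: dict[str, float] = {}
    for data, axes in channels:
        per_axis = [axis_metrics(data[:, k], variant.abs_max) for k in range(3)]
        for ax, m in zip(axes, per_axis):
            for stat in STATS:
                axis_rows[f"{stat}{ax}"] = m[stat]
        inter_rows.update(inter_axial(*per_axis, axes=axes))
    if metric_set in ("axis", "both"):
        row.update(axis_rows)
    if metric_set in ("interaxial", "both"):
        row.update(inter_rows)
    return row


def build_feature_table(
    segments: list[EventSegment],
    variant: VariantSpec = VariantSpec(),
    metric_set: str = "both",
) -> pd.DataFrame:
    """Feature table: one row per segment, plus a ``label`` column.

    Column order is fixed per variant; computation is independent of
    segment order.
    """
    cols = feature_names(variant, metric_set)
    rows = []
    for seg in segments:
        row = segment_features(seg, variant, metric_set)
        row["label"] = seg.label
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols + ["label"])
    return df


__all__ = [
    "STATS", "ACC_AXES", "GYRO_AXES", "PAIRS", "VARIANTS", "VariantSpec",
    "axis_metrics", "inter_axial", "axis_feature_names",
    "inter_axial_feature_names", "feature_names", "segment_features",
    "build_feature_table",
]
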