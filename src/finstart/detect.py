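"""Fast-start event detection by sliding-window SD of signal magnitude.

A fast-start (FS) is a brief (~0.2-0.5 s) burst of high acceleration and
rotation superimposed on routine swimming.  Detection thresholds the sample
standard deviation of the acceleration magnitude (MA) or angular-velocity
magnitude (MG) over a sliding 1-s window; an excursion above threshold is an
event, anchored at the local MA peak, and a fixed-length segment centred on
that peak is extracted for feature computation.

MA is computed on the raw measured acceleration (gravity included): the
windowed SD is insensitive to the quasi-constant gravity component, and the
magnitude series is defined before any gravity separation.  A config flag
allows the dynamic-acceleration magnitude instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fusion import AttitudeTrack
from .sensor_io import SensorRecording, ValidationError

#: Detection thresholds learned by a depth-1 decision tree on SD series
#: of tank-experiment data (m s^-2 for MA, deg s^-1 for MG).
DEFAULT_MA_THRESHOLD = 5.16
DEFAULT_MG_THRESHOLD = 129.32


@dataclass
class MagnitudeSeries:
    """Per-sample Euclidean magnitudes of acceleration (ma) and gyro (mg)."""

    ma: np.ndarray   # m s^-2
    mg: np.ndarray   # deg s^-1


@dataclass(frozen=True)
class DetectionParams:
    window: float = 1.0        # s
    stride: int = 1            # samples
    channel: str = "MA"        # "MA" | "MG"
    threshold: float | None = None   # channel units; None -> channel default
    refractory: float = 1.0    # s; events closer than this are merged
    use_dynamic: bool = False  # compute MA on dynamic rather than raw acc

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValidationError("window must be > 0")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.channel not in ("MA", "MG"):
            raise ValidationError("channel must be MA or MG")
        if self.threshold is not None and self.threshold <= 0:
            raise ValidationError("threshold must be > 0")
        if self.refractory < 0:
            raise ValidationError("refractory must be >= 0")

    @property
    def effective_threshold(self) -> float:
        if self.threshold is not None:
            return self.threshold
        return DEFAULT_MA_THRESHOLD if self.channel == "MA" else DEFAULT_MG_THRESHOLD


@dataclass
class EventSegment:
    """A fixed-length excerpt centred on the MA peak of one event.

    All three channel views (raw acceleration, dynamic acceleration, angular
    velocity) are retained so that every dataset variant can be featurised
    from the same segment.
    """

    source_id: str
    centre_index: int
    acc_raw: np.ndarray            # (w, 3) m s^-2
    acc_dyn: np.ndarray | None     # (w, 3) m s^-2; None if no fusion track
    gyro: np.ndarray               # (w, 3) deg s^-1
    sampling_rate: float
    label: str = "unknown"


@dataclass
class SlidingSD:
    """Sliding-window sample SD indexed at window-centre sample positions."""

    centres: np.ndarray   # sample indices into the source series
    values: np.ndarray
    window_samples: int
    stride: int = 1


def magnitude_series(
    rec: SensorRecording, fused: AttitudeTrack | None = None, use_dynamic: bool = False
) -> MagnitudeSeries:
    """Per-sample vector magnitudes MA and MG.

    ``ma_t = sqrt(Ax² + Ay² + Az²)`` on raw measured acceleration by default;
    with ``use_dynamic`` the fused dynamic acceleration is used instead.
    """
    if use_dynamic:
        if fused is None:
            raise ValidationError("use_dynamic requires a fused AttitudeTrack")
        acc = fused.dyn_acc
    else:
        acc = rec.acc
    return MagnitudeSeries(
        ma=np.linalg.norm(acc, axis=1),
        mg=np.linalg.norm(rec.gyro, axis=1),
    )


def sliding_sd(series: np.ndarray, window_samples: int, stride: int = 1) -> SlidingSD:
    """Sample SD (n−1 denominator) over a sliding window.

    Output has ``floor((n − w) / stride) + 1`` values; value ``k`` covers
    samples ``[k·stride, k·stride + w)`` and is indexed at that window's
    centre sample ``k·stride + w // 2``.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    w = int(window_samples)
    if w < 2:
        raise ValidationError("window must span at least 2 samples")
    if n < w:
        raise ValidationError(f"series of length {n} shorter than window {w}")
    rolled = pd.Series(series).rolling(w).std(ddof=1).to_numpy()[w - 1 :]
    starts = np.arange(0, n - w + 1, stride)
    return SlidingSD(
        centres=starts + w // 2,
        values=rolled[starts],
        window_samples=w,
        stride=stride,
    )


def detect_events(
    sd: SlidingSD,
    ma: np.ndarray,
    params: DetectionParams,
    sampling_rate: float,
) -> list[int]:
    """Event centre indices from a thresholded SD series.

    Contiguous super-threshold runs each yield one event at the MA maximum
    within the run's span; events closer than the refractory period are
    merged, keeping the larger MA peak.  Deterministic; may be empty.
    """
    thr = params.effective_threshold
    above = sd.values > thr
    if not above.any():
        return []
    # contiguous runs of super-threshold windows
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    events: list[int] = []
    for start, stop in zip(edges[::2], edges[1::2]):
        span = sd.centres[start:stop]
        lo, hi = int(span[0]), int(span[-1]) + 1
        peak = lo + int(np.argmax(ma[lo:hi]))
        events.append(peak)
    # refractory merge keeping the larger MA peak
    min_gap = int(round(params.refractory * sampling_rate))
    merged: list[int] = []
    for ev in sorted(events):
        if merged and ev - merged[-1] < min_gap:
            if ma[ev] > ma[merged[-1]]:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def extract_segment(
    rec: SensorRecording,
    fused: AttitudeTrack | None,
    centre_index: int,
    window: float = 1.0,
    label: str = "unknown",
) -> EventSegment:
    """Symmetric fixed-length excerpt centred on an event peak.

    The excerpt covers ``[centre − w//2, centre − w//2 + w)`` with
    ``w = round(window × sampling_rate)``.  No padding: a window overrunning
    the recording bounds is an error (the excerpt must be homogeneous data).
    """
    w = int(round(window * rec.spec.sampling_rate))
    start = centre_index - w // 2
    stop = start + w
    if start < 0 or stop > rec.n_samples:
        raise IndexError(
            f"segment [{start}, {stop}) around centre {centre_index} overruns "
            f"recording of {rec.n_samples} samples"
        )
    return EventSegment(
        source_id=rec.source_id,
        centre_index=centre_index,
        acc_raw=rec.acc[start:stop].copy(),
        acc_dyn=None if fused is None else fused.dyn_acc[start:stop].copy(),
        gyro=rec.gyro[start:stop].copy(),
        sampling_rate=rec.spec.sampling_rate,
        label=label,
    )


def extract_routine(
    rec: SensorRecording,
    fused: AttitudeTrack | None,
    n: int,
    params: DetectionParams = DetectionParams(),
    seed: int = 0,
    event_centres: list[int] | None = None,
) -> list[EventSegment]:
    """Draw ``n`` routine-movement segments from quiet stretches.

    Anchors are chosen seeded-randomly among samples whose windowed SD is
    below threshold, rejecting overlaps with each other and with any
    detected event window.  Raises with the achievable count when the
    recording has too little quiet data.
    """
    fs = rec.spec.sampling_rate
    w = int(round(params.window * fs))
    mags = magnitude_series(rec, fused, params.use_dynamic)
    series = mags.ma if params.channel == "MA" else mags.mg
    sd = sliding_sd(series, w, stride=1)
    quiet = sd.centres[sd.values <= params.effective_threshold]
    # exclude anchors whose window would overlap an event window
    if event_centres:
        ev = np.asarray(event_centres)
        keep = np.all(np.abs(quiet[:, None] - ev[None, :]) >= w, axis=1)
        quiet = quiet[keep]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(quiet))
    chosen: list[int] = []
    for idx in order:
        c = int(quiet[idx])
        if c - w // 2 < 0 or c - w // 2 + w > rec.n_samples:
            continue
        if all(abs(c - p) >= w for p in chosen):
            chosen.append(c)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValidationError(
            f"requested {n} routine segments but only {len(chosen)} "
            f"non-overlapping sub-threshold windows are available"
        )
    return [
        extract_segment(rec, fused, c, params.window, label="routine")
        for c in sorted(chosen)
    ]


__all__ = [
    "DEFAULT_MA_THRESHOLD", "DEFAULT_MG_THRESHOLD",
    "MagnitudeSeries", "DetectionParams", "EventSegment", "SlidingSD",
    "magnitude_series", "sliding_sd", "detect_events",
    "extract_segment", "extract_routine",
]
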