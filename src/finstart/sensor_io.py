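"""Reading, validation, and unit conversion of raw 9-axis logger channels.

A gyro logger records 3-axis acceleration, 3-axis angular velocity, and
3-axis magnetic field as plain delimited text, either in raw signed 16-bit
counts or already converted to physical units.  This module owns the logger
hardware description (:class:`LoggerSpec`), the validated in-memory container
(:class:`SensorRecording`), and the count <-> unit conversion.

Axis semantics (fish body frame, fixed throughout the package):

* ``x`` — lateral; rotation about x is pitch
* ``y`` — longitudinal / forward
* ``z`` — dorso-ventral; rotation about z is yaw

A logger at level rest reads about ``-g`` on its z acceleration channel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("finstart")

#: Closed label vocabulary for event segments.
CLASSES = ("escape", "feeding", "routine")

STANDARD_GRAVITY = 9.80665  # m s^-2


class ValidationError(ValueError):
    """Raised when channel data violates the logger specification."""


class ParseError(ValueError):
    """Raised on malformed recording or label files; carries a row number."""

    def __init__(self, message: str, row: int | None = None):
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)
        self.row = row


@dataclass(frozen=True)
class LoggerSpec:
    """Hardware description of the gyro logger.

    Defaults match a 500 Hz tag with ±16 g, ±1500 deg s⁻¹ and ±1.0 Gauss
    full-scale ranges at 16-bit resolution.
    """

    sampling_rate: float = 500.0          # Hz
    acc_range: float = 16.0               # g, full scale (±)
    gyro_range: float = 1500.0            # deg s^-1, full scale (±)
    mag_range: float = 1.0                # Gauss, full scale (±)
    counts_full_scale: int = 32768        # signed 16-bit
    gravity_constant: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be > 0")
        for name in ("acc_range", "gyro_range", "mag_range"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.counts_full_scale <= 0:
            raise ValidationError("counts_full_scale must be > 0")

    # count-to-unit scales -------------------------------------------------
    @property
    def acc_scale(self) -> float:
        """m s^-2 per count (range in g converted via gravity_constant)."""
        return self.acc_range * self.gravity_constant / self.counts_full_scale

    @property
    def gyro_scale(self) -> float:
        """deg s^-1 per count."""
        return self.gyro_range / self.counts_full_scale

    @property
    def mag_scale(self) -> float:
        """Gauss per count."""
        return self.mag_range / self.counts_full_scale


@dataclass
class SensorRecording:
    """Time-aligned 9-axis channel matrix.

    ``acc`` is in m s^-2, ``gyro`` in deg s^-1, ``mag`` in Gauss (or any
    uniform scaling thereof — downstream fusion normalises it).  The sample
    index is the only time base: ``time = index / spec.sampling_rate``.
    """

    acc: np.ndarray
    gyro: np.ndarray
    mag: np.ndarray
    spec: LoggerSpec = field(default_factory=LoggerSpec)
    source_id: str = ""
    clipped: np.ndarray | None = None   # boolean mask of saturated samples

    def __post_init__(self) -> None:
        self.acc = np.atleast_2d(np.asarray(self.acc, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        self.mag = np.atleast_2d(np.asarray(self.mag, dtype=float))
        n = self.acc.shape[0]
        for name, arr in (("acc", self.acc), ("gyro", self.gyro), ("mag", self.mag)):
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"{name} must be an (n, 3) array")
            if arr.shape[0] != n:
                raise ValidationError("acc, gyro and mag must have equal length")
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr).all(axis=1))[0])
                raise ValidationError(f"non-finite value in {name} at sample {bad}")
        self._flag_clipping()

    def _flag_clipping(self) -> None:
        """Flag out-of-range samples (±(range + 1 count)) instead of rejecting.

        Fast-start events can legitimately saturate a ±16 g accelerometer.
        """
        s = self.spec
        lims = (
            (self.acc, (s.acc_range * s.gravity_constant) + s.acc_scale),
            (self.gyro, s.gyro_range + s.gyro_scale),
            (self.mag, s.mag_range + s.mag_scale),
        )
        mask = np.zeros(self.n_samples, dtype=bool)
        for arr, lim in lims:
            mask |= (np.abs(arr) > lim).any(axis=1)
        if mask.any():
            logger.warning(
                "%d of %d samples exceed the sensor range and were flagged as clipped",
                int(mask.sum()), self.n_samples,
            )
        self.clipped = mask

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.spec.sampling_rate

    def slice(self, start: int, stop: int) -> "SensorRecording":
        return SensorRecording(
            acc=self.acc[start:stop], gyro=self.gyro[start:stop],
            mag=self.mag[start:stop], spec=self.spec, source_id=self.source_id,
        )


@dataclass(frozen=True)
class LabelEntry:
    source_id: str
    centre_index: int
    label: str


@dataclass
class LabelSet:
    """Event bookkeeping: (source_id, event-centre sample index, class)."""

    entries: list[LabelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.label not in CLASSES:
                raise ValidationError(
                    f"label {e.label!r} not in closed vocabulary {CLASSES}"
                )
            if e.centre_index < 0:
                raise ValidationError("centre_index must be >= 0")

    def for_source(self, source_id: str) -> list[LabelEntry]:
        return [e for e in self.entries if e.source_id == source_id]

    def validate_against(self, rec: SensorRecording) -> None:
        for e in self.for_source(rec.source_id):
            if e.centre_index >= rec.n_samples:
                raise ValidationError(
                    f"label centre {e.centre_index} beyond recording "
                    f"length {rec.n_samples} for {rec.source_id!r}"
                )


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def counts_to_units(
    counts: np.ndarray, sensor: str, spec: LoggerSpec, channel: str = ""
) -> np.ndarray:
    """Convert raw signed 16-bit counts to physical units.

    ``sensor`` is one of ``acc`` (→ m s⁻²), ``gyro`` (→ deg s⁻¹) or ``mag``
    (→ Gauss).  The mapping is linear: value = counts × range / full_scale,
    with acceleration additionally converted g → m s⁻².  The conversion is
    odd-symmetric: f(−c) = −f(c).
    """
    counts = np.asarray(counts, dtype=float)
    lo, hi = -spec.counts_full_scale, spec.counts_full_scale
    bad = (counts < lo) | (counts > hi) | ~np.isfinite(counts)
    if np.any(bad):
        idx = int(np.flatnonzero(np.atleast_1d(bad))[0])
        raise ValidationError(
            f"count outside {lo}..{hi} in channel {channel or sensor!s} "
            f"at sample {idx}"
        )
    try:
        scale = {"acc": spec.acc_scale, "gyro": spec.gyro_scale,
                 "mag": spec.mag_scale}[sensor]
    except KeyError:
        raise ValidationError(f"unknown sensor kind {sensor!r}") from None
    return counts * scale


def units_to_counts(values: np.ndarray, sensor: str, spec: LoggerSpec) -> np.ndarray:
    """Inverse of :func:`counts_to_units`, rounding to the nearest count."""
    scale = {"acc": spec.acc_scale, "gyro": spec.gyro_scale,
             "mag": spec.mag_scale}[sensor]
    counts = np.rint(np.asarray(values, dtype=float) / scale)
    return np.clip(counts, -spec.counts_full_scale, spec.counts_full_scale).astype(int)


# ---------------------------------------------------------------------------
# file dialect and I/O
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS = {
    "acc": ("Ax", "Ay", "Az"),
    "gyro": ("Gx", "Gy", "Gz"),
    "mag": ("Mx", "My", "Mz"),
}


@dataclass(frozen=True)
class Dialect:
    """Column map for delimited-text recordings.

    ``mode`` says whether numbers are raw counts or physical units;
    ``delimiter`` of ``None`` auto-detects tab vs comma from the header line.
    Extra columns (temperature, depth, ...) are ignored with a logged notice.
    """

    mode: str = "units"                       # "units" | "counts"
    delimiter: str | None = None
    acc: Sequence[str] = DEFAULT_COLUMNS["acc"]
    gyro: Sequence[str] = DEFAULT_COLUMNS["gyro"]
    mag: Sequence[str] = DEFAULT_COLUMNS["mag"]

    def __post_init__(self) -> None:
        if self.mode not in ("units", "counts"):
            raise ValidationError(f"dialect mode must be units|counts, got {self.mode!r}")

    @property
    def columns(self) -> list[str]:
        return [*self.acc, *self.gyro, *self.mag]


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_recording(
    path: str | Path,
    dialect: Dialect = Dialect(),
    spec: LoggerSpec = LoggerSpec(),
    source_id: str | None = None,
) -> SensorRecording:
    """Read a delimited-text recording into a validated :class:`SensorRecording`.

    Count-mode files are converted through :func:`counts_to_units`.  Rows are
    never reordered; errors cite 1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = dialect.delimiter or _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path} is empty (no header)")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    missing = [c for c in dialect.columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path} is missing columns {missing}")
    extras = [c for c in df.columns if c not in dialect.columns]
    if extras:
        logger.info("ignoring extra columns %s in %s", extras, path)

    data = {}
    for col in dialect.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
            raise ParseError(f"non-numeric value in column {col!r}", row=row)
        # numpy's string conversion round-trips doubles exactly;
        # pandas' fast parser does not
        data[col] = df[col].to_numpy(dtype=float)

    def block(cols: Sequence[str]) -> np.ndarray:
        if len(df) == 0:
            return np.empty((0, 3))
        return np.column_stack([data[c] for c in cols])

    acc, gyro, mag = block(dialect.acc), block(dialect.gyro), block(dialect.mag)
    if dialect.mode == "counts":
        acc = counts_to_units(acc, "acc", spec)
        gyro = counts_to_units(gyro, "gyro", spec)
        mag = counts_to_units(mag, "mag", spec)
    return SensorRecording(
        acc=acc.reshape(-1, 3), gyro=gyro.reshape(-1, 3), mag=mag.reshape(-1, 3),
        spec=spec, source_id=source_id if source_id is not None else path.stem,
    )


def write_recording(
    rec: SensorRecording, path: str | Path, dialect: Dialect = Dialect()
) -> Path:
    """Write a recording as delimited text.

    Unit mode round-trips bit-identically; counts mode quantises to one
    count, so a round trip is exact to ±1 count × scale.
    """
    path = Path(path)
    sep = dialect.delimiter or ","
    if dialect.mode == "counts":
        cols = {
            **dict(zip(dialect.acc, units_to_counts(rec.acc, "acc", rec.spec).T)),
            **dict(zip(dialect.gyro, units_to_counts(rec.gyro, "gyro", rec.spec).T)),
            **dict(zip(dialect.mag, units_to_counts(rec.mag, "mag", rec.spec).T)),
        }
    else:
        cols = {
            **dict(zip(dialect.acc, rec.acc.T)),
            **dict(zip(dialect.gyro, rec.gyro.T)),
            **dict(zip(dialect.mag, rec.mag.T)),
        }
    df = pd.DataFrame(cols, columns=dialect.columns)
    try:
        df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"could not write recording to {path}: {exc}") from exc
    return path


def read_labels(path: str | Path) -> LabelSet:
    """Read a label CSV with columns source_id, centre_index, class."""
    df = pd.read_csv(path)
    required = {"source_id", "centre_index", "class"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path} must have columns {sorted(required)}")
    entries = [
        LabelEntry(str(sid), int(ci), str(cls))
        for sid, ci, cls in df[["source_id", "centre_index", "class"]].itertuples(
            index=False, name=None
        )
    ]
    return LabelSet(entries)


def write_labels(labels: LabelSet, path: str | Path) -> Path:
    df = pd.DataFrame(
        [(e.source_id, e.centre_index, e.label) for e in labels.entries],
        columns=["source_id", "centre_index", "class"],
    )
    df.to_csv(path, index=False)
    return Path(path)


__all__ = [
    "CLASSES", "STANDARD_GRAVITY", "LoggerSpec", "SensorRecording",
    "LabelEntry", "LabelSet", "Dialect", "ValidationError", "ParseError",
    "counts_to_units", "units_to_counts", "read_recording", "write_recording",
    "read_labels", "write_labels",
]
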