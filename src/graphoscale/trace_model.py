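"""Data model, validation and file I/O for digitizer pen recordings.

A recording is an ordered sequence of *strokes* (maximal pen-down
intervals).  Each on-surface sample carries a timestamp, the pen tip
position, the pen pressure and the two pen-orientation angles
(tilt-azimuth and tilt-altitude, both reported by the tablet in
[0, 180] degrees).  In-air motion is not recorded: the time the pen
spends off the surface is inferred from the gaps between consecutive
strokes.

Coordinates are in device points with y growing downward (screen
convention).  All downstream features are unit-covariant, so the
absolute scale of the coordinate system does not matter; norm models
absorb it.

Two on-disk dialects are supported:

* CSV — header ``stroke_id,t,x,y,pressure,azimuth,altitude``, one row
  per sample, metadata in leading ``# key=value`` comment lines (or in
  a ``<file>.meta.json`` sidecar);
* JSON — ``{"meta": {...}, "strokes": [[{t,x,y,...}, ...], ...]}``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENDERS = ("F", "M")
LATERALITIES = ("left", "right", "unknown")
COHORT_LABELS = ("school", "dysgraphic", "unknown")

#: column order of the CSV dialect
_CSV_COLUMNS = ("stroke_id", "t", "x", "y", "pressure", "azimuth", "altitude")
_SAMPLE_FIELDS = ("t", "x", "y", "pressure", "azimuth", "altitude")

# New text line when the gap between consecutive sorted stroke
# median-y values exceeds this multiple of the median stroke height.
LINE_GAP_FACTOR = 1.5


class ValidationError(ValueError):
    """A recording or one of its strokes violates a structural invariant."""


class ParseError(ValueError):
    """A recording file is malformed; the message names the offending line."""


@dataclass(frozen=True)
class PenSample:
    """One on-surface digitizer sample."""

    t: float  # seconds since recording start
    x: float  # device points
    y: float  # device points, growing downward
    pressure: float  # device units, >= 0
    azimuth: float  # degrees in [0, 180]
    altitude: float  # degrees in [0, 180]


class Stroke:
    """A maximal pen-down interval: >= 2 samples with strictly increasing t.

    Samples are stored as parallel float64 arrays for fast feature
    extraction; :meth:`samples` materialises :class:`PenSample` objects.
    """

    __slots__ = ("t", "x", "y", "pressure", "azimuth", "altitude", "line_id")

    def __init__(
        self,
        t: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        pressure: Sequence[float],
        azimuth: Sequence[float],
        altitude: Sequence[float],
        line_id: int | None = None,
        validate: bool = True,
    ):
        self.t = np.asarray(t, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.pressure = np.asarray(pressure, dtype=float)
        self.azimuth = np.asarray(azimuth, dtype=float)
        self.altitude = np.asarray(altitude, dtype=float)
        self.line_id = line_id
        if validate:
            self.validate()

    @classmethod
    def from_samples(cls, samples: Iterable[PenSample], line_id: int | None = None) -> "Stroke":
        samples = list(samples)
        cols = {f: [getattr(s, f) for s in samples] for f in _SAMPLE_FIELDS}
        return cls(line_id=line_id, **cols)

    def validate(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "pressure", "azimuth", "altitude"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"stroke column '{name}' length mismatch")
        if n < 2:
            raise ValidationError(f"stroke needs >= 2 samples, got {n}")
        if not np.all(np.isfinite(self.t)):
            raise ValidationError("non-finite timestamps in stroke")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps not strictly increasing within stroke")
        if np.any(self.pressure < 0):
            raise ValidationError("negative pressure")
        for name in ("azimuth", "altitude"):
            a = getattr(self, name)
            if np.any((a < 0) | (a > 180)):
                raise ValidationError(f"{name} outside [0, 180] degrees")

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def start_time(self) -> float:
        return float(self.t[0])

    @property
    def end_time(self) -> float:
        return float(self.t[-1])

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    @property
    def median_y(self) -> float:
        return float(np.median(self.y))

    @property
    def height(self) -> float:
        return float(self.y.max() - self.y.min())

    def samples(self) -> list[PenSample]:
        return [
            PenSample(*(float(getattr(self, f)[i]) for f in _SAMPLE_FIELDS))
            for i in range(self.n_samples)
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Stroke):
            return NotImplemented
        return self.line_id == other.line_id and all(
            np.array_equal(getattr(self, f), getattr(other, f)) for f in _SAMPLE_FIELDS
        )

    def __repr__(self) -> str:
        return f"Stroke(n={self.n_samples}, t=[{self.t[0]:.3f}, {self.t[-1]:.3f}], line_id={self.line_id})"


@dataclass
class Recording:
    """One child's writing session plus the metadata the norms need."""

    strokes: list[Stroke]
    age: float  # years, continuous
    gender: str  # "F" | "M"
    laterality: str = "unknown"
    sampling_rate_hz: float = 60.0
    child_id: str | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.strokes:
            raise ValidationError("recording has no strokes")
        if not (self.age > 0 and math.isfinite(self.age)):
            raise ValidationError(f"age must be a positive real, got {self.age!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"gender must be one of {GENDERS}, got {self.gender!r}")
        if self.laterality not in LATERALITIES:
            raise ValidationError(f"laterality must be one of {LATERALITIES}")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        prev_end = -np.inf
        for i, s in enumerate(self.strokes):
            if s.start_time <= prev_end:
                raise ValidationError(f"stroke {i} overlaps or precedes stroke {i - 1}")
            prev_end = s.end_time
        if sum(s.duration for s in self.strokes) <= 0:
            raise ValidationError("total on-surface time must be > 0")

    @property
    def n_samples(self) -> int:
        return sum(s.n_samples for s in self.strokes)

    @property
    def duration(self) -> float:
        """Elapsed time from first to last sample, in-air gaps included."""
        return self.strokes[-1].end_time - self.strokes[0].start_time

    def __eq__(self, other) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.strokes == other.strokes
            and self.age == other.age
            and self.gender == other.gender
            and self.laterality == other.laterality
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.child_id == other.child_id
        )


# ---------------------------------------------------------------------------
# concatenation helpers

def concat_samples(rec: Recording) -> tuple[list[PenSample], list[int]]:
    """All on-surface samples in time order plus stroke start positions.

    Returns ``(samples, boundaries)`` where ``boundaries[i]`` is the index
    of stroke *i*'s first sample in the flat list.
    """
    samples: list[PenSample] = []
    boundaries: list[int] = []
    for s in rec.strokes:
        boundaries.append(len(samples))
        samples.extend(s.samples())
    return samples, boundaries


def stacked_arrays(rec: Recording) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Vectorized counterpart of :func:`concat_samples`.

    Returns a dict of concatenated per-field arrays and the array of
    stroke start indices (one per stroke, first is 0).
    """
    cols = {f: np.concatenate([getattr(s, f) for s in rec.strokes]) for f in _SAMPLE_FIELDS}
    sizes = [s.n_samples for s in rec.strokes]
    bounds = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    return cols, bounds


# ---------------------------------------------------------------------------
# line segmentation

def segment_lines(rec: Recording) -> Recording:
    """Assign a text-line label to every stroke.

    Strokes are grouped by 1-D single linkage on their median y: after
    sorting median-y values, a new line starts whenever the gap between
    consecutive values exceeds ``LINE_GAP_FACTOR`` x the median stroke
    height.  Line ids increase with median y (i.e. top line first).
    Explicit ``line_id`` labels on the input win: if every stroke already
    carries one, the recording is returned unchanged.
    """
    if all(s.line_id is not None for s in rec.strokes):
        return rec
    med_y = np.array([s.median_y for s in rec.strokes])
    heights = np.array([s.height for s in rec.strokes])
    med_h = float(np.median(heights))
    threshold = LINE_GAP_FACTOR * med_h if med_h > 0 else 0.0
    order = np.argsort(med_y, kind="stable")
    line_of = np.zeros(len(rec.strokes), dtype=int)
    current = 0
    for prev, idx in zip(order[:-1], order[1:]):
        if med_y[idx] - med_y[prev] > threshold:
            current += 1
        line_of[idx] = current
    line_of[order[0]] = 0
    new_strokes = [
        Stroke(s.t, s.x, s.y, s.pressure, s.azimuth, s.altitude,
               line_id=int(line_of[i]), validate=False)
        for i, s in enumerate(rec.strokes)
    ]
    return replace(rec, strokes=new_strokes)


# ---------------------------------------------------------------------------
# recording I/O

def _fmt(v: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(v))


def _meta_dict(rec: Recording) -> dict:
    return {
        "child_id": rec.child_id,
        "age": rec.age,
        "gender": rec.gender,
        "laterality": rec.laterality,
        "sampling_rate_hz": rec.sampling_rate_hz,
    }


def _recording_from_parts(meta: dict, stroke_rows: dict[int, list[tuple]],
                          line_ids: dict[int, int | None]) -> Recording:
    strokes = []
    for sid in sorted(stroke_rows):
        rows = stroke_rows[sid]
        if len(rows) < 2:
            logger.warning("dropping degenerate stroke %s with %d sample(s)", sid, len(rows))
            continue
        cols = list(zip(*rows))
        strokes.append(Stroke(*cols, line_id=line_ids.get(sid)))
    if not strokes:
        raise ValidationError("recording contains no usable strokes")
    return Recording(
        strokes=strokes,
        age=float(meta["age"]),
        gender=str(meta["gender"]),
        laterality=str(meta.get("laterality", "unknown")),
        sampling_rate_hz=float(meta.get("sampling_rate_hz", 60.0)),
        child_id=meta.get("child_id"),
    )


def read_recording(path: str | Path, dialect: str = "auto") -> Recording:
    """Read a recording from a CSV or JSON file.

    ``dialect`` is ``"csv"``, ``"json"`` or ``"auto"`` (by extension).
    Degenerate strokes (< 2 samples) are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if dialect == "auto":
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        return _read_json(path)
    if dialect == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_json(path: Path) -> Recording:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    meta = doc.get("meta", {})
    stroke_rows: dict[int, list[tuple]] = {}
    line_ids: dict[int, int | None] = {}
    for sid, samples in enumerate(doc.get("strokes", [])):
        stroke_rows[sid] = [tuple(float(s[f]) for f in _SAMPLE_FIELDS) for s in samples]
        line_ids[sid] = None
    if "line_ids" in doc:
        line_ids = {i: v for i, v in enumerate(doc["line_ids"])}
    return _recording_from_parts(meta, stroke_rows, line_ids)


def _read_csv(path: Path) -> Recording:
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if not sidecar.exists():
        sidecar = path.with_name(path.stem + ".meta.json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))

    stroke_rows: dict[int, list[tuple]] = {}
    line_ids: dict[int, int | None] = {}
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            fields = line.split(",")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _CSV_COLUMNS if c not in header and c != "line_id"]
                if missing:
                    raise ParseError(f"{path}:{lineno}: header missing columns {missing}")
                continue
            try:
                row = dict(zip(header, fields))
                sid = int(row["stroke_id"])
                values = tuple(float(row[f]) for f in _SAMPLE_FIELDS)
                lid = row.get("line_id", "")
                line_ids.setdefault(sid, int(lid) if lid not in ("", None) else None)
            except (KeyError, ValueError) as e:
                raise ParseError(f"{path}:{lineno}: malformed row ({e})") from e
            stroke_rows.setdefault(sid, []).append(values)
    if header is None or not stroke_rows:
        raise ValidationError(f"{path}: empty recording")
    if "age" not in meta or "gender" not in meta:
        raise ParseError(f"{path}: metadata must provide at least 'age' and 'gender'")
    return _recording_from_parts(meta, stroke_rows, line_ids)


def write_recording(rec: Recording, path: str | Path, dialect: str = "auto") -> None:
    """Write ``rec`` so that :func:`read_recording` restores it exactly.

    Floats are printed with shortest round-tripping precision.
    """
    rec.validate()
    path = Path(path)
    if dialect == "auto":
        dialect = "json" if path.suffix.lower() == ".json" else "csv"
    if dialect == "json":
        doc = {
            "meta": _meta_dict(rec),
            "strokes": [
                [dict(zip(_SAMPLE_FIELDS, map(float, row))) for row in zip(
                    *(getattr(s, f) for f in _SAMPLE_FIELDS))]
                for s in rec.strokes
            ],
            "line_ids": [s.line_id for s in rec.strokes],
        }
        path.write_text(json.dumps(doc))
        return
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for key, value in _meta_dict(rec).items():
        if value is not None:
            lines.append(f"# {key}={value}")
    has_lines = any(s.line_id is not None for s in rec.strokes)
    cols = list(_CSV_COLUMNS) + (["line_id"] if has_lines else [])
    lines.append(",".join(cols))
    for sid, s in enumerate(rec.strokes):
        for i in range(s.n_samples):
            row = [str(sid)] + [_fmt(getattr(s, f)[i]) for f in _SAMPLE_FIELDS]
            if has_lines:
                row.append("" if s.line_id is None else str(s.line_id))
            lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# cohort feature tables

from .catalogue import FEATURE_IDS  # noqa: E402  (registry is import-light)


def feature_column(feature_id: int) -> str:
    return f"f_{feature_id}"


@dataclass
class CohortTable:
    """Per-child feature table: one row per child, one column per feature.

    Columns: ``child_id, age, gender, label, f_1 ... f_36, f_38 ... f_63``.
    ``label`` is one of ``school`` (recruited as reference population),
    ``dysgraphic`` or ``unknown``.
    """

    df: pd.DataFrame

    META_COLUMNS = ("child_id", "age", "gender", "label")

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for col in self.META_COLUMNS:
            if col not in self.df.columns:
                raise ValidationError(f"cohort table missing column {col!r}")
        if self.df["child_id"].duplicated().any():
            dupes = self.df.loc[self.df["child_id"].duplicated(), "child_id"].tolist()
            raise ValidationError(f"duplicate child_id values: {dupes[:5]}")
        bad = set(self.df["label"]) - set(COHORT_LABELS)
        if bad:
            raise ValidationError(f"unknown cohort labels: {sorted(bad)}")
        expected = {feature_column(i) for i in FEATURE_IDS}
        present = {c for c in self.df.columns if c.startswith("f_")}
        if present != expected:
            raise ValidationError(
                f"feature columns do not match the catalogue "
                f"(missing {sorted(expected - present)[:5]}, extra {sorted(present - expected)[:5]})"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_ids(self) -> list[int]:
        return list(FEATURE_IDS)

    def feature_matrix(self, feature_ids: Sequence[int] | None = None) -> np.ndarray:
        ids = list(feature_ids) if feature_ids is not None else list(FEATURE_IDS)
        return self.df[[feature_column(i) for i in ids]].to_numpy(dtype=float)

    @classmethod
    def from_rows(cls, rows: Iterable[dict]) -> "CohortTable":
        """Build from dicts with keys child_id/age/gender/label/values
        where ``values`` maps feature id -> value."""
        records = []
        for r in rows:
            rec = {k: r[k] for k in cls.META_COLUMNS}
            for fid in FEATURE_IDS:
                rec[feature_column(fid)] = r["values"].get(fid, np.nan)
            records.append(rec)
        return cls(pd.DataFrame.from_records(records))

    def to_csv(self, path: str | Path) -> None:
        cols = list(self.META_COLUMNS) + [feature_column(i) for i in FEATURE_IDS]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        return cls(pd.read_csv(path, dtype={"child_id": str}))
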