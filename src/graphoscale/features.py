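"""Extraction of the 62-feature handwriting catalogue from a pen recording.

The catalogue (see :mod:`graphoscale.catalogue`) splits into four
families:

static (1-12)
    geometry of the written trace: line straightness, size, density,
    stroke spacing, direction, angular smoothness, convex-hull area,
    and the five spectral summaries of the *tremor* residual signal;
kinematic (13-23)
    speed statistics, speed trend, smoothed-speed extrema per second,
    the five spectral summaries of the speed series, and the in-air
    time ratio;
pressure (24-36)
    pressure statistics, the rate-of-change of pressure over averaged
    10-sample bins, its trend, pressure sign inversions per second and
    the five spectral summaries of the rate series;
tilt (38-63)
    the pressure block mirrored onto the tilt-azimuth and the
    tilt-altitude angle series.

Spectral "entropy / correlation / distance" features compare the
writer's spectrum to a cohort-average *reference* spectrum, so feature
extraction is a two-pass affair on a cohort: first collect every
writer's spectra (:func:`compute_spectra`), average them
(:func:`build_reference_spectra`), then extract features against that
reference.  When no reference is supplied those features are flagged
``insufficient_data`` rather than silently computed against an
arbitrary baseline.

A feature that cannot be computed from the data at hand (too few
samples for a 300-point bin, too short a series for a 600-point
spectral bin, ...) is flagged ``insufficient_data`` instead of being
given a made-up value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal.windows import general_gaussian
from scipy.spatial import ConvexHull, QhullError

from .catalogue import CATEGORIES, FEATURE_IDS, category_ids
from .spectral_core import (
    Spectrum,
    SpectralError,
    mean_spectrum,
    summarize,
    reference_spectrum,
    tremor_signal,
)
from .trace_model import Recording, stacked_arrays, segment_lines

logger = logging.getLogger(__name__)

FLAG_OK = "ok"
FLAG_INSUFFICIENT = "insufficient_data"

#: the five series whose spectra feed the spectral feature blocks
SIGNAL_KINDS = ("tremor", "velocity", "pressure_rate", "azimuth_rate", "altitude_rate")

# fixed analysis constants
STATIC_BIN = 300      # points per static-geometry bin (within one line)
SPECTRAL_BIN = 600    # points per spectral bin
RATE_BIN = 10         # samples per averaged rate-of-change bin
GRID_CELL = 20        # pixels, handwriting-density grid
TREMOR_WINDOW = 10    # local vectors per global writing-direction vector

# smoothing window for the speed-extrema feature (17)
PEAK_WINDOW_M = 3
PEAK_WINDOW_P = 0.5
PEAK_WINDOW_SIGMA = 2.0

# spectral feature ids per signal kind: (bandwidth, median, entropy, corr, distance)
SPECTRAL_BLOCKS: dict[str, tuple[int, ...]] = {
    "tremor": (8, 9, 10, 11, 12),
    "velocity": (18, 19, 20, 21, 22),
    "pressure_rate": (32, 33, 34, 35, 36),
    "azimuth_rate": (54, 55, 56, 57, 58),
    "altitude_rate": (59, 60, 61, 62, 63),
}


@dataclass
class FeatureVector:
    """Per-child map feature id -> value, with per-feature quality flags."""

    values: dict[int, float] = field(default_factory=dict)
    flags: dict[int, str] = field(default_factory=dict)

    def set(self, fid: int, value: float | None) -> None:
        if value is None or not math.isfinite(value):
            self.values[fid] = float("nan")
            self.flags[fid] = FLAG_INSUFFICIENT
        else:
            self.values[fid] = float(value)
            self.flags[fid] = FLAG_OK

    def ok_ids(self) -> list[int]:
        return [fid for fid in sorted(self.values) if self.flags.get(fid) == FLAG_OK]

    def is_ok(self, fid: int) -> bool:
        return self.flags.get(fid) == FLAG_OK

    def __getitem__(self, fid: int) -> float:
        return self.values[fid]

    def update(self, other: "FeatureVector") -> None:
        self.values.update(other.values)
        self.flags.update(other.flags)

    def validate_complete(self) -> None:
        missing = set(FEATURE_IDS) - set(self.values)
        if missing:
            raise ValueError(f"feature vector incomplete, missing ids {sorted(missing)}")


# ---------------------------------------------------------------------------
# shared series builders

def velocity_series(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Pen speed over consecutive on-surface steps, within strokes only.

    Returns ``(speed, t_mid)`` where ``t_mid`` is the midpoint time of
    each step.  No velocity is computed across pen lifts.
    """
    speeds, times = [], []
    for s in rec.strokes:
        dt = np.diff(s.t)
        step = np.hypot(np.diff(s.x), np.diff(s.y))
        speeds.append(step / dt)
        times.append(0.5 * (s.t[:-1] + s.t[1:]))
    return np.concatenate(speeds), np.concatenate(times)


def binned_rate_series(values_per_stroke: list[np.ndarray], times_per_stroke: list[np.ndarray],
                       bin_size: int = RATE_BIN) -> tuple[np.ndarray, np.ndarray]:
    """|rate of change| between consecutive averaged bins of a sample series.

    Within each stroke the series is cut into consecutive ``bin_size``-sample
    bins (trailing partial bins dropped); each bin is summarised by its
    mean value and mid time.  The rate between consecutive bins of the
    same stroke is ``|delta mean| / delta mid-time``; bins never straddle
    a pen lift.  Returns ``(rates, t_mid)`` with the midpoint time of
    each bin pair.
    """
    rates, times = [], []
    for v, t in zip(values_per_stroke, times_per_stroke):
        n_bins = len(v) // bin_size
        if n_bins < 2:
            continue
        vb = v[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        tb = t[: n_bins * bin_size].reshape(n_bins, bin_size).mean(axis=1)
        dt = np.diff(tb)
        keep = dt > 0
        if not np.any(keep):
            continue
        rates.append(np.abs(np.diff(vb))[keep] / dt[keep])
        times.append((0.5 * (tb[:-1] + tb[1:]))[keep])
    if not rates:
        return np.empty(0), np.empty(0)
    return np.concatenate(rates), np.concatenate(times)


def _lsq_slope(y: np.ndarray, t: np.ndarray) -> float | None:
    """Least-squares slope of y against t (None if degenerate)."""
    if len(y) < 2 or np.ptp(t) == 0:
        return None
    return float(np.polyfit(t, y, 1)[0])


def _sign_inversions_per_second(values: np.ndarray, duration: float) -> float | None:
    """Strict sign changes of consecutive non-zero first differences, per second."""
    if duration <= 0 or len(values) < 3:
        return None
    d = np.diff(values)
    d = d[d != 0]
    if len(d) < 2:
        return 0.0
    inversions = int(np.sum(np.sign(d[1:]) != np.sign(d[:-1])))
    return inversions / duration


def smoothed_extrema_count(signal: np.ndarray) -> int:
    """Local extrema of the series after generalized-Gaussian smoothing.

    The window (M=3, p=0.5, sigma=2) is normalized to unit sum and
    applied with reflect padding; strict local maxima and minima of the
    smoothed series are counted.
    """
    if len(signal) < 3:
        return 0
    win = general_gaussian(PEAK_WINDOW_M, PEAK_WINDOW_P, PEAK_WINDOW_SIGMA)
    win = win / win.sum()
    pad = len(win) // 2
    padded = np.pad(signal, pad, mode="reflect")
    smooth = np.convolve(padded, win, mode="valid")
    left = smooth[:-2]
    mid = smooth[1:-1]
    right = smooth[2:]
    maxima = (mid > left) & (mid > right)
    minima = (mid < left) & (mid < right)
    return int(np.sum(maxima) + np.sum(minima))


# ---------------------------------------------------------------------------
# per-recording spectra

def compute_spectra(rec: Recording) -> dict[str, Spectrum | None]:
    """The five per-writer spectra feeding the spectral feature blocks.

    Series that are too short for one complete spectral bin map to
    ``None``.  Rate series are sampled at ``sampling_rate / RATE_BIN``.
    """
    fs = rec.sampling_rate_hz
    out: dict[str, Spectrum | None] = {}

    tremor_parts = [tremor_signal(s.x, s.y, TREMOR_WINDOW) for s in rec.strokes]
    tremor = np.concatenate(tremor_parts) if tremor_parts else np.empty(0)
    out["tremor"] = _safe_spectrum(tremor, fs)

    speed, t_mid = velocity_series(rec)
    out["velocity"] = _safe_spectrum(speed, fs, times=t_mid)

    for kind, column in (("pressure_rate", "pressure"),
                         ("azimuth_rate", "azimuth"),
                         ("altitude_rate", "altitude")):
        rates, rt = binned_rate_series(
            [getattr(s, column) for s in rec.strokes], [s.t for s in rec.strokes]
        )
        out[kind] = _safe_spectrum(rates, fs / RATE_BIN, times=rt)
    return out


def _safe_spectrum(signal: np.ndarray, fs: float, times: np.ndarray | None = None) -> Spectrum | None:
    try:
        return mean_spectrum(signal, fs, SPECTRAL_BIN, times=times)
    except SpectralError:
        return None


def build_reference_spectra(recordings: Sequence[Recording]) -> dict[str, Spectrum]:
    """Cohort-average spectrum per signal kind (writers lacking a series skipped)."""
    per_kind: dict[str, list[Spectrum]] = {k: [] for k in SIGNAL_KINDS}
    for rec in recordings:
        for kind, spec in compute_spectra(rec).items():
            if spec is not None:
                per_kind[kind].append(spec)
    out = {}
    for kind, specs in per_kind.items():
        if specs:
            out[kind] = reference_spectrum(specs)
        else:
            logger.warning("no writer produced a %s spectrum; reference missing", kind)
    return out


def _resolve_reference(ref) -> Mapping[str, Spectrum]:
    """Accept a NormModel-like object, a plain dict, or None."""
    if ref is None:
        return {}
    spectra = getattr(ref, "reference_spectra", ref)
    return spectra or {}


def _spectral_block(fv: FeatureVector, kind: str, spec: Spectrum | None,
                    ref: Mapping[str, Spectrum]) -> None:
    ids = SPECTRAL_BLOCKS[kind]
    if spec is None:
        for fid in ids:
            fv.set(fid, None)
        return
    ref_spec = ref.get(kind)
    from .spectral_core import bandwidth90 as _bw, spectral_median as _med
    fv.set(ids[0], _bw(spec))
    fv.set(ids[1], _med(spec))
    if ref_spec is None:
        for fid in ids[2:]:
            fv.set(fid, None)
        return
    from .spectral_core import spectrum_compare
    ent, corr, dist = spectrum_compare(spec, ref_spec)
    fv.set(ids[2], ent)
    fv.set(ids[3], corr)
    fv.set(ids[4], dist)


# ---------------------------------------------------------------------------
# static features (1-12)

def static_features(rec: Recording, ref=None,
                    spectra: dict[str, Spectrum | None] | None = None) -> FeatureVector:
    """Static geometry features plus tremor spectral summaries (ids 1-12)."""
    rec = segment_lines(rec)
    fv = FeatureVector()
    cols, _ = stacked_arrays(rec)
    x, y = cols["x"], cols["y"]
    n = len(x)

    # (1), (2): 300-point bins within a line of text
    dy_list: list[float] = []
    areas: list[float] = []
    lines: dict[int, list[np.ndarray]] = {}
    for s in rec.strokes:
        lines.setdefault(s.line_id, []).append(np.column_stack([s.x, s.y]))
    for pts_list in lines.values():
        pts = np.vstack(pts_list)
        n_bins = len(pts) // STATIC_BIN
        if n_bins == 0:
            continue
        binned = pts[: n_bins * STATIC_BIN].reshape(n_bins, STATIC_BIN, 2)
        bary = binned.mean(axis=1)
        if n_bins >= 2:
            dy_list.extend(np.abs(np.diff(bary[:, 1])).tolist())
        extent = binned.max(axis=1) - binned.min(axis=1)
        areas.extend((extent[:, 0] * extent[:, 1]).tolist())
    fv.set(1, float(np.mean(dy_list)) if dy_list else None)
    fv.set(2, float(np.mean(areas)) if areas else None)

    # (3) pen-lift displacement between consecutive strokes
    if len(rec.strokes) >= 2:
        gaps = [
            math.hypot(b.x[0] - a.x[-1], b.y[0] - a.y[-1])
            for a, b in zip(rec.strokes[:-1], rec.strokes[1:])
        ]
        fv.set(3, float(np.mean(gaps)))
    else:
        fv.set(3, 0.0)

    # (4) handwriting density on a 20-pixel grid anchored at the trace corner
    ix = np.floor((x - x.min()) / GRID_CELL).astype(int)
    iy = np.floor((y - y.min()) / GRID_CELL).astype(int)
    _, counts = np.unique(ix * (iy.max() + 1) + iy, return_counts=True)
    fv.set(4, float(counts.mean()))

    # (5) circular mean of step directions within strokes
    sins, coss = [], []
    for s in rec.strokes:
        dx, dy = np.diff(s.x), np.diff(s.y)
        keep = (dx != 0) | (dy != 0)
        theta = np.arctan2(dy[keep], dx[keep])
        sins.append(np.sin(theta))
        coss.append(np.cos(theta))
    sins, coss = np.concatenate(sins), np.concatenate(coss)
    fv.set(5, float(np.arctan2(sins.sum(), coss.sum())) if len(sins) else None)

    # (6) mean absolute turning angle over consecutive point triples
    angles = []
    for s in rec.strokes:
        dx, dy = np.diff(s.x), np.diff(s.y)
        keep = (dx != 0) | (dy != 0)
        dx, dy = dx[keep], dy[keep]
        if len(dx) < 2:
            continue
        cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
        dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
        angles.append(np.abs(np.arctan2(cross, dot)))
    fv.set(6, float(np.mean(np.concatenate(angles))) if angles else None)

    # (7) convex-hull area of all on-surface points
    try:
        fv.set(7, float(ConvexHull(np.column_stack([x, y])).volume))
    except (QhullError, ValueError):
        fv.set(7, None)

    # (8)-(12) tremor spectral summaries
    if spectra is None:
        spectra = compute_spectra(rec)
    _spectral_block(fv, "tremor", spectra.get("tremor"), _resolve_reference(ref))
    return fv


# ---------------------------------------------------------------------------
# kinematic features (13-23)

def kinematic_features(rec: Recording, ref=None,
                       spectra: dict[str, Spectrum | None] | None = None) -> FeatureVector:
    """Speed statistics, fluency and in-air time (ids 13-23)."""
    fv = FeatureVector()
    speed, t_mid = velocity_series(rec)
    duration = rec.duration

    fv.set(13, float(speed.mean()))
    fv.set(14, float(speed.max()))
    fv.set(15, float(speed.std()))
    fv.set(16, _lsq_slope(speed, t_mid))
    n_extrema = smoothed_extrema_count(speed)
    fv.set(17, n_extrema / duration if duration > 0 else None)

    if spectra is None:
        spectra = compute_spectra(rec)
    _spectral_block(fv, "velocity", spectra.get("velocity"), _resolve_reference(ref))

    on_surface = sum(s.duration for s in rec.strokes)
    fv.set(23, (duration - on_surface) / duration if duration > 0 else None)
    return fv


# ---------------------------------------------------------------------------
# pressure / tilt families share one channel extractor

def _channel_features(rec: Recording, column: str, ids: dict[str, object],
                      spectra_kind: str, ref, spectra) -> FeatureVector:
    """mean/max/SD + binned rate block + inversions + spectra for one channel.

    ``ids`` maps roles to feature ids: stats=(mean,max,sd),
    rate=(mean,max,sd), slope=id, inversions=id.
    """
    fv = FeatureVector()
    values = np.concatenate([getattr(s, column) for s in rec.strokes])
    m, mx, sd = ids["stats"]
    fv.set(m, float(values.mean()))
    fv.set(mx, float(values.max()))
    fv.set(sd, float(values.std()))

    rates, rt = binned_rate_series(
        [getattr(s, column) for s in rec.strokes], [s.t for s in rec.strokes]
    )
    rm, rmx, rsd = ids["rate"]
    if len(rates):
        fv.set(rm, float(rates.mean()))
        fv.set(rmx, float(rates.max()))
        fv.set(rsd, float(rates.std()))
        fv.set(ids["slope"], _lsq_slope(rates, rt))
    else:
        for fid in (rm, rmx, rsd, ids["slope"]):
            fv.set(fid, None)

    fv.set(ids["inversions"], _sign_inversions_per_second(values, rec.duration))

    if spectra is None:
        spectra = compute_spectra(rec)
    _spectral_block(fv, spectra_kind, spectra.get(spectra_kind), _resolve_reference(ref))
    return fv


def pressure_features(rec: Recording, ref=None,
                      spectra: dict[str, Spectrum | None] | None = None) -> FeatureVector:
    """Pressure statistics, rate-of-change block and inversions (ids 24-36)."""
    return _channel_features(
        rec, "pressure",
        {"stats": (24, 25, 26), "rate": (27, 28, 29), "slope": 30, "inversions": 31},
        "pressure_rate", ref, spectra,
    )


def tilt_features(rec: Recording, ref=None,
                  spectra: dict[str, Spectrum | None] | None = None) -> FeatureVector:
    """The pressure block mirrored onto azimuth and altitude (ids 38-63)."""
    fv = _channel_features(
        rec, "azimuth",
        {"stats": (38, 39, 40), "rate": (44, 45, 46), "slope": 50, "inversions": 52},
        "azimuth_rate", ref, spectra,
    )
    fv.update(_channel_features(
        rec, "altitude",
        {"stats": (41, 42, 43), "rate": (47, 48, 49), "slope": 51, "inversions": 53},
        "altitude_rate", ref, spectra,
    ))
    return fv


# ---------------------------------------------------------------------------

_FAMILIES = {
    "static": static_features,
    "kinematic": kinematic_features,
    "pressure": pressure_features,
    "tilt": tilt_features,
}


def extract_all(rec: Recording, ref=None,
                categories: Sequence[str] | None = None,
                spectra: dict[str, Spectrum | None] | None = None) -> FeatureVector:
    """Extract the full catalogue (or a category subset) from one recording.

    ``ref`` supplies the cohort reference spectra (a NormModel or a
    plain ``{kind: Spectrum}`` dict); without it the entropy /
    correlation / distance features are flagged ``insufficient_data``.
    ``spectra`` may pass the writer's own precomputed spectra (from
    :func:`compute_spectra`) to avoid recomputing them in cohort passes.
    """
    rec.validate()
    cats = list(categories) if categories is not None else list(CATEGORIES)
    unknown = set(cats) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    if spectra is None:
        spectra = compute_spectra(rec)
    fv = FeatureVector()
    for cat in cats:
        fv.update(_FAMILIES[cat](rec, ref=ref, spectra=spectra))
    expected = set().union(*(category_ids(c) for c in cats))
    assert set(fv.values) == expected
    return fv
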