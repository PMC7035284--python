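"""Frequency-domain machinery shared by all spectral handwriting features.

The pipeline derives several one-dimensional series from a pen recording
(the tremor residual of the pen path, the speed series, the binned
rate-of-change of pressure and of the two tilt angles) and summarises
each by the same five quantities: the 90% spectral bandwidth, the
spectral median, and the entropy / correlation / distance of the
writer's spectrum relative to a cohort-average reference spectrum.

The spectrum of a series is estimated by splitting it into consecutive
non-overlapping bins of ``bin_size`` points, taking the magnitude of the
discrete Fourier transform of each mean-removed bin, averaging the bin
spectra point-wise and normalizing the average to sum 1.  The DC line is
excluded (the series mean carries no tremor/fluency information and
would otherwise dominate the normalized vector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: additive smoothing used before the KL divergence
KL_EPSILON = 1e-12

#: bins never span a pen-up gap longer than this many seconds
MAX_BIN_GAP_S = 1.0


class SpectralError(ValueError):
    """Raised when a series is too short or two spectra are incompatible."""


@dataclass(frozen=True)
class Spectrum:
    """A normalized magnitude spectrum: ``power`` sums to 1 over ``freqs``."""

    freqs: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # non-negative, sums to 1

    def __post_init__(self):
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "power", np.asarray(self.power, dtype=float))
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise SpectralError("freqs and power must be 1-D arrays of equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise SpectralError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise SpectralError("power must be non-negative")
        if abs(self.power.sum() - 1.0) > 1e-9:
            raise SpectralError(f"power must sum to 1, got {self.power.sum()!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.freqs, other.freqs) and np.array_equal(self.power, other.power)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {"freq_hz": self.freqs.tolist(), "power": self.power.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Spectrum":
        return cls(np.asarray(d["freq_hz"]), np.asarray(d["power"]))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, np.column_stack([self.freqs, self.power]),
                   delimiter=",", header="freq_hz,power", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])


@dataclass(frozen=True)
class SpectralSummary:
    """The five spectral summaries attached to every spectral feature block."""

    bandwidth90: float
    median_freq: float
    entropy_vs_ref: float
    correlation_vs_ref: float
    distance_vs_ref: float


# ---------------------------------------------------------------------------
# tremor residual

def tremor_signal(x: np.ndarray, y: np.ndarray, window: int = 10) -> np.ndarray:
    """Per-step deviation of the pen path from its local writing direction.

    Consecutive samples define *local* displacement vectors.  For every
    run of ``window`` consecutive local vectors their mean is the
    *global* (writing-direction) vector; the residual of that run is the
    magnitude of the 2-D cross product between the run's central local
    vector and the global vector.  Straight or smoothly curving paths
    give residuals near zero; shaky paths give large residuals.

    Returns one residual per window position (``n - 1 - window + 1``
    values for ``n`` samples); an empty array with a warning if fewer
    than ``window + 1`` samples are supplied.  Purely geometric: any
    re-parameterization of time leaves the result unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < window + 1:
        logger.warning("tremor_signal: %d samples < window + 1 = %d", len(x), window + 1)
        return np.empty(0)
    dx = np.diff(x)
    dy = np.diff(y)
    # sliding mean of the local vectors over `window` positions
    kernel = np.ones(window) / window
    gx = np.convolve(dx, kernel, mode="valid")
    gy = np.convolve(dy, kernel, mode="valid")
    center = window // 2
    lx = dx[center:center + len(gx)]
    ly = dy[center:center + len(gy)]
    return np.abs(lx * gy - ly * gx)


# ---------------------------------------------------------------------------
# spectrum estimation

def _bin_spectrum(segment: np.ndarray) -> np.ndarray:
    """Magnitude DFT of one mean-removed bin, DC line excluded."""
    seg = segment - segment.mean()
    return np.abs(np.fft.rfft(seg))[1:]


def mean_spectrum(
    signal: np.ndarray,
    sampling_rate_hz: float,
    bin_size: int = 600,
    times: np.ndarray | None = None,
) -> Spectrum:
    """Averaged, normalized magnitude spectrum of a real time series.

    The series is split into consecutive non-overlapping bins of
    ``bin_size`` points (the incomplete trailing bin is dropped), each
    bin is mean-removed and Fourier-transformed, the magnitude spectra
    are averaged point-wise and the average is normalized to sum 1.

    If ``times`` is given, the series is first cut wherever the gap
    between consecutive samples exceeds ``MAX_BIN_GAP_S`` (a page
    change); bins never span such a cut.

    Frequency grid: ``k * sampling_rate_hz / bin_size`` for
    ``k = 1 .. bin_size // 2`` (DC excluded).

    Raises :class:`SpectralError` when fewer than ``bin_size`` points
    are available in any segment.  A degenerate all-zero average (e.g. a
    constant signal) maps to the uniform spectrum with a warning.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < bin_size:
        raise SpectralError(
            f"insufficient samples for spectral features: {len(signal)} < bin size {bin_size}"
        )
    if times is not None:
        times = np.asarray(times, dtype=float)
        dt = np.diff(times)
        # a cut happens when the gap exceeds MAX_BIN_GAP_S beyond two of
        # the series' own sampling intervals (derived series timestamped
        # at bin midpoints widen a pen-up gap by up to two bin widths);
        # the cut targets page changes, which last many seconds
        nominal = np.median(dt) if len(dt) else 0.0
        cuts = np.flatnonzero(dt > MAX_BIN_GAP_S + 2 * nominal) + 1
        segments = np.split(signal, cuts)
    else:
        segments = [signal]

    spectra = []
    for seg in segments:
        n_bins = len(seg) // bin_size
        for b in range(n_bins):
            spectra.append(_bin_spectrum(seg[b * bin_size:(b + 1) * bin_size]))
    if not spectra:
        raise SpectralError(
            f"insufficient samples for spectral features: no complete {bin_size}-point bin"
        )
    mean_mag = np.mean(spectra, axis=0)
    freqs = np.arange(1, bin_size // 2 + 1) * (sampling_rate_hz / bin_size)
    total = mean_mag.sum()
    if total <= 0:
        logger.warning("mean_spectrum: degenerate all-zero spectrum, falling back to uniform")
        power = np.full_like(mean_mag, 1.0 / len(mean_mag))
    else:
        power = mean_mag / total
    return Spectrum(freqs, power)


# ---------------------------------------------------------------------------
# spectral summaries

def bandwidth90(spec: Spectrum, mass: float = 0.9) -> float:
    """Width of the smallest low-frequency interval holding 90% of the power.

    The interval runs from the lowest occupied frequency line to the
    smallest line at which the cumulative power reaches ``mass``; its
    width is returned in Hz (0 when all power sits on one line).
    """
    cum = np.cumsum(spec.power)
    hi = int(np.searchsorted(cum, mass - 1e-12))
    hi = min(hi, len(spec.freqs) - 1)
    occupied = np.flatnonzero(spec.power > 0)
    lo = int(occupied[0]) if len(occupied) else 0
    return float(max(spec.freqs[hi] - spec.freqs[lo], 0.0))


def spectral_median(spec: Spectrum) -> float:
    """Smallest frequency at which the cumulative power reaches one half."""
    cum = np.cumsum(spec.power)
    idx = int(np.searchsorted(cum, 0.5 - 1e-12))
    idx = min(idx, len(spec.freqs) - 1)
    return float(spec.freqs[idx])


def spectrum_compare(spec: Spectrum, ref: Spectrum) -> tuple[float, float, float]:
    """(entropy, correlation, distance) of a spectrum against a reference.

    entropy     Kullback-Leibler divergence KL(spec || ref), with
                epsilon-smoothing so disjoint supports stay finite;
    correlation Pearson correlation of the two power vectors;
    distance    Euclidean norm of their difference.
    """
    if spec.freqs.shape != ref.freqs.shape or not np.allclose(spec.freqs, ref.freqs):
        raise SpectralError("spectra are on different frequency grids")
    p = spec.power + KL_EPSILON
    q = ref.power + KL_EPSILON
    p = p / p.sum()
    q = q / q.sum()
    entropy = float(np.sum(p * np.log(p / q)))
    entropy = max(entropy, 0.0)  # clip the tiny negative round-off at p == q

    a, b = spec.power, ref.power
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        correlation = 1.0 if np.allclose(a, b) else 0.0
    else:
        correlation = float(np.corrcoef(a, b)[0, 1])
    distance = float(np.linalg.norm(a - b))
    return entropy, correlation, distance


def summarize(spec: Spectrum, ref: Spectrum) -> SpectralSummary:
    """All five spectral summaries in one call."""
    ent, corr, dist = spectrum_compare(spec, ref)
    return SpectralSummary(
        bandwidth90=bandwidth90(spec),
        median_freq=spectral_median(spec),
        entropy_vs_ref=ent,
        correlation_vs_ref=corr,
        distance_vs_ref=dist,
    )


def reference_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Point-wise mean of cohort spectra, renormalized to sum 1."""
    if not spectra:
        raise SpectralError("reference_spectrum needs at least one spectrum")
    freqs = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != freqs.shape or not np.allclose(s.freqs, freqs):
            raise SpectralError("cohort spectra are on different frequency grids")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    return Spectrum(freqs, mean_power / mean_power.sum())
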