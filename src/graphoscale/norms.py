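"""Age- and gender-conditional norm curves, Z-scores and feature scores.

Handwriting features drift strongly with age and differ by gender, so a
raw feature value is meaningless on its own.  For every feature and
gender the cohort's mean and dispersion are modelled as cubic
polynomials of age (age treated as a continuous variable):

    f_mean(age) = c0 + c1*age + c2*age^2 + c3*age^3

and analogously ``f_std(age)`` fitted to the dispersion of the
residuals.  A child's deviation is the one-sided z-score

    Z = |value - f_mean(age)| / f_std(age)

mapped to a bounded, interpretable score

    score = exp(-alpha * Z**beta),  alpha, beta > 0.

With the defaults ``alpha = ln 2``, ``beta = 2`` a child exactly on the
norm scores 1, one SD away scores 0.5 and two SDs away scores 0.0625 —
a smooth, easily explained calibration.  Both parameters are
configurable and stored in the model.

Norm models are country/curriculum specific (children start writing at
different ages in different school systems); fit one model per cohort
and persist it as a JSON document.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalogue import FEATURE_IDS
from .features import FeatureVector
from .spectral_core import Spectrum
from .trace_model import CohortTable, GENDERS, feature_column

logger = logging.getLogger(__name__)

SCHEMA = "graphoscale-norms/1"

DEFAULT_ALPHA = math.log(2.0)
DEFAULT_BETA = 2.0

#: std floor = this fraction of the cohort feature SD (guards division)
STD_FLOOR_FRACTION = 1e-6
#: absolute fallback floor for constant features
STD_FLOOR_ABSOLUTE = 1e-9

MIN_CHILDREN_PER_GENDER = 20
MIN_DISTINCT_AGES = 3


class NormError(ValueError):
    """Raised when a cohort cannot support a norm fit or a lookup fails."""


@dataclass
class NormCurve:
    """Cubic mean and SD curves of one feature for one gender.

    Coefficients are stored lowest order first (c0 + c1*a + c2*a^2 + c3*a^3);
    shorter arrays mean a reduced-degree fallback fit.
    """

    feature_id: int
    gender: str
    mean_coeffs: np.ndarray
    std_coeffs: np.ndarray
    age_support: tuple[float, float]
    n_fit: int
    std_floor: float
    #: the SD cubic is fitted on 1-year-bin centers; evaluation is clamped
    #: to their range because extrapolating a cubic beyond its data is
    #: unsafe (None means no clamping, e.g. hand-built curves)
    std_age_support: tuple[float, float] | None = None

    def mean_at(self, age: float) -> float:
        return float(np.polynomial.polynomial.polyval(age, self.mean_coeffs))

    def std_at(self, age: float) -> float:
        if self.std_age_support is not None:
            age = min(max(age, self.std_age_support[0]), self.std_age_support[1])
        return max(float(np.polynomial.polynomial.polyval(age, self.std_coeffs)),
                   self.std_floor)

    def to_dict(self) -> dict:
        return {
            "feature_id": self.feature_id,
            "gender": self.gender,
            "mean_coeffs": np.asarray(self.mean_coeffs).tolist(),
            "std_coeffs": np.asarray(self.std_coeffs).tolist(),
            "age_support": list(self.age_support),
            "n_fit": self.n_fit,
            "std_floor": self.std_floor,
            "std_age_support": (None if self.std_age_support is None
                                else list(self.std_age_support)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormCurve":
        return cls(
            feature_id=int(d["feature_id"]),
            gender=d["gender"],
            mean_coeffs=np.asarray(d["mean_coeffs"], dtype=float),
            std_coeffs=np.asarray(d["std_coeffs"], dtype=float),
            age_support=tuple(d["age_support"]),
            n_fit=int(d["n_fit"]),
            std_floor=float(d["std_floor"]),
            std_age_support=(None if d.get("std_age_support") is None
                             else tuple(d["std_age_support"])),
        )


@dataclass
class NormModel:
    """All norm curves plus the cohort reference spectra and score parameters."""

    curves: dict[tuple[int, str], NormCurve]
    reference_spectra: dict[str, Spectrum] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise NormError("alpha and beta must both be positive")

    def curve(self, feature_id: int, gender: str) -> NormCurve:
        try:
            return self.curves[(feature_id, gender)]
        except KeyError:
            raise NormError(f"no norm curve for feature {feature_id}, gender {gender!r}") from None

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema": SCHEMA,
            "alpha": self.alpha,
            "beta": self.beta,
            "curves": [c.to_dict() for c in self.curves.values()],
            "reference_spectra": {k: s.to_dict() for k, s in self.reference_spectra.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema") != SCHEMA:
            raise NormError(f"unexpected norm model schema {doc.get('schema')!r}")
        curves = {}
        for cd in doc["curves"]:
            c = NormCurve.from_dict(cd)
            curves[(c.feature_id, c.gender)] = c
        spectra = {k: Spectrum.from_dict(v) for k, v in doc.get("reference_spectra", {}).items()}
        return cls(curves=curves, reference_spectra=spectra,
                   alpha=doc["alpha"], beta=doc["beta"])


# ---------------------------------------------------------------------------
# fitting

def _polyfit_safe(x: np.ndarray, y: np.ndarray, degree: int, what: str) -> np.ndarray:
    """Least-squares polynomial fit, degree reduced if the design is deficient."""
    max_deg = min(degree, len(np.unique(x)) - 1)
    if max_deg < degree:
        logger.warning("%s: only %d distinct ages, reducing fit degree %d -> %d",
                       what, len(np.unique(x)), degree, max_deg)
    return np.polynomial.polynomial.polyfit(x, y, max_deg)


def _fit_std_curve(ages: np.ndarray, residuals: np.ndarray, degree: int,
                   what: str) -> tuple[np.ndarray, tuple[float, float]]:
    """Cubic fit to per-1-year-bin SDs of the residuals.

    Returns the coefficients and the bin-center range the fit is valid
    over (evaluation outside it is clamped).
    """
    bins = np.floor(ages).astype(int)
    centers, sds = [], []
    for b in np.unique(bins):
        r = residuals[bins == b]
        if len(r) >= 2:
            centers.append(b + 0.5)
            sds.append(r.std(ddof=1))
    if not centers:
        sd = residuals.std() if len(residuals) > 1 else 0.0
        return np.array([sd]), (float(ages.min()), float(ages.max()))
    coeffs = _polyfit_safe(np.asarray(centers), np.asarray(sds), degree, what)
    return coeffs, (float(min(centers)), float(max(centers)))


def fit_norms(
    cohort: CohortTable,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    degree: int = 3,
    reference_spectra: dict[str, Spectrum] | None = None,
) -> NormModel:
    """Fit per-feature, per-gender cubic norm curves from a cohort table.

    Only rows labeled ``school`` (the reference population) enter the
    fit; if no such rows exist every row is used.  Requires at least
    ``MIN_CHILDREN_PER_GENDER`` children per gender spanning at least
    ``MIN_DISTINCT_AGES`` distinct integer ages.

    ``f_mean`` is the least-squares cubic of value vs. age; ``f_std``
    is a cubic fitted to the SDs of the residuals in 1-year age bins,
    clipped from below at a small fraction of the cohort feature SD so
    z-scores stay finite for (near-)constant features.
    """
    df = cohort.df
    ref_df = df[df["label"] == "school"]
    if ref_df.empty:
        logger.warning("no 'school' rows in cohort; fitting norms on all %d rows", len(df))
        ref_df = df

    curves: dict[tuple[int, str], NormCurve] = {}
    for gender in GENDERS:
        sub = ref_df[ref_df["gender"] == gender]
        ages = sub["age"].to_numpy(dtype=float)
        n_ages = len(np.unique(np.floor(ages)))
        if len(sub) < MIN_CHILDREN_PER_GENDER or n_ages < MIN_DISTINCT_AGES:
            raise NormError(
                f"gender {gender!r}: need >= {MIN_CHILDREN_PER_GENDER} children over "
                f">= {MIN_DISTINCT_AGES} distinct ages, got {len(sub)} children, {n_ages} ages"
            )
        support = (float(ages.min()), float(ages.max()))
        for fid in FEATURE_IDS:
            values = sub[feature_column(fid)].to_numpy(dtype=float)
            ok = np.isfinite(values)
            if ok.sum() < MIN_CHILDREN_PER_GENDER:
                raise NormError(
                    f"feature {fid}, gender {gender!r}: only {int(ok.sum())} finite values"
                )
            a, v = ages[ok], values[ok]
            what = f"feature {fid}/{gender}"
            mean_coeffs = _polyfit_safe(a, v, degree, what)
            residuals = v - np.polynomial.polynomial.polyval(a, mean_coeffs)
            std_coeffs, std_support = _fit_std_curve(a, residuals, degree, what)
            cohort_sd = float(v.std())
            floor = max(STD_FLOOR_FRACTION * cohort_sd, STD_FLOOR_ABSOLUTE)
            curves[(fid, gender)] = NormCurve(
                feature_id=fid, gender=gender,
                mean_coeffs=mean_coeffs, std_coeffs=std_coeffs,
                age_support=support, n_fit=int(ok.sum()), std_floor=floor,
                std_age_support=std_support,
            )
    return NormModel(curves=curves, reference_spectra=reference_spectra or {},
                     alpha=alpha, beta=beta)


# ---------------------------------------------------------------------------
# scoring

def _clamp_age(age: float, curve: NormCurve) -> float:
    lo, hi = curve.age_support
    if age < lo or age > hi:
        logger.warning("age %.2f outside fitted support [%.2f, %.2f]; clamping", age, lo, hi)
        return min(max(age, lo), hi)
    return age


def zscore(value: float, age: float, gender: str, feature_id: int, model: NormModel) -> float:
    """One-sided deviation |value - f_mean(age)| / f_std(age)."""
    curve = model.curve(feature_id, gender)
    age = _clamp_age(age, curve)
    return abs(value - curve.mean_at(age)) / curve.std_at(age)


def signed_deviation(value: float, age: float, gender: str, feature_id: int,
                     model: NormModel) -> float:
    """Signed deviation (value - f_mean(age)) / f_std(age); input to the scales."""
    curve = model.curve(feature_id, gender)
    age = _clamp_age(age, curve)
    return (value - curve.mean_at(age)) / curve.std_at(age)


def feature_score(z: float, model: NormModel) -> float:
    """Bounded score exp(-alpha * z**beta) in (0, 1]; 1 iff z == 0."""
    if z < 0:
        raise NormError(f"z-score must be non-negative, got {z}")
    return float(math.exp(-model.alpha * z ** model.beta))


def score_vector(fv: FeatureVector, age: float, gender: str,
                 model: NormModel) -> dict[int, float]:
    """Per-feature scores for one child; flagged features are omitted.

    A feature flagged ``insufficient_data`` never receives a fabricated
    score — it is simply absent from the returned map.
    """
    out: dict[int, float] = {}
    for fid in sorted(fv.values):
        if not fv.is_ok(fid):
            continue
        z = zscore(fv[fid], age, gender, fid, model)
        out[fid] = feature_score(z, model)
    return out
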