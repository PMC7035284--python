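"""Data-driven handwriting scales: PCA, 2-cluster K-means and severity bands.

The scale construction works on *signed standardized deviations*
``(value - f_mean(age)) / f_std(age)`` rather than raw feature values,
so that age and gender effects cannot masquerade as handwriting
variance.  The deviation matrix is standardized (per-feature center and
spread from the fitting cohort), projected onto its three leading
principal axes, and clustered with K-means (k = 2).  The cluster
holding the majority of school-recruited children defines the *typical*
centroid; a child's global score is

    score = exp(-d / d_ref)

where ``d`` is the child's Euclidean distance to the typical centroid
in the 3-D projection and ``d_ref`` is the mean distance of the school
children.  Scores live in (0, 1]: 1 means sitting exactly on the
typical centroid, e^-1 means being as far as the average reference
child.

Four severity thresholds, set at configurable quantiles of the school
children's scores (defaults 2%, 8.6%, 15%, 25%), band the scale into
five categories: very severe, severe, moderate, light, typical.

The same construction restricted to one feature category (static,
kinematic, pressure, tilt) yields per-category sub-scales; together
with the per-feature scores they form a child's handwriting profile.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .catalogue import CATALOGUE, CATEGORIES, category_ids
from .features import FeatureVector
from .norms import NormModel, feature_score, score_vector, zscore
from .trace_model import CohortTable, feature_column

logger = logging.getLogger(__name__)

SCHEMA = "graphoscale-scale/1"

SCALE_CATEGORIES = ("total",) + CATEGORIES

DEFAULT_THRESHOLD_FRACTIONS = (0.02, 0.086, 0.15, 0.25)
DEFAULT_N_AXES = 3
DEFAULT_KMEANS_RESTARTS = 50
MIN_SCHOOL_CHILDREN = 10
MIN_FEATURES = 4
MIN_REFERENCE_SCORES = 50


class ScaleError(ValueError):
    """Raised for degenerate clusterings or unusable fitting cohorts."""


class Severity(str, Enum):
    VERY_SEVERE = "very_severe"
    SEVERE = "severe"
    MODERATE = "moderate"
    LIGHT = "light"
    TYPICAL = "typical"


@dataclass(frozen=True)
class Thresholds:
    """Four increasing score cut-points banding the scale into five levels."""

    vs: float
    s: float
    m: float
    l: float

    def __post_init__(self):
        vals = (self.vs, self.s, self.m, self.l)
        if not all(np.diff(vals) > 0):
            raise ScaleError(f"thresholds must be strictly increasing, got {vals}")
        if not all(0 < v < 1 for v in vals):
            raise ScaleError(f"thresholds must lie in (0, 1), got {vals}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.vs, self.s, self.m, self.l)


@dataclass
class AxisImportance:
    """Absolute PCA loadings per axis and per-category loading shares."""

    loadings: list[dict[int, float]]        # per axis: feature id -> |loading|
    category_shares: list[dict[str, float]]  # per axis: category -> share (sums to 1)

    def top_features(self, axis: int, per_category: int = 6) -> dict[str, list[int]]:
        """The most-loaded feature ids per category on one axis (for reporting)."""
        out: dict[str, list[int]] = {}
        for cat in CATEGORIES:
            ids = [fid for fid in self.loadings[axis] if CATALOGUE[fid].category == cat]
            ids.sort(key=lambda fid: -self.loadings[axis][fid])
            if ids:
                out[cat] = ids[:per_category]
        return out


@dataclass
class ScaleModel:
    """A fitted handwriting scale (global or one category)."""

    category: str
    feature_ids: list[int]
    center: np.ndarray           # standardizer: per-feature mean of deviations
    spread: np.ndarray           # standardizer: per-feature SD of deviations
    axes: np.ndarray             # (n_axes, n_features) orthonormal loadings
    explained_variance_fractions: np.ndarray
    centroid_typical: np.ndarray
    centroid_atypical: np.ndarray
    d_ref: float
    thresholds: Thresholds
    seed: int | None = None

    def __post_init__(self):
        gram = self.axes @ self.axes.T
        if not np.allclose(gram, np.eye(len(self.axes)), atol=1e-9):
            raise ScaleError("PCA axes are not orthonormal")
        if self.d_ref <= 0:
            raise ScaleError("d_ref must be positive")

    # -- persistence ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "schema": SCHEMA,
            "category": self.category,
            "feature_ids": self.feature_ids,
            "center": self.center.tolist(),
            "spread": self.spread.tolist(),
            "axes": self.axes.tolist(),
            "explained_variance_fractions": self.explained_variance_fractions.tolist(),
            "centroid_typical": self.centroid_typical.tolist(),
            "centroid_atypical": self.centroid_atypical.tolist(),
            "d_ref": self.d_ref,
            "thresholds": self.thresholds.as_tuple(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScaleModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("schema") != SCHEMA:
            raise ScaleError(f"unexpected scale model schema {doc.get('schema')!r}")
        return cls(
            category=doc["category"],
            feature_ids=[int(i) for i in doc["feature_ids"]],
            center=np.asarray(doc["center"], dtype=float),
            spread=np.asarray(doc["spread"], dtype=float),
            axes=np.asarray(doc["axes"], dtype=float),
            explained_variance_fractions=np.asarray(doc["explained_variance_fractions"]),
            centroid_typical=np.asarray(doc["centroid_typical"], dtype=float),
            centroid_atypical=np.asarray(doc["centroid_atypical"], dtype=float),
            d_ref=float(doc["d_ref"]),
            thresholds=Thresholds(*doc["thresholds"]),
            seed=doc.get("seed"),
        )


@dataclass
class HandwritingProfile:
    """Global, per-category and per-feature scores for one child."""

    child_id: str | None
    global_score: float
    category_scores: dict[str, float]
    severity: Severity
    feature_scores: dict[int, float]

    def to_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "global_score": self.global_score,
            "category_scores": self.category_scores,
            "severity": self.severity.value,
            "feature_scores": {str(k): v for k, v in self.feature_scores.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HandwritingProfile":
        return cls(
            child_id=d.get("child_id"),
            global_score=float(d["global_score"]),
            category_scores={k: float(v) for k, v in d["category_scores"].items()},
            severity=Severity(d["severity"]),
            feature_scores={int(k): float(v) for k, v in d["feature_scores"].items()},
        )


# ---------------------------------------------------------------------------
# deviation matrix

def deviation_matrix(cohort: CohortTable, norms: NormModel,
                     feature_ids: Sequence[int]) -> np.ndarray:
    """Signed standardized deviations, one row per child, one column per feature."""
    df = cohort.df
    out = np.empty((len(df), len(feature_ids)))
    ages = df["age"].to_numpy(dtype=float)
    genders = df["gender"].to_numpy()
    for j, fid in enumerate(feature_ids):
        values = df[feature_column(fid)].to_numpy(dtype=float)
        for g in np.unique(genders):
            rows = genders == g
            curve = norms.curve(fid, str(g))
            a = np.clip(ages[rows], *curve.age_support)
            mean = np.polynomial.polynomial.polyval(a, curve.mean_coeffs)
            a_std = np.clip(a, *curve.std_age_support) if curve.std_age_support else a
            std = np.maximum(
                np.polynomial.polynomial.polyval(a_std, curve.std_coeffs), curve.std_floor
            )
            out[rows, j] = (values[rows] - mean) / std
    if not np.all(np.isfinite(out)):
        bad = [feature_ids[j] for j in np.unique(np.argwhere(~np.isfinite(out))[:, 1])]
        raise ScaleError(f"non-finite deviations for features {bad}")
    return out


# ---------------------------------------------------------------------------
# fitting

def fit_scale(
    cohort: CohortTable,
    norms: NormModel,
    category: str = "total",
    n_axes: int = DEFAULT_N_AXES,
    kmeans_restarts: int = DEFAULT_KMEANS_RESTARTS,
    seed: int = 0,
    threshold_fractions: Sequence[float] = DEFAULT_THRESHOLD_FRACTIONS,
) -> ScaleModel:
    """Fit a handwriting scale for one category (or ``"total"``).

    Standardized signed deviations restricted to the category's
    features are projected on their ``n_axes`` leading principal axes
    and clustered with K-means (k = 2, k-means++ with
    ``kmeans_restarts`` restarts).  The typical centroid, the reference
    distance and the severity thresholds are derived from the
    school-labeled children.

    ``n_axes`` defaults to 3; overriding it changes the geometry the
    thresholds were calibrated on, so refit thresholds if you do.
    """
    if category not in SCALE_CATEGORIES:
        raise ScaleError(f"unknown scale category {category!r}")
    if n_axes != DEFAULT_N_AXES:
        logger.warning("retaining %d axes instead of %d; thresholds must be refit",
                       n_axes, DEFAULT_N_AXES)
    ids = list(category_ids(category))
    if len(ids) < MIN_FEATURES:
        raise ScaleError(f"category {category!r} has fewer than {MIN_FEATURES} features")
    school_mask = (cohort.df["label"] == "school").to_numpy()
    if school_mask.sum() < MIN_SCHOOL_CHILDREN:
        raise ScaleError(
            f"need >= {MIN_SCHOOL_CHILDREN} school-labeled children, got {int(school_mask.sum())}"
        )

    D = deviation_matrix(cohort, norms, ids)
    center = D.mean(axis=0)
    spread = D.std(axis=0)
    if np.all(spread < 1e-12):
        raise ScaleError("degenerate clustering: cohort has no feature variance")
    spread = np.where(spread < 1e-12, 1.0, spread)
    X = (D - center) / spread

    pca = PCA(n_components=n_axes, svd_solver="full")
    proj = pca.fit_transform(X)

    km = KMeans(n_clusters=2, n_init=kmeans_restarts, random_state=seed)
    assign = km.fit_predict(proj)
    sizes = np.bincount(assign, minlength=2)
    if sizes.min() == 0 or np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]) < 1e-9:
        raise ScaleError("degenerate clustering: K-means found a single effective cluster")

    school_in_0 = int(np.sum(assign[school_mask] == 0))
    school_in_1 = int(school_mask.sum()) - school_in_0
    if school_in_0 > school_in_1:
        typical = 0
    elif school_in_1 > school_in_0:
        typical = 1
    else:  # tie broken toward the larger cluster
        typical = int(np.argmax(sizes))

    centroid_typical = km.cluster_centers_[typical]
    centroid_atypical = km.cluster_centers_[1 - typical]

    d_school = np.linalg.norm(proj[school_mask] - centroid_typical, axis=1)
    d_ref = float(d_school.mean())
    if d_ref <= 0:
        raise ScaleError("degenerate clustering: zero reference distance")

    school_scores = np.exp(-d_school / d_ref)
    thresholds = threshold_from_quantiles(
        school_scores, fractions=threshold_fractions,
        strict=len(np.unique(school_scores)) >= MIN_REFERENCE_SCORES,
    )

    return ScaleModel(
        category=category,
        feature_ids=ids,
        center=center,
        spread=spread,
        axes=pca.components_,
        explained_variance_fractions=pca.explained_variance_ratio_,
        centroid_typical=centroid_typical,
        centroid_atypical=centroid_atypical,
        d_ref=d_ref,
        thresholds=thresholds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# projection & scoring

def _deviation_row(fv: FeatureVector, age: float, gender: str,
                   scale: ScaleModel, norms: NormModel) -> np.ndarray:
    from .norms import signed_deviation
    missing = [fid for fid in scale.feature_ids
               if fid not in fv.values or not fv.is_ok(fid)]
    if missing:
        raise ScaleError(f"feature vector missing required features {missing}")
    return np.array([
        signed_deviation(fv[fid], age, gender, fid, norms) for fid in scale.feature_ids
    ])


def project(fv: FeatureVector, age: float, gender: str,
            scale: ScaleModel, norms: NormModel) -> np.ndarray:
    """Project one child onto the scale's three principal axes."""
    d = _deviation_row(fv, age, gender, scale, norms)
    x = (d - scale.center) / scale.spread
    return scale.axes @ x


def global_score(fv: FeatureVector, age: float, gender: str,
                 scale: ScaleModel, norms: NormModel) -> float:
    """exp(-d / d_ref) for the child's distance d to the typical centroid."""
    p = project(fv, age, gender, scale, norms)
    d = float(np.linalg.norm(p - scale.centroid_typical))
    return float(np.exp(-d / scale.d_ref))


def axis_importance(scale: ScaleModel) -> AxisImportance:
    """Absolute loadings and per-category loading shares for each axis."""
    loadings: list[dict[int, float]] = []
    shares: list[dict[str, float]] = []
    for axis in np.abs(scale.axes):
        per_feature = {fid: float(a) for fid, a in zip(scale.feature_ids, axis)}
        loadings.append(per_feature)
        total = sum(per_feature.values())
        cats = {c: 0.0 for c in CATEGORIES if any(
            CATALOGUE[f].category == c for f in scale.feature_ids)}
        for fid, a in per_feature.items():
            cats[CATALOGUE[fid].category] += a
        shares.append({c: v / total for c, v in cats.items()})
    return AxisImportance(loadings=loadings, category_shares=shares)


# ---------------------------------------------------------------------------
# thresholds & categorization

def threshold_from_quantiles(
    reference_scores: Sequence[float],
    fractions: Sequence[float] = DEFAULT_THRESHOLD_FRACTIONS,
    strict: bool = True,
) -> Thresholds:
    """Severity cut-points from rank counts over the reference scores.

    The threshold for fraction ``p`` is the smallest reference score
    with at least ``ceil(p * n)`` scores at or below it; for distinct
    scores exactly ``ceil(p * n) / n`` of the reference falls at or
    below each threshold.  With heavy ties the realized fraction can
    only exceed the nominal one (never undershoot).

    ``strict`` enforces the >= 50 distinct-scores precondition; the
    scale fitter relaxes it with a warning for small cohorts.
    """
    fr = np.asarray(fractions, dtype=float)
    if np.any(np.diff(fr) <= 0) or np.any(fr <= 0) or np.any(fr >= 1):
        raise ScaleError(f"fractions must be strictly increasing in (0, 1), got {fractions}")
    scores = np.sort(np.asarray(reference_scores, dtype=float))
    n_distinct = len(np.unique(scores))
    if strict and n_distinct < MIN_REFERENCE_SCORES:
        raise ScaleError(
            f"need >= {MIN_REFERENCE_SCORES} distinct reference scores, got {n_distinct}"
        )
    if not strict and n_distinct < MIN_REFERENCE_SCORES:
        logger.warning("only %d distinct reference scores; thresholds will be coarse",
                       n_distinct)
    n = len(scores)
    cuts = [float(scores[min(int(np.ceil(p * n)) - 1, n - 1)]) for p in fr]
    if len(set(cuts)) < len(cuts) or not all(np.diff(cuts) > 0):
        raise ScaleError(f"reference scores too coarse for distinct thresholds: {cuts}")
    return Thresholds(*cuts)


def categorize(score: float, th: Thresholds) -> Severity:
    """Band a score into one of the five severity categories."""
    if score <= th.vs:
        return Severity.VERY_SEVERE
    if score <= th.s:
        return Severity.SEVERE
    if score <= th.m:
        return Severity.MODERATE
    if score <= th.l:
        return Severity.LIGHT
    return Severity.TYPICAL


# ---------------------------------------------------------------------------
# profiles

def profile(fv: FeatureVector, age: float, gender: str,
            scales: Mapping[str, ScaleModel], norms: NormModel,
            child_id: str | None = None) -> HandwritingProfile:
    """Global + category scores, severity band and per-feature scores."""
    missing = [c for c in SCALE_CATEGORIES if c not in scales]
    if missing:
        raise ScaleError(f"missing fitted scales for {missing}")
    g = global_score(fv, age, gender, scales["total"], norms)
    cat_scores = {
        c: global_score(fv, age, gender, scales[c], norms) for c in CATEGORIES
    }
    return HandwritingProfile(
        child_id=child_id,
        global_score=g,
        category_scores=cat_scores,
        severity=categorize(g, scales["total"].thresholds),
        feature_scores=score_vector(fv, age, gender, norms),
    )


# ---------------------------------------------------------------------------
# cluster evaluation

def cluster_assignments(cohort: CohortTable, scale: ScaleModel,
                        norms: NormModel) -> np.ndarray:
    """Boolean array: True where a child falls in the *atypical* cluster."""
    D = deviation_matrix(cohort, norms, scale.feature_ids)
    X = (D - scale.center) / scale.spread
    proj = X @ scale.axes.T
    d_typ = np.linalg.norm(proj - scale.centroid_typical, axis=1)
    d_aty = np.linalg.norm(proj - scale.centroid_atypical, axis=1)
    return d_aty < d_typ


def evaluate_clustering(is_atypical: Sequence[bool],
                        labels: Sequence[str]) -> tuple[float, float]:
    """Sensitivity and specificity of a 2-cluster split against cohort labels.

    sensitivity = fraction of dysgraphic-labeled children in the
    atypical cluster; specificity = fraction of school-labeled children
    in the typical cluster.
    """
    is_atypical = np.asarray(is_atypical, dtype=bool)
    labels = np.asarray(labels)
    dys = labels == "dysgraphic"
    sch = labels == "school"
    if not dys.any() or not sch.any():
        raise ScaleError("both 'dysgraphic' and 'school' labels must be present")
    sensitivity = float(is_atypical[dys].mean())
    specificity = float((~is_atypical[sch]).mean())
    return sensitivity, specificity
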