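"""PCA + K-means scale construction, scoring, thresholds and evaluation."""

import json

import numpy as np
import pytest

from graphoscale import (
    CohortTable,
    HandwritingProfile,
    ScaleModel,
    Severity,
    Thresholds,
    axis_importance,
    categorize,
    category_ids,
    cluster_assignments,
    evaluate_clustering,
    fit_scale,
    global_score,
    profile,
    project,
    threshold_from_quantiles,
)
from graphoscale.features import FeatureVector
from graphoscale.scales import ScaleError, deviation_matrix

from conftest import identity_norms, planted_deviation_cohort


@pytest.fixture(scope="module")
def norms():
    return identity_norms()


@pytest.fixture(scope="module")
def planted(norms):
    cohort = planted_deviation_cohort(n_school=200, n_atypical=50,
                                      shift=6.0, shifted_category="kinematic", seed=1)
    scale = fit_scale(cohort, norms, category="total", seed=0)
    return cohort, scale


# ---------------------------------------------------------------------------
# fitting

def test_pca_matches_brute_force_eigendecomposition(norms):
    """The scale's axes and variance fractions agree with an independent
    eigendecomposition of the standardized deviation covariance."""
    cohort = planted_deviation_cohort(n_school=60, n_atypical=15, seed=3)
    scale = fit_scale(cohort, norms, category="kinematic", seed=0)
    ids = list(category_ids("kinematic"))
    D = deviation_matrix(cohort, norms, ids)
    X = (D - D.mean(axis=0)) / D.std(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    np.testing.assert_allclose(
        scale.explained_variance_fractions, evals[:3] / evals.sum(), atol=1e-6
    )
    for k in range(3):
        dot = abs(np.dot(scale.axes[k], evecs[:, k]))
        assert dot == pytest.approx(1.0, abs=1e-6)  # equal up to sign
    assert scale.explained_variance_fractions.sum() <= 1.0 + 1e-9
    assert np.all(np.diff(scale.explained_variance_fractions) <= 1e-12)


def test_planted_populations_recovered(planted, norms):
    """Two 6-SD-separated populations: the clusters recover the labels."""
    cohort, scale = planted
    atyp = cluster_assignments(cohort, scale, norms)
    sens, spec = evaluate_clustering(atyp, cohort.df["label"])
    assert sens >= 0.95 and spec >= 0.95


def test_identical_children_give_degenerate_clustering_error(norms):
    cohort = planted_deviation_cohort(n_school=40, n_atypical=0, seed=0)
    for col in cohort.df.columns:
        if col.startswith("f_"):
            cohort.df[col] = 1.0
    with pytest.raises(ScaleError, match="degenerate"):
        fit_scale(cohort, norms, seed=0)


def test_too_few_school_children_rejected(norms):
    cohort = planted_deviation_cohort(n_school=5, n_atypical=40, seed=0)
    with pytest.raises(ScaleError, match="school"):
        fit_scale(cohort, norms, seed=0)


# ---------------------------------------------------------------------------
# projection and scoring on a hand-built scale

def _one_hot_scale(n_features=62, d_ref=2.0):
    axes = np.zeros((3, n_features))
    axes[0, 0] = axes[1, 1] = axes[2, 2] = 1.0
    return ScaleModel(
        category="total",
        feature_ids=list(category_ids("total"))[:n_features],
        center=np.zeros(n_features),
        spread=np.ones(n_features),
        axes=axes,
        explained_variance_fractions=np.array([0.5, 0.3, 0.2]),
        centroid_typical=np.zeros(3),
        centroid_atypical=np.array([5.0, 0.0, 0.0]),
        d_ref=d_ref,
        thresholds=Thresholds(0.1, 0.2, 0.3, 0.4),
    )


def _fv_with(deviations: dict[int, float]) -> FeatureVector:
    fv = FeatureVector()
    for fid in category_ids("total"):
        fv.set(fid, deviations.get(fid, 0.0))
    return fv


def test_projection_of_one_hot_axis(norms):
    scale = _one_hot_scale()
    first = scale.feature_ids[0]
    p = project(_fv_with({first: 2.0}), 8.0, "M", scale, norms)
    np.testing.assert_allclose(p, [2.0, 0.0, 0.0])
    p0 = project(_fv_with({}), 8.0, "M", scale, norms)
    np.testing.assert_allclose(p0, 0.0)


def test_projection_norm_bounded_by_input_norm(planted, norms):
    cohort, scale = planted
    D = deviation_matrix(cohort, norms, scale.feature_ids)
    X = (D - scale.center) / scale.spread
    proj = X @ scale.axes.T
    assert np.all(np.linalg.norm(proj, axis=1)
                  <= np.linalg.norm(X, axis=1) + 1e-9)


def test_missing_feature_rejected_by_name(norms):
    scale = _one_hot_scale()
    fv = _fv_with({})
    dropped = scale.feature_ids[5]
    del fv.values[dropped]
    with pytest.raises(ScaleError, match=str(dropped)):
        project(fv, 8.0, "M", scale, norms)


def test_global_score_closed_forms(norms):
    scale = _one_hot_scale(d_ref=2.0)
    assert global_score(_fv_with({}), 8.0, "M", scale, norms) == pytest.approx(1.0)
    first = scale.feature_ids[0]
    at_dref = _fv_with({first: 2.0})
    assert global_score(at_dref, 8.0, "M", scale, norms) == pytest.approx(np.exp(-1))


def test_global_score_monotone_along_rays(norms):
    scale = _one_hot_scale()
    first = scale.feature_ids[0]
    radii = np.linspace(0, 8, 30)
    scores = [global_score(_fv_with({first: r}), 8.0, "M", scale, norms) for r in radii]
    assert all(a >= b for a, b in zip(scores, scores[1:]))
    assert all(0 < s <= 1 for s in scores)


# ---------------------------------------------------------------------------
# axis importance

def test_axis_importance_one_hot_and_shares(norms):
    scale = _one_hot_scale()
    imp = axis_importance(scale)
    first_cat = "static"  # feature id 1
    assert imp.category_shares[0][first_cat] == pytest.approx(1.0)
    for shares in imp.category_shares:
        assert sum(shares.values()) == pytest.approx(1.0)


def test_axis_importance_equal_loadings_give_equal_shares():
    ids = [1, 13, 24, 38]  # one feature per category
    axes = np.zeros((3, 4))
    axes[0] = 0.5
    axes[1] = [0.5, -0.5, 0.5, -0.5]
    axes[2] = [0.5, 0.5, -0.5, -0.5]
    scale = ScaleModel(
        category="total", feature_ids=ids,
        center=np.zeros(4), spread=np.ones(4), axes=axes,
        explained_variance_fractions=np.array([0.4, 0.3, 0.2]),
        centroid_typical=np.zeros(3), centroid_atypical=np.ones(3),
        d_ref=1.0, thresholds=Thresholds(0.1, 0.2, 0.3, 0.4),
    )
    imp = axis_importance(scale)
    for axis_shares in imp.category_shares:
        for share in axis_shares.values():
            assert share == pytest.approx(0.25)


def test_axis_importance_shares_sum_to_one(planted):
    _, scale = planted
    imp = axis_importance(scale)
    for shares in imp.category_shares:
        assert sum(shares.values()) == pytest.approx(1.0)
    top = scale and imp.top_features(0, per_category=6)
    assert all(len(v) <= 6 for v in top.values())


# ---------------------------------------------------------------------------
# thresholds

def test_thresholds_hit_exact_rank_counts():
    rng = np.random.default_rng(0)
    scores = rng.uniform(0.01, 0.99, 1000)  # distinct w.p. 1
    th = threshold_from_quantiles(scores)
    for frac, cut in zip((0.02, 0.086, 0.15, 0.25), th.as_tuple()):
        assert int(np.sum(scores <= cut)) == int(np.ceil(frac * 1000))


def test_threshold_rank_arithmetic_on_1_to_100():
    scores = np.arange(1, 101) / 101.0
    th = threshold_from_quantiles(scores)
    assert th.vs == pytest.approx(2 / 101.0)  # 2nd smallest
    assert th.s == pytest.approx(9 / 101.0)   # ceil(8.6) = 9th
    assert th.m == pytest.approx(15 / 101.0)
    assert th.l == pytest.approx(25 / 101.0)


def test_duplicate_heavy_scores_overshoot_nominal_fractions():
    rng = np.random.default_rng(1)
    scores = np.round(rng.uniform(0.01, 0.99, 500), 2)  # ~5 ties per value
    th = threshold_from_quantiles(scores)
    for frac, cut in zip((0.02, 0.086, 0.15, 0.25), th.as_tuple()):
        assert np.mean(scores <= cut) >= frac  # bias direction: >= nominal


def test_bad_fractions_rejected():
    with pytest.raises(ScaleError, match="increasing"):
        threshold_from_quantiles(np.linspace(0, 1, 100), fractions=(0.3, 0.2, 0.4, 0.5))


def test_too_few_distinct_scores_rejected():
    with pytest.raises(ScaleError, match="distinct"):
        threshold_from_quantiles(np.linspace(0.1, 0.9, 20))


def test_thresholds_must_increase():
    with pytest.raises(ScaleError):
        Thresholds(0.3, 0.2, 0.4, 0.5)


# ---------------------------------------------------------------------------
# categorization

def test_categorize_sweep_produces_all_five_bands_in_order():
    th = Thresholds(0.1, 0.2, 0.3, 0.4)
    grid = np.linspace(0.01, 1.0, 200)
    seen = [categorize(s, th) for s in grid]
    order = [Severity.VERY_SEVERE, Severity.SEVERE, Severity.MODERATE,
             Severity.LIGHT, Severity.TYPICAL]
    assert [c for i, c in enumerate(seen) if i == 0 or c != seen[i - 1]] == order
    assert categorize(1.0, th) is Severity.TYPICAL
    assert categorize(0.05, th) is Severity.VERY_SEVERE


# ---------------------------------------------------------------------------
# profiles

def _manual_scales():
    scales = {}
    for cat in ("total", "static", "kinematic", "pressure", "tilt"):
        ids = list(category_ids(cat))
        axes = np.zeros((3, len(ids)))
        if cat == "total":
            # load one feature from each of three categories so deviations
            # in any of them reach the global score
            for k, fid in enumerate((24, 13, 1)):
                axes[k, ids.index(fid)] = 1.0
        else:
            axes[0, 0] = axes[1, 1] = axes[2, 2] = 1.0
        scales[cat] = ScaleModel(
            category=cat, feature_ids=ids,
            center=np.zeros(len(ids)), spread=np.ones(len(ids)), axes=axes,
            explained_variance_fractions=np.array([0.5, 0.3, 0.2]),
            centroid_typical=np.zeros(3), centroid_atypical=np.ones(3),
            d_ref=1.0, thresholds=Thresholds(0.1, 0.2, 0.3, 0.4),
        )
    return scales


def test_profile_of_child_at_all_norms(norms):
    scales = _manual_scales()
    p = profile(_fv_with({}), 8.0, "M", scales, norms, child_id="kid")
    assert p.global_score == pytest.approx(1.0)
    assert all(v == pytest.approx(1.0) for v in p.category_scores.values())
    assert p.severity is Severity.TYPICAL
    assert all(v == pytest.approx(1.0) for v in p.feature_scores.values())


def test_pressure_deviant_child_has_low_pressure_score(norms):
    scales = _manual_scales()
    first_pressure = scales["pressure"].feature_ids[0]  # id 24
    fv = _fv_with({first_pressure: 4.0})
    p = profile(fv, 8.0, "M", scales, norms)
    assert p.category_scores["pressure"] < min(
        p.category_scores[c] for c in ("static", "kinematic", "tilt"))
    assert p.global_score < 1.0


def test_profile_requires_all_scales(norms):
    scales = _manual_scales()
    del scales["tilt"]
    with pytest.raises(ScaleError, match="tilt"):
        profile(_fv_with({}), 8.0, "M", scales, norms)


def test_profile_json_roundtrip(norms):
    p = profile(_fv_with({13: 1.0}), 8.0, "M", _manual_scales(), norms, child_id="c1")
    back = HandwritingProfile.from_dict(json.loads(json.dumps(p.to_dict())))
    assert back.child_id == p.child_id
    assert back.global_score == pytest.approx(p.global_score)
    assert back.severity is p.severity
    assert back.feature_scores == pytest.approx(p.feature_scores)


# ---------------------------------------------------------------------------
# cluster evaluation

def test_perfect_separation_scores_one():
    labels = ["dysgraphic"] * 10 + ["school"] * 30
    atyp = [True] * 10 + [False] * 30
    assert evaluate_clustering(atyp, labels) == (1.0, 1.0)


def test_contingency_53_of_58_recovered():
    # 58 atypical writers, 5 assigned to the wrong cluster
    labels = ["dysgraphic"] * 58 + ["school"] * 100
    atyp = [True] * 53 + [False] * 5 + [False] * 86 + [True] * 14
    sens, spec = evaluate_clustering(atyp, labels)
    assert sens == pytest.approx(53 / 58)
    assert sens == pytest.approx(0.914, abs=5e-4)
    assert spec == pytest.approx(0.86)


def test_random_assignment_near_half():
    rng = np.random.default_rng(0)
    labels = np.where(rng.random(4000) < 0.5, "dysgraphic", "school")
    atyp = rng.random(4000) < 0.5
    sens, spec = evaluate_clustering(atyp, labels)
    assert sens == pytest.approx(0.5, abs=0.05)
    assert spec == pytest.approx(0.5, abs=0.05)


def test_missing_label_rejected():
    with pytest.raises(ScaleError):
        evaluate_clustering([True, False], ["school", "school"])


# ---------------------------------------------------------------------------
# persistence

def test_scale_model_json_roundtrip(tmp_path, planted):
    _, scale = planted
    path = tmp_path / "scale.json"
    scale.to_json(path)
    back = ScaleModel.from_json(path)
    np.testing.assert_allclose(back.axes, scale.axes)
    np.testing.assert_allclose(back.centroid_typical, scale.centroid_typical)
    assert back.d_ref == scale.d_ref
    assert back.thresholds == scale.thresholds
    assert back.feature_ids == scale.feature_ids
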