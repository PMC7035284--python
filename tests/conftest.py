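"""Shared fixtures and builders for the graphoscale test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from graphoscale import (
    CohortTable,
    FEATURE_IDS,
    NormCurve,
    NormModel,
    Recording,
    Stroke,
)
from graphoscale.synthetic import WriterParams, simulate_recording


def make_stroke(t, x, y, pressure=None, azimuth=None, altitude=None, line_id=None):
    """Stroke with sensible constant defaults for unspecified channels."""
    t = np.asarray(t, dtype=float)
    n = len(t)
    if pressure is None:
        pressure = np.full(n, 1.0)
    if azimuth is None:
        azimuth = np.full(n, 140.0)
    if altitude is None:
        altitude = np.full(n, 55.0)
    return Stroke(t, x, y, pressure, azimuth, altitude, line_id=line_id)


def make_recording(strokes, age=8.0, gender="M", **kwargs):
    return Recording(strokes=strokes, age=age, gender=gender, **kwargs)


def horizontal_line_recording(n=600, fs=60.0, speed=30.0, **stroke_channels):
    """One straight horizontal stroke at constant speed: the degenerate
    trace where every variability feature vanishes."""
    t = np.arange(n) / fs
    x = 10.0 + speed * t
    y = np.full(n, 100.0)
    return make_recording([make_stroke(t, x, y, **stroke_channels)])


@pytest.fixture(scope="session")
def sim_recording():
    """A typical synthetic writer, long enough for every spectral feature."""
    return simulate_recording(WriterParams(age=8.0, gender="M", seed=11))


@pytest.fixture(scope="session")
def sim_reference(sim_recording):
    from graphoscale import build_reference_spectra

    return build_reference_spectra([sim_recording])


@pytest.fixture(scope="session")
def sim_features(sim_recording, sim_reference):
    from graphoscale import extract_all

    return extract_all(sim_recording, ref=sim_reference)


# ---------------------------------------------------------------------------
# table-level synthetic cohorts (cheap: no trace simulation)

def make_cohort_table(
    n_per_gender=200,
    mean_coeffs=(2.0, 0.5, 0.0, -0.01),
    sd=1.0,
    seed=0,
    constant_ids=(),
    age_range=(5.0, 12.0),
    label="school",
) -> CohortTable:
    """Feature table whose every feature follows one planted cubic age
    trend with Gaussian noise (constant features optional)."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for gender in ("F", "M"):
        ages = rng.uniform(*age_range, n_per_gender)
        base = np.polynomial.polynomial.polyval(ages, np.asarray(mean_coeffs))
        for j in range(n_per_gender):
            values = {}
            for fid in FEATURE_IDS:
                if fid in constant_ids:
                    values[fid] = 7.0
                else:
                    values[fid] = base[j] + rng.normal(0.0, sd)
            rows.append({"child_id": f"C{i:04d}", "age": float(ages[j]),
                         "gender": gender, "label": label, "values": values})
            i += 1
    return CohortTable.from_rows(rows)


def identity_norms(alpha=None, beta=None, age_support=(5.0, 12.0)) -> NormModel:
    """Norm model with f_mean == 0 and f_std == 1 for every feature and
    gender, so feature values ARE the standardized deviations."""
    kwargs = {}
    if alpha is not None:
        kwargs["alpha"] = alpha
    if beta is not None:
        kwargs["beta"] = beta
    curves = {
        (fid, g): NormCurve(
            feature_id=fid, gender=g,
            mean_coeffs=np.array([0.0]), std_coeffs=np.array([1.0]),
            age_support=age_support, n_fit=0, std_floor=1e-9,
        )
        for fid in FEATURE_IDS
        for g in ("F", "M")
    }
    return NormModel(curves=curves, **kwargs)


def planted_deviation_cohort(
    n_school=200, n_atypical=50, shift=6.0, shifted_category="kinematic", seed=0
) -> CohortTable:
    """Two Gaussian populations in deviation space: school children at
    N(0, 1) on every feature, atypical children shifted by ``shift`` SDs
    on the features of one category."""
    from graphoscale import category_ids

    rng = np.random.default_rng(seed)
    shifted = set(category_ids(shifted_category))
    rows = []
    for i in range(n_school + n_atypical):
        label = "school" if i < n_school else "dysgraphic"
        values = {fid: rng.normal(0.0, 1.0) for fid in FEATURE_IDS}
        if label == "dysgraphic":
            for fid in shifted:
                values[fid] += shift
        rows.append({"child_id": f"C{i:04d}", "age": float(rng.uniform(5, 12)),
                     "gender": "F" if i % 2 else "M", "label": label,
                     "values": values})
    return CohortTable.from_rows(rows)
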