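"""The handwriting feature catalogue: 62 features in four categories.

Feature identifiers run 1-36 and 38-63 (37 is unassigned and kept so
deliberately: the numbering is the one practitioners using this feature
set know, and renumbering would break cross-references).  The partition
is: static 1-12, kinematic 13-23, pressure 24-36, tilt 38-63.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

CATEGORIES = ("static", "kinematic", "pressure", "tilt")


@dataclass(frozen=True)
class FeatureInfo:
    feature_id: int
    name: str
    category: str
    description: str


def _f(fid, name, category, description):
    return fid, FeatureInfo(fid, name, category, description)


CATALOGUE: dict[int, FeatureInfo] = dict(
    [
        # -- static -----------------------------------------------------
        _f(1, "Handwriting Moment", "static",
           "Mean |dy| between consecutive barycenters of 300-point bins within a "
           "line of text; measures straightness of the text line."),
        _f(2, "Handwriting Size", "static",
           "Mean area of the bounding box of 300-point bins within a line."),
        _f(3, "Space Between Strokes", "static",
           "Mean Euclidean distance from each stroke's last sample to the next "
           "stroke's first sample (pen-lift displacement)."),
        _f(4, "Handwriting Density", "static",
           "Mean number of samples per occupied cell of a 20-pixel grid covering "
           "the trace."),
        _f(5, "Average Stroke Direction", "static",
           "Circular mean of per-step movement directions arctan2(dy, dx), radians."),
        _f(6, "Angle Smoothness", "static",
           "Mean absolute turning angle over consecutive point triples, radians."),
        _f(7, "Area of the Text's Convex Hull", "static",
           "Area of the convex hull of all on-surface points."),
        _f(8, "Bandwidth of the Power Spectral of Tremor Frequencies", "static",
           "Width of the frequency interval covering 90% of the tremor spectrum."),
        _f(9, "Median of the Power Spectral of Tremor Frequencies", "static",
           "Median frequency of the tremor spectrum."),
        _f(10, "Entropy of Mean of Tremor Frequencies", "static",
           "KL divergence of the writer's tremor spectrum from the cohort reference."),
        _f(11, "Correlation of Mean of Tremor Frequencies", "static",
           "Pearson correlation of the writer's tremor spectrum with the cohort reference."),
        _f(12, "Distance of Mean of Tremor Frequencies", "static",
           "Euclidean distance of the writer's tremor spectrum from the cohort reference."),
        # -- kinematic --------------------------------------------------
        _f(13, "Mean Velocity", "kinematic", "Mean pen-tip speed over on-surface steps."),
        _f(14, "Maximum Velocity", "kinematic", "Maximum pen-tip speed."),
        _f(15, "Standard Deviation of Velocity", "kinematic", "SD of pen-tip speed."),
        _f(16, "Increase in Velocity", "kinematic",
           "Least-squares slope of speed vs. time."),
        _f(17, "Nb of Peaks of Velocity Change Per Second", "kinematic",
           "Local extrema of the smoothed speed series per second of writing."),
        _f(18, "Bandwidth of the Power Spectral of Speed Frequencies", "kinematic",
           "90% bandwidth of the speed spectrum."),
        _f(19, "Median of the Power Spectral of Speed Frequencies", "kinematic",
           "Median frequency of the speed spectrum."),
        _f(20, "Entropy of Mean of Speed Frequencies", "kinematic",
           "KL divergence of the speed spectrum from the cohort reference."),
        _f(21, "Correlation of Mean of Speed Frequencies", "kinematic",
           "Pearson correlation of the speed spectrum with the cohort reference."),
        _f(22, "Distance of Mean of Speed Frequencies", "kinematic",
           "Euclidean distance of the speed spectrum from the cohort reference."),
        _f(23, "In-Air-Time Ratio", "kinematic",
           "Fraction of total writing time the pen spends off the surface."),
        # -- pressure ---------------------------------------------------
        _f(24, "Mean Pressure", "pressure", "Mean pen pressure."),
        _f(25, "Maximum Pressure", "pressure", "Maximum pen pressure."),
        _f(26, "Standard Deviation of Pressure", "pressure", "SD of pen pressure."),
        _f(27, "Mean Speed of Pressure Change", "pressure",
           "Mean |rate of change| between consecutive 10-sample pressure bins."),
        _f(28, "Max Speed of Pressure Change", "pressure",
           "Maximum |rate of change| between consecutive 10-sample pressure bins."),
        _f(29, "Standard Deviation of Speed of Pressure Change", "pressure",
           "SD of the binned pressure rate-of-change series."),
        _f(30, "Increase of Speed of Pressure Change", "pressure",
           "Least-squares slope of the pressure rate series vs. time."),
        _f(31, "Nb of Peaks of Pressure Change Per Second", "pressure",
           "Pressure difference sign inversions per second."),
        _f(32, "Bandwidth of the Power Spectral of Speed of Pressure Change Frequencies",
           "pressure", "90% bandwidth of the pressure-rate spectrum."),
        _f(33, "Median of the Power Spectral of Speed of Pressure Change Frequencies",
           "pressure", "Median frequency of the pressure-rate spectrum."),
        _f(34, "Entropy of Mean of Speed of Pressure Change Frequencies", "pressure",
           "KL divergence of the pressure-rate spectrum from the cohort reference."),
        _f(35, "Correlation of Mean of Speed of Pressure Change Frequencies", "pressure",
           "Pearson correlation of the pressure-rate spectrum with the cohort reference."),
        _f(36, "Distance of Mean of Speed of Pressure Change Frequencies", "pressure",
           "Euclidean distance of the pressure-rate spectrum from the cohort reference."),
        # -- tilt -------------------------------------------------------
        _f(38, "Mean Tilt-Azimuth", "tilt", "Mean tilt-azimuth angle, degrees."),
        _f(39, "Maximum Tilt-Azimuth", "tilt", "Maximum tilt-azimuth angle, degrees."),
        _f(40, "Standard Deviation of Tilt-Azimuth", "tilt", "SD of the tilt-azimuth angle."),
        _f(41, "Mean Tilt-Altitude", "tilt", "Mean tilt-altitude angle, degrees."),
        _f(42, "Maximum Tilt-Altitude", "tilt", "Maximum tilt-altitude angle, degrees."),
        _f(43, "Standard Deviation of Tilt-Altitude", "tilt", "SD of the tilt-altitude angle."),
        _f(44, "Mean Speed of Tilt-Azimuth Change", "tilt",
           "Mean |rate of change| between consecutive 10-sample azimuth bins."),
        _f(45, "Max Speed of Tilt-Azimuth Change", "tilt",
           "Maximum |rate of change| between consecutive 10-sample azimuth bins."),
        _f(46, "Standard Deviation of Speed of Tilt-Azimuth Change", "tilt",
           "SD of the binned azimuth rate-of-change series."),
        _f(47, "Mean Speed of Tilt-Altitude Change", "tilt",
           "Mean |rate of change| between consecutive 10-sample altitude bins."),
        _f(48, "Max Speed of Tilt-Altitude Change", "tilt",
           "Maximum |rate of change| between consecutive 10-sample altitude bins."),
        _f(49, "Standard Deviation of Speed of Tilt-Altitude Change", "tilt",
           "SD of the binned altitude rate-of-change series."),
        _f(50, "Increase of Speed of Tilt-Azimuth Change", "tilt",
           "Least-squares slope of the azimuth rate series vs. time."),
        _f(51, "Increase of Speed of Tilt-Altitude Change", "tilt",
           "Least-squares slope of the altitude rate series vs. time."),
        _f(52, "Nb of Peaks of Tilt-Azimuth Change Per Second", "tilt",
           "Azimuth difference sign inversions per second."),
        _f(53, "Nb of Peaks of Tilt-Altitude Change Per Second", "tilt",
           "Altitude difference sign inversions per second."),
        _f(54, "Bandwidth of the Power Spectral of Speed of Tilt-Azimuth Change Frequencies",
           "tilt", "90% bandwidth of the azimuth-rate spectrum."),
        _f(55, "Median of the Power Spectral of Speed of Tilt-Azimuth Change Frequencies",
           "tilt", "Median frequency of the azimuth-rate spectrum."),
        _f(56, "Entropy of Mean of Speed of Tilt-Azimuth Change Frequencies", "tilt",
           "KL divergence of the azimuth-rate spectrum from the cohort reference."),
        _f(57, "Correlation of Mean of Speed of Tilt-Azimuth Change Frequencies", "tilt",
           "Pearson correlation of the azimuth-rate spectrum with the cohort reference."),
        _f(58, "Distance of Mean of Speed of Tilt-Azimuth Change Frequencies", "tilt",
           "Euclidean distance of the azimuth-rate spectrum from the cohort reference."),
        _f(59, "Bandwidth of the Power Spectral of Speed of Tilt-Altitude Change Frequencies",
           "tilt", "90% bandwidth of the altitude-rate spectrum."),
        _f(60, "Median of the Power Spectral of Speed of Tilt-Altitude Change Frequencies",
           "tilt", "Median frequency of the altitude-rate spectrum."),
        _f(61, "Entropy of Mean of Speed of Tilt-Altitude Change Frequencies", "tilt",
           "KL divergence of the altitude-rate spectrum from the cohort reference."),
        _f(62, "Correlation of Mean of Speed of Tilt-Altitude Change Frequencies", "tilt",
           "Pearson correlation of the altitude-rate spectrum with the cohort reference."),
        _f(63, "Distance of Mean of Speed of Tilt-Altitude Change Frequencies", "tilt",
           "Euclidean distance of the altitude-rate spectrum from the cohort reference."),
    ]
)

#: all 62 feature identifiers, ascending
FEATURE_IDS: tuple[int, ...] = tuple(sorted(CATALOGUE))


def category_ids(category: str) -> tuple[int, ...]:
    """Feature ids belonging to one category (or all of them for 'total')."""
    if category == "total":
        return FEATURE_IDS
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES + ('total',)}")
    return tuple(i for i in FEATURE_IDS if CATALOGUE[i].category == category)


def export_catalogue_csv(path: str | Path) -> None:
    """Write the catalogue as ``id,name,category,description`` CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "category", "description"])
        for fid in FEATURE_IDS:
            info = CATALOGUE[fid]
            writer.writerow([fid, info.name, info.category, info.description])


# sanity of the partition, checked at import time
_counts = {c: len(category_ids(c)) for c in CATEGORIES}
assert _counts == {"static": 12, "kinematic": 11, "pressure": 13, "tilt": 26}, _counts
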