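"""Synthetic pen recordings and cohorts with the statistics the pipeline assumes.

The generator produces *plausible-statistics* traces, not legible
handwriting: several lines of several strokes each, built from smooth
sinusoidal letter-like oscillations advancing in x and sampled at a
nominal 60 Hz.  Its realism target is the joint distribution of the 62
catalogue features, namely

* cubic age trends — baseline writing speed rises with age while speed
  variability and path tremor shrink;
* a small gender offset in speed and pressure so per-gender norm
  curves differ;
* four per-writer *deficit* severities (kinematic, pressure, tilt,
  static), each 0 for a typical writer, that monotonically distort the
  corresponding feature family:

  - ``kinematic``: stronger velocity jitter and jerk, extra
    high-frequency path tremor, slower mean speed, longer in-air gaps;
  - ``pressure``: larger pressure SD and more sample-to-sample pressure
    inversions;
  - ``tilt``: wobblier azimuth and altitude angles;
  - ``static``: wavier text lines and more irregular letter size.

All randomness flows from a single integer seed through spawned
``numpy`` seed sequences, so cohorts are exactly reproducible and
per-writer streams are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .trace_model import Recording, Stroke

DEFICIT_KEYS = ("kinematic", "pressure", "tilt", "static")

# default trace shape: 16 strokes of 440 samples (~2 min of writing),
# long enough that every spectral feature has at least one complete bin
N_LINES = 4
STROKES_PER_LINE = 4
SAMPLES_PER_STROKE = 440
SAMPLING_RATE_HZ = 60.0
LINE_SPACING = 70.0     # device points, y grows downward
LETTER_WAVELENGTH = 30.0  # points of forward progress per letter oscillation

# cubic age trend of baseline speed, coefficients in (age - 5) years
SPEED_AGE_COEFFS = (20.0, 9.0, -0.45, -0.005)  # points/s


def _speed_for_age(age: float) -> float:
    a = age - 5.0
    c0, c1, c2, c3 = SPEED_AGE_COEFFS
    return c0 + c1 * a + c2 * a**2 + c3 * a**3


@dataclass
class WriterParams:
    """One synthetic writer: demographics, deficit severities and a seed."""

    age: float
    gender: str
    deficit: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    laterality: str = "right"
    child_id: str | None = None

    def severity(self, key: str) -> float:
        return float(self.deficit.get(key, 0.0))


@dataclass
class CohortSpec:
    """A two-population cohort: typical (school) and atypical writers."""

    n_school: int
    n_atypical: int
    age_range: tuple[float, float] = (5.0, 12.0)
    gender_mix: float = 0.5  # fraction of girls
    deficit_profile: dict[str, float] = field(
        default_factory=lambda: {"kinematic": 3.0, "pressure": 3.0, "tilt": 1.0, "static": 1.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_school < 0 or self.n_atypical < 0:
            raise ValueError("cohort counts must be non-negative")


def _smooth_noise(rng: np.random.Generator, n: int, sigma_samples: float) -> np.ndarray:
    """Unit-SD low-pass noise (Gaussian-filtered white noise)."""
    w = gaussian_filter1d(rng.standard_normal(n), sigma_samples, mode="reflect")
    sd = w.std()
    return w / sd if sd > 0 else w


def simulate_recording(
    params: WriterParams,
    n_lines: int = N_LINES,
    strokes_per_line: int = STROKES_PER_LINE,
    samples_per_stroke: int = SAMPLES_PER_STROKE,
    sampling_rate_hz: float = SAMPLING_RATE_HZ,
) -> Recording:
    """Generate one multi-line, multi-stroke recording for a writer."""
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    dt = 1.0 / sampling_rate_hz
    k = params.severity("kinematic")
    dp = params.severity("pressure")
    tl = params.severity("tilt")
    st = params.severity("static")
    a5 = params.age - 5.0

    # writer-level baselines
    v_base = _speed_for_age(params.age) * float(np.exp(rng.normal(0.0, 0.12)))
    v_base *= 1.04 if params.gender == "F" else 1.0
    v_base /= 1.0 + 0.08 * k
    sigma_v = max(0.16 - 0.01 * a5, 0.05) * (1.0 + 0.5 * k)
    tremor_amp = max(0.35 - 0.02 * a5, 0.1) + 1.0 * k
    p_base = max(float(rng.normal(1.0, 0.1)), 0.3) * (1.02 if params.gender == "F" else 1.0)
    p_sigma = p_base * (0.03 + 0.05 * dp) * max(1.1 - 0.03 * a5, 0.8)
    p_flicker = p_base * (0.003 + 0.03 * dp)
    az_base = float(np.clip(rng.normal(40.0 if params.laterality == "left" else 140.0, 8.0), 5, 175))
    al_base = float(np.clip(rng.normal(55.0, 5.0), 10, 170))
    tilt_sigma = 1.0 + 3.0 * tl
    letter_amp = 10.0 * (1.0 - 0.02 * a5)
    wave_amp = 1.5 + 5.0 * st
    gap_scale = (1.0 + 0.35 * k)

    strokes: list[Stroke] = []
    t_cursor = 0.0
    for line in range(n_lines):
        baseline_y = 100.0 + line * LINE_SPACING
        x_cursor = 50.0
        wave_phase = rng.uniform(0, 2 * np.pi)
        for j in range(strokes_per_line):
            n = samples_per_stroke
            t = t_cursor + np.arange(n) * dt

            # modulated forward speed
            jitter = sigma_v * _smooth_noise(rng, n, sigma_samples=5.0)
            f_jerk = rng.uniform(8.0, 12.0)
            jerk = (0.12 * k) * np.sin(2 * np.pi * f_jerk * (t - t[0]) + rng.uniform(0, 2 * np.pi))
            jerk += (0.05 * k) * rng.standard_normal(n)
            speed = v_base * np.clip(1.0 + jitter + jerk, 0.15, None)
            progress = np.cumsum(speed) * dt

            amp = letter_amp * (1.0 + (0.06 + 0.25 * st) * rng.normal())
            amp = max(abs(amp), 1.0)
            x = x_cursor + 0.6 * progress
            y = baseline_y + amp * np.sin(2 * np.pi * progress / LETTER_WAVELENGTH)
            y += wave_amp * np.sin(2 * np.pi * (x - 50.0) / 400.0 + wave_phase)

            # high-frequency path tremor
            f1, f2 = rng.uniform(8.0, 15.0, size=2)
            ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
            tr = tremor_amp * (np.sin(2 * np.pi * f1 * (t - t[0]) + ph1)
                               + 0.6 * np.sin(2 * np.pi * f2 * (t - t[0]) + ph2))
            tr += 0.3 * tremor_amp * rng.standard_normal(n)
            y = y + tr
            x = x + 0.5 * tr * rng.uniform(0.3, 0.7)

            pressure = (
                p_base * (1.0 + 0.08 * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi)))
                + p_sigma * _smooth_noise(rng, n, sigma_samples=8.0)
                + p_flicker * rng.standard_normal(n)
            )
            pressure = np.clip(pressure, 0.01, None)

            azimuth = np.clip(
                az_base
                + 3.0 * _smooth_noise(rng, n, sigma_samples=30.0)
                + tilt_sigma * rng.standard_normal(n),
                0.0, 180.0,
            )
            altitude = np.clip(
                al_base
                + 2.0 * _smooth_noise(rng, n, sigma_samples=30.0)
                + tilt_sigma * rng.standard_normal(n),
                0.0, 180.0,
            )

            strokes.append(Stroke(t, x, y, pressure, azimuth, altitude, line_id=line))
            x_cursor = float(x[-1]) + 8.0

            last_in_line = j == strokes_per_line - 1
            base_gap = 0.55 if last_in_line else 0.25
            gap = base_gap * gap_scale * float(np.exp(rng.normal(0.0, 0.15)))
            t_cursor = float(t[-1]) + min(gap, 0.95)

    return Recording(
        strokes=strokes,
        age=params.age,
        gender=params.gender,
        laterality=params.laterality,
        sampling_rate_hz=sampling_rate_hz,
        child_id=params.child_id,
    )


def simulate_cohort(spec: CohortSpec, **recording_kwargs) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a labeled two-population cohort of recordings.

    Returns the recordings plus a metadata table with columns
    ``child_id, age, gender, label``.  School writers have all deficit
    severities at 0; atypical writers draw per-category severities
    around ``spec.deficit_profile`` (log-normal spread so profiles vary
    child to child, echoing that the same condition expresses itself in
    different skill combinations).
    """
    root = np.random.SeedSequence(spec.seed)
    n_total = spec.n_school + spec.n_atypical
    child_seqs = root.spawn(n_total + 1)
    meta_rng = np.random.default_rng(child_seqs[-1])

    recordings: list[Recording] = []
    rows: list[dict] = []
    for i in range(n_total):
        label = "school" if i < spec.n_school else "dysgraphic"
        age = float(meta_rng.uniform(*spec.age_range))
        gender = "F" if meta_rng.random() < spec.gender_mix else "M"
        laterality = "left" if meta_rng.random() < 0.12 else "right"
        if label == "school":
            deficit = {}
        else:
            deficit = {
                key: base * float(np.exp(meta_rng.normal(0.0, 0.25)))
                for key, base in spec.deficit_profile.items()
            }
        child_id = f"{'S' if label == 'school' else 'D'}{i:04d}"
        params = WriterParams(
            age=age, gender=gender, deficit=deficit,
            seed=int(child_seqs[i].generate_state(1)[0] % (2**31)),
            laterality=laterality, child_id=child_id,
        )
        recordings.append(simulate_recording(params, **recording_kwargs))
        rows.append({"child_id": child_id, "age": age, "gender": gender, "label": label})
    return recordings, pd.DataFrame(rows)
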