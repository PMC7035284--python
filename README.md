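# graphoscale

Data-driven handwriting-quality scales from digitizer pen recordings.

Handwriting difficulties (dysgraphia, in its severe form) are usually
diagnosed with rule-based pen-and-paper tests that see only the static
trace. A tablet records much more — pen position, pressure and tilt at
~60 Hz — and the dynamics of writing carry most of the diagnostic
signal. `graphoscale` turns such recordings into interpretable,
norm-referenced scores for clinicians, researchers and school
assessment tools:

1. **Feature extraction.** A catalogue of 62 features in four
   categories — *static* (line straightness, size, density, convex-hull
   area, tremor spectra), *kinematic* (speed statistics and spectra,
   fluency, in-air time ratio), *pressure* and *tilt* (level, rate of
   change, sign inversions and rate spectra of each channel) — computed
   per child from the stroke time series.
2. **Norm referencing.** Each feature *f* is compared to cubic
   age-trend curves fitted per gender on a reference cohort:
   Z = |f − f_mean(age)| / f_std(age), mapped to a bounded score
   e^(−α·Z^β) ∈ (0, 1] (defaults α = ln 2, β = 2: score 0.5 at 1 SD).
3. **Severity scales.** Signed standardized deviations are projected on
   their 3 leading principal axes and clustered with K-means (k = 2).
   The child's distance *d* to the *typical* centroid (the cluster
   holding most reference children) gives the global score
   e^(−d / d_ref). Quantile thresholds over the reference scores
   (2 / 8.6 / 15 / 25 %) band the scale into five severity levels, and
   the same construction per category yields a four-axis handwriting
   profile.

Because no public pen-recording corpus exists, the package ships a
synthetic cohort generator (`graphoscale.synthetic`) producing traces
with planted age trends and per-category deficit severities, so the
whole pipeline is testable and reproducible end to end.

## Worked example

```python
from graphoscale import (CohortSpec, simulate_cohort, fit_norms, fit_scale,
                         profile, FeatureVector)
from graphoscale.cli import extract_cohort

recordings, labels = simulate_cohort(CohortSpec(n_school=120, n_atypical=25, seed=8))
cohort, _ = extract_cohort(recordings, labels)          # 62 features per child
norms = fit_norms(cohort)                               # age/gender norm curves
scales = {c: fit_scale(cohort, norms, category=c, seed=8)
          for c in ("total", "static", "kinematic", "pressure", "tilt")}

row = cohort.df[cohort.df["label"] == "dysgraphic"].iloc[0]
fv = FeatureVector(values={fid: row[f"f_{fid}"] for fid in cohort.feature_ids},
                   flags={fid: "ok" for fid in cohort.feature_ids})
p = profile(fv, row["age"], row["gender"], scales, norms, child_id=row["child_id"])
print(f"child {p.child_id}: global {p.global_score:.3f} ({p.severity.value})")
for cat, s in p.category_scores.items():
    print(f"  {cat:9s} {s:.3f}")
```

prints

```
child D0120: global 0.000 (very_severe)
  static    0.025
  kinematic 0.000
  pressure  0.000
  tilt      0.004
```

— this child, generated with strong kinematic and pressure deficits,
scores near 0 on the global scale and lands in the *very severe* band;
the per-category scores show the deficit is worst in the kinematic and
pressure skills while the static trace is (relatively) least affected.
A score of 1.0 would mean sitting exactly on the typical centroid;
e^(−1) ≈ 0.37 means being as far from it as the average reference
child.

The same pipeline is available from the shell:

```bash
graphoscale run --n-school 120 --n-atypical 25 --seed 8 --out out/
graphoscale score out/features.csv --norms out/norms.json \
    --scale out/scale_total.json --out out/scores.csv
```

## Layout

| module | contents |
| --- | --- |
| `graphoscale.trace_model` | recording data model, validation, CSV/JSON I/O, line segmentation |
| `graphoscale.catalogue` | the 62-feature registry (ids, names, categories) |
| `graphoscale.spectral_core` | tremor residual, averaged spectra, the five spectral summaries |
| `graphoscale.features` | the four feature families and `extract_all` |
| `graphoscale.norms` | cubic age/gender norm curves, z-scores, feature scores |
| `graphoscale.scales` | PCA + K-means scales, thresholds, profiles, cluster evaluation |
| `graphoscale.synthetic` | synthetic writer and cohort generator |
| `graphoscale.cli` | `graphoscale` command-line tool and pipeline orchestration |

See `docs/methods.md` for the modelling choices, parameters and known
limitations.
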