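# mirdose

Preclinical internal-dosimetry toolkit for beta-emitter radiopharmaceutical
therapy studies in mice — built around the self-dose MIRD schema for
Lu-177-labelled tracers, with peritoneal carcinomatosis scoring and a
matching synthetic-cohort generator.

## Who this is for

Groups running gamma-counting biodistribution and radioimmunotherapy
experiments in mice (e.g. pretargeted therapy of peritoneal carcinomatosis
with Lu-177-labelled tetrazine probes) who need to go from raw per-organ
counting tables to organ and tumor absorbed doses, and from necropsy lesion
scores to cohort treatment-effect summaries.

## The model

**Quantification.** A harvested organ's measurement is reduced to the
standard biodistribution quantity, percent injected activity per gram:

    %IA/g = 100 · A(t) · e^{λ_phys t} / A_inj / m

with λ_phys = ln 2 / T½ (Lu-177: T½ = 6.65 d, mean β energy 133.3 keV,
endpoint 498.3 keV, mean soft-tissue range 0.2 mm). Decay correction to the
injection time makes harvest cohorts at 24/48/144 h comparable.

**Cumulated activity.** The MIRD source term Ã = ∫ A(t) dt is assembled from
the sparse physical time-activity curve as: linear rise from (0, 0) to the
first point, trapezoids between points, and an analytic mono-exponential
tail A_last/λ_tail with λ_tail = max(λ_eff, λ_phys), λ_eff fitted
log-linearly to the last points. The physical floor keeps Ã finite.

**Absorbed dose.** With electron ranges (0.2 mm) far below organ sizes only
self-irradiation matters, so per region

    D = Ã · S,

S the self S-value (Gy/Bq/s). S comes tabulated (packaged full-transport
Monte Carlo reference values for heart, lungs, liver, kidneys, spleen,
brain and a 3 mm / 0.016 g tumor sphere), from the local-deposition limit
S = E_mean/m (an upper bound: absorbed fraction φ = 1), or from a
straight-track Monte Carlo absorbed-fraction estimator for spheres
(S = φ · E_mean/m). Cohort tables report mean ± sample SD over mice and
scale linearly to the administered activity (e.g. Gy per 40 MBq).

**PCI.** The peritoneal carcinomatosis index sums lesion-size scores (0–3)
over 13 abdominopelvic regions (Sugarbaker grid, rodent-adapted), maximum
39; group summaries and baseline-normalised bioluminescence growth
trajectories (geometric means) quantify treatment effect.

## Worked example

```python
import mirdose as m

cfg = m.default_study_config(seed=1)          # Tz-2-like cohort, n = 9 mice
counting = m.generate_biodist_cohort(cfg)     # raw gamma-counting table
model = m.MIRDDoseModel.from_counting(counting)
res = model.fit(scheme="trapezoid_tail")
print(res.summary(administered_MBq=40))
```

prints

```
MIRD self-dose cohort summary
  nuclide: Lu-177 (T1/2 = 6.65 d)
  integration scheme: trapezoid_tail
  organs without S-value (excluded): Blood
  organ tracer  dose_gy_per_MBq  sd_gy_per_MBq  n_mice   dose_gy     sd_gy
  Heart   Tz-2        2.505e-03      5.278e-04       9 1.002e-01 2.111e-02
  Lungs   Tz-2        3.997e-03      9.932e-04       9 1.599e-01 3.973e-02
  Liver   Tz-2        1.677e-02      3.113e-03       9 6.706e-01 1.245e-01
Kidneys   Tz-2        2.879e-02      5.042e-03       9 1.152e+00 2.017e-01
 Spleen   Tz-2        5.976e-02      1.895e-02       9 2.390e+00 7.580e-01
  Brain   Tz-2        9.378e-04      3.477e-04       9 3.751e-02 1.391e-02
 Tumors   Tz-2        5.241e-01      2.757e-01       9 2.097e+01 1.103e+01
```

Reading the table: each row is one region's cohort dosimetry. The tumor row
says this simulated cohort receives 0.52 ± 0.28 Gy per MBq injected, i.e.
21 ± 11 Gy for a 40 MBq therapy administration — dominated by the high
tumor S-value (1.32 × 10⁻⁹ Gy/Bq/s for the 0.016 g sphere), while healthy
organs stay one to two orders of magnitude lower. The large tumor SD is
real biology, not noise: the configured tumor uptake distribution has a
~70% coefficient of variation. Blood has no self S-value entry and is
excluded from dosimetry (it still appears in %IA/g outputs).

The same pipeline runs from the shell:

```bash
mirdose simulate --seed 1 --out-dir out/
mirdose dose --counting out/counting.csv --administered-mbq 40 --out out/dose.csv
mirdose pci --pci out/pci.csv
mirdose report --seed 1 --out-dir out/        # combined dose + PCI + growth report
```

Real data drop in anywhere synthetic data appear: `mirdose dose --counting
your_counts.csv` expects columns `mouse_id, organ, mass_g, activity_Bq,
time_h, injected_MBq`.

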