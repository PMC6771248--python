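# Methods

This note documents the models, numerical choices and limitations behind
`mirdose`. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Decay arithmetic and %IA/g quantification

All corrections use the physical decay constant λ_phys = ln 2 / T½ with the
half-life stored in days and converted to hours once, inside
`NuclideProperties`. Hours are the time unit everywhere else. The packaged
Lu-177 constants are: T½ = 6.65 d, mean β energy 133.3 keV, endpoint
498.3 keV, mean soft-tissue range 0.2 mm.

`to_pct_ia_per_g` reduces one gamma-counting measurement to
%IA/g = 100 · A_ref / A_inj / m. By default A_ref is the measured activity
decay-corrected back to the injection time (t = 0), so values from 24, 48
and 144 h harvest groups are directly comparable; the uncorrected behaviour
is exposed via `decay_correct=False` since counting protocols differ on
this point. Counts-to-Bq calibration is a single multiplicative efficiency
factor divided out at quantification; spectroscopy, dead time and geometry
corrections are out of scope. Paired organs (kidneys) are treated as one
region with combined mass, matching the reference S-factor table's single
kidneys row.

## Time-activity curves and cumulated activity

The integrator works on the *physical* activity fraction of the injected
activity. `tac_from_biodist` therefore re-applies e^{−λ_phys t} when fed
decay-corrected records; without this, the floor below would be meaningless
(a decay-corrected biological curve may legitimately clear slower than
λ_phys, while physical activity cannot).

Ã is assembled piecewise:

* **Rise:** linear from (0, 0) to the first measured point. Rationale:
  after intraperitoneal administration the region holds no activity at
  t = 0 and no earlier samples exist.
* **Body:** trapezoids between measured points.
* **Tail:** analytic mono-exponential, A_last/λ_tail, with
  λ_tail = max(λ_eff, λ_phys). λ_eff comes from a log-linear least-squares
  fit over the last `tail_window` points (default 2, i.e. the exact
  two-point formula). The physical floor encodes that apparent biological
  accumulation cannot outlast physical decay and guarantees a finite Ã for
  every curve; a fitted non-positive rate (rising tail) is flagged with a
  warning and floored the same way.

A `single_point_tail` scheme (Ã = A(t₁)·(t₁ + 1/λ_tail)) is provided for
designs with one usable time point. Refinement invariance holds wherever an
added point lies on the piecewise model *and* leaves the tail-fit window's
points unchanged; inserting points between the last two measurements
redefines the fitted tail, which is by construction data-driven.

Because the underlying study does not state its own integration scheme, the
scheme is an explicit, recorded parameter of every result rather than an
attempt to reproduce an unpublished internal pipeline; the printed
per-organ Gy/MBq of the reference study are correspondingly shipped as a
reference table, not regenerated (their underlying per-mouse curves are not
public). Units: Ã is reported in Bq·s per MBq injected
(fraction × 10⁶ Bq × 3600 s/h).

## Self S-values

Only self-irradiation is modelled: the 0.2 mm mean electron range is small
against mouse organ dimensions, and the photon contribution to self-dose is
ignored on the same electrons-dominate rationale. Three provenances:

1. **Tabulated** — the packaged reference table (full-transport Monte Carlo
   values for 7 regions with reference masses) drives cohort dosimetry.
2. **Local deposition** — S = E_mean/m with absorbed fraction φ ≡ 1. This
   is an upper bound on any self S-value at the same mass (escape only
   reduces deposition), a property the test suite checks against every
   tabulated row.
3. **Straight-track Monte Carlo** — for spheres: source points uniform in
   volume, isotropic directions, energy deposited uniformly along a
   straight track (continuous slowing down; no scattering, no
   bremsstrahlung). For a convex region the inside portion of a track is
   its initial segment, so φ = E[min(d_exit, L)]/L with
   d_exit = −sc + √(R² − s²(1−c²)). Estimates are reproducible for a fixed
   seed and carry a standard error (∝ n^{−1/2}).

`mc_s_value` has two modes: `mean_energy` (every history at the mean β
energy and mean range — the default, matching the mean-energy S-value
definition) and `sampled_spectrum` (energies drawn from a simplified
allowed β spectrum N(E) ∝ p·E_tot·(Q−E)², each mapped to a track length by
a configurable energy→range map, default a power law E^1.7 anchored at the
mean range). The simplified single-branch spectrum has a higher mean energy
(~Q/3 ≈ 166 keV) than the true multi-branch decay (133.3 keV), so
spectrum-mode S-values exceed mean-energy ones; the mode exists for
sensitivity analysis, not as a transport benchmark.

Sphere geometry: when a weighed mass is supplied it wins — the effective
density follows from mass/volume (the study tumor, 3 mm diameter at
0.016 g, implies 1.13 g/cm³). An explicitly supplied density must agree
with a supplied mass within 5%. Default density without a mass is
1.0 g/cm³ (soft tissue).

## Cohort dosimetry

D = Ã × S per mouse and region; cohort tables report the arithmetic mean
and the n−1 sample SD (SD 0 with n = 1 flagged by `n_mice`), ordered by the
S-table's organ order then tracer so output is permutation-invariant.
Sample SD follows the dosimetry-table convention of the reference study
(whose statistics section says SEM but whose tables say SD); SEM is
available in the PCI summaries where dispersion choice is exposed. Scaling
to an administered activity multiplies mean and SD alike — the SD of a
linearly scaled variable — which is also how the reference per-MBq table
reproduces its printed Gy/40 MBq therapy doses (a 0.1% regression test).

Both aggregation orders are implemented: per-mouse integration then
averaging (default) and integration of the cohort-mean curve
(`per_mouse=False`; no dispersion estimate, reported as NaN). Organs
lacking an S-table row (blood, typically) are dropped with a warning, or
raise with `strict=True`.

## PCI and growth

The region grid is the 13-region Sugarbaker scheme (9 abdominopelvic + 4
small bowel) with free-form region labels so any 13-region rodent dialect
fits; scores are integers 0–3, the total lies in [0, 39]. A total of 0 is
allowed for generality although tumor-bearing study animals score ≥ 1.

Growth records are scalar bioluminescence fluxes. Trajectories are
normalised per mouse to the baseline day (calibration constants cancel) and
summarised per group by the geometric mean, appropriate for log-normally
dispersed fluxes. Observations beyond day 20 are excluded: the flux–size
relationship loses linearity there. Mice without a positive baseline are
dropped with a logged warning.

## Synthetic cohorts

The generators emit exactly the CSV dialects the readers consume and invert
the quantification stage (physical decay and counting efficiency applied on
the way out), so the full pipeline round-trips; in the noiseless limit the
recovery is exact to machine precision and the cohort dose equals the
hand-computed dose of the configured mean curve (both tested).

Distributional choices: %IA/g is lognormal with exact moment matching
(σ² = ln(1 + sd²/mean²), μ = ln mean − σ²/2) — tumor CVs near 70% would
drive Gaussian draws negative; organ masses and per-animal PCI targets are
truncated normals (masses on (0, ∞), PCI targets on [0, 39], rounded). PCI
targets are spread over the 13 regions by constrained uniform allocation
(one unit at a time to a random region below the 3 cap), so each emitted
map sums exactly to its drawn target. Growth is exponential,
flux = baseline · e^{rate·g·day} · lognormal noise, with g the treatment
rate multiplier for the therapy group and 1 otherwise, on a weekly-style
schedule (days 0, 7, 13, 20).

Default study conditions: three harvest times (24/48/144 h), n = 9 mice,
10 MBq injected; tumor %IA/g 6.29 ± 4.27 (24 h) and 3.80 ± 2.18 (144 h)
and blood 0.22 ± 0.02 (24 h) from the emulated study's printed values, with
the 48 h tumor level (5.0 ± 3.4) interpolated between them; tumor mass
0.016 ± 0.003 g and healthy-organ masses from the reference S-table; the
remaining organs carry renal-clearance-like levels chosen once as
plausible. PCI groups: saline 30.0 ± 2.3, tracer-only 30.8 ± 1.4, therapy
15.5 ± 2.3, n = 6 each. Draws are independent across organs and times
within a mouse — real repeated-measures correlation is not modelled — and
every generator is deterministic for a fixed seed.

What passing tests therefore show: the pipeline's arithmetic, integration,
scoring and round-trip consistency under realistic marginal distributions.
What they do not show: recovery of real in-vivo kinetics (no compartmental
PK model is fitted), inter-organ correlation structure, or the reference
study's unpublished per-mouse curves.

## Problem sizes and numerical tolerances

The acceptance computations use cohorts of 10,000 mice (biodistribution
means), 1,000 animals (PCI) and 10⁶ Monte Carlo histories — sizes at which
the 3-standard-error sampling bounds are decisively tight while a full run
stays in the seconds range. Integrator cross-checks use dense trapezoidal
quadrature of the identical piecewise model on ~2 × 10⁵-point grids
including the knots (piecewise-linear parts are then exact; the tail is
truncated at 40/λ, a e^{−40} remainder). The sphere absorbed-fraction
oracle is an 800-node Gauss–Legendre product quadrature over emission
radius and direction cosine, independent of the Monte Carlo code path.
Known edge cases: equal tail points fit λ_eff = 0 (floored); zero track
length returns φ = 1 exactly; zero-activity curves integrate to the ramp +
body area only.
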