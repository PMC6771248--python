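"""Synthetic preclinical cohorts with the statistical structure of a
pretargeted-radioimmunotherapy biodistribution study.

The generators emit the same CSV dialects the real-data readers consume, so
every pipeline stage is exercisable without downloads:

* **Biodistribution** — per mouse x organ x scheduled harvest time, organ
  mass ~ truncated normal (> 0) and %IA/g ~ lognormal with moments matched
  to the configured mean/SD (%IA/g has coefficients of variation near 70%
  in tumors, so Gaussian draws would go negative). The emitted quantity is
  the *measured* activity at harvest: physical decay and the counting
  efficiency are applied, i.e. the exact inverse of the quantification
  stage, so the pipeline round-trips.
* **PCI** — per-animal target totals ~ truncated normal on [0, 39],
  distributed over the 13 regions by constrained random allocation with a
  per-region cap of 3.
* **Tumor growth** — exponential bioluminescence flux with a treatment rate
  multiplier for the therapy group and multiplicative lognormal noise, on a
  weekly imaging schedule.

Defaults are parameterised from the study conditions the package targets:
tumor 24 h %IA/g 6.29 +/- 4.27 and 144 h 3.80 +/- 2.18, blood 24 h
0.22 +/- 0.02 (Tz-2 radioligand), tumor mass ~= 0.016 g, the organ masses of
the packaged S-factor table, PCI group means 15.5/30.0/30.8, and group
sizes of 3-9 (biodistribution) and 6 (therapy). Organ %IA/g levels not
printed anywhere are plausible renal-clearance values chosen once.
Inter-organ and inter-time correlations within a mouse are not modelled
(draws are independent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .nuclide import LU177, NuclideProperties
from .pci import MAX_PCI, SUGARBAKER_REGIONS


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal matching a lognormal mean/SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2. ``sd = 0``
    degenerates to a point mass at ``mean``.
    """
    if not mean > 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _truncated_normal(rng: np.random.Generator, mean, sd, low, high, size) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal(rng: np.random.Generator, mean, sd, size) -> np.ndarray:
    if mean == 0:
        return np.zeros(size)
    mu, sigma = lognormal_params(mean, sd)
    if sigma == 0:
        return np.full(size, float(mean))
    return rng.lognormal(mu, sigma, size)


@dataclass(frozen=True)
class OrganSpec:
    """Mass distribution and per-time-point %IA/g distribution of one organ."""

    mass_g_mean: float
    mass_g_sd: float
    #: time_h -> (mean %IA/g, sd %IA/g)
    pct_ia_per_g: dict[float, tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.mass_g_mean > 0 or self.mass_g_sd < 0:
            raise ValueError("mass_g_mean must be > 0 and mass_g_sd >= 0")
        for t, (m, s) in self.pct_ia_per_g.items():
            if m < 0 or s < 0:
                raise ValueError(f"negative %IA/g spec at t={t}")


@dataclass(frozen=True)
class GrowthSpec:
    """Exponential bioluminescence growth model parameters."""

    baseline_flux: float = 1e7  # photons/s at treatment start
    growth_rate_per_day: float = 0.25
    treatment_rate_multiplier: float = 0.5
    lognormal_cv: float = 0.3
    days: tuple[int, ...] = (0, 7, 13, 20)
    n_per_group: int = 6


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to draw one synthetic study cohort."""

    n_mice: int = 9
    tracer: str = "Tz-2"
    organ_specs: dict[str, OrganSpec] = field(default_factory=dict)
    time_points_h: tuple[float, ...] = (24.0, 48.0, 144.0)
    injected_MBq: float = 10.0
    counting_efficiency: float = 1.0
    #: group -> (mean total PCI, sd)
    pci_group_specs: dict[str, tuple[float, float]] = field(default_factory=dict)
    pci_n_per_group: int = 6
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if not self.injected_MBq > 0:
            raise ValueError("injected_MBq must be > 0")
        if not 0 < self.counting_efficiency:
            raise ValueError("counting_efficiency must be > 0")
        for g, (m, s) in self.pci_group_specs.items():
            if not 0 <= m <= MAX_PCI:
                raise ValueError(f"PCI group {g!r}: mean must lie in [0, {MAX_PCI}]")
            if s < 0:
                raise ValueError(f"PCI group {g!r}: sd must be >= 0")


def default_study_config(seed: int = 0) -> CohortConfig:
    """The shipped study conditions (Tz-2-like pretargeted cohort).

    Tumor and blood distributions use the printed study values; the
    remaining organs carry plausible low renal-clearance levels with the
    packaged reference organ masses.
    """
    specs = {
        "Blood": OrganSpec(1.5, 0.15, {24.0: (0.22, 0.02), 48.0: (0.12, 0.02), 144.0: (0.03, 0.01)}),
        "Heart": OrganSpec(0.141, 0.014, {24.0: (0.15, 0.05), 48.0: (0.10, 0.03), 144.0: (0.04, 0.015)}),
        "Lungs": OrganSpec(0.208, 0.02, {24.0: (0.20, 0.07), 48.0: (0.13, 0.05), 144.0: (0.05, 0.02)}),
        "Liver": OrganSpec(1.333, 0.13, {24.0: (0.35, 0.10), 48.0: (0.25, 0.08), 144.0: (0.10, 0.03)}),
        "Kidneys": OrganSpec(0.362, 0.036, {24.0: (0.80, 0.20), 48.0: (0.50, 0.15), 144.0: (0.20, 0.06)}),
        "Spleen": OrganSpec(0.118, 0.012, {24.0: (0.90, 0.30), 48.0: (0.70, 0.20), 144.0: (0.40, 0.15)}),
        "Brain": OrganSpec(0.388, 0.039, {24.0: (0.02, 0.01), 48.0: (0.015, 0.008), 144.0: (0.005, 0.003)}),
        # tumor: 24 h 6.29 +/- 4.27 and 144 h 3.80 +/- 2.18 %IA/g; mass ~ 0.016 g
        "Tumors": OrganSpec(0.016, 0.003, {24.0: (6.29, 4.27), 48.0: (5.00, 3.40), 144.0: (3.80, 2.18)}),
    }
    pci = {"NaCl": (30.0, 2.3), "Tz-only": (30.8, 1.4), "PRIT": (15.5, 2.3)}
    return CohortConfig(n_mice=9, tracer="Tz-2", organ_specs=specs, pci_group_specs=pci, seed=seed)


def generate_biodist_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a gamma-counting table (raw counting CSV dialect + tracer column).

    Each synthetic mouse is longitudinal (measured at every scheduled time);
    organ masses are drawn once per mouse, %IA/g independently per time.
    The activity column is the measured harvest-time activity:
    A_meas(t) = (%IA/g / 100) * mass * A_injected * exp(-lambda_phys t) * efficiency.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nuclide: NuclideProperties = LU177
    injected_bq = config.injected_MBq * 1e6
    n = config.n_mice
    width = len(str(n))
    mice = np.array([f"{config.tracer}-m{i + 1:0{width}d}" for i in range(n)])
    frames = []
    for organ, spec in config.organ_specs.items():
        mass = _truncated_normal(rng, spec.mass_g_mean, spec.mass_g_sd, 0.0, np.inf, n)
        for t in config.time_points_h:
            if t not in spec.pct_ia_per_g:
                continue
            mean, sd = spec.pct_ia_per_g[t]
            pct = _lognormal(rng, mean, sd, n)
            a_ref = pct / 100.0 * mass * injected_bq  # decay-corrected activity
            a_meas = a_ref * math.exp(-nuclide.lambda_phys_per_h * t)
            frames.append(
                pd.DataFrame(
                    {
                        "mouse_id": mice,
                        "organ": organ,
                        "mass_g": mass,
                        "activity_Bq": a_meas * config.counting_efficiency,
                        "time_h": t,
                        "injected_MBq": config.injected_MBq,
                        "tracer": config.tracer,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["mouse_id", "organ", "time_h"], kind="mergesort").reset_index(drop=True)


def allocate_pci_target(target: int, rng: np.random.Generator, n_regions: int = 13) -> np.ndarray:
    """Distribute a total PCI over regions, each capped at 3, uniformly at random.

    Increments one unit at a time on a region drawn uniformly among those
    still below the cap, so the emitted map sums exactly to ``target``.
    """
    if not 0 <= target <= 3 * n_regions:
        raise ValueError(f"target {target} infeasible for {n_regions} regions capped at 3")
    scores = np.zeros(n_regions, dtype=int)
    for _ in range(target):
        open_regions = np.flatnonzero(scores < 3)
        scores[open_regions[rng.integers(open_regions.size)]] += 1
    return scores


def generate_pci_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw per-animal PCI maps as a long table (mouse_id, group, region_id, score).

    Per-animal target totals are truncated-normal on [0, 39] and rounded;
    the constrained allocation guarantees the map sums to the target.
    Only regions with a positive score are emitted (missing = 0).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if not config.pci_group_specs:
        raise ValueError("config.pci_group_specs is empty")
    rows = []
    for group in config.pci_group_specs:
        mean, sd = config.pci_group_specs[group]
        targets = _truncated_normal(rng, mean, sd, 0.0, float(MAX_PCI), config.pci_n_per_group)
        for i, tgt in enumerate(np.rint(targets).astype(int)):
            mouse = f"{group}-m{i + 1:02d}"
            scores = allocate_pci_target(int(tgt), rng, len(SUGARBAKER_REGIONS))
            for region, s in zip(SUGARBAKER_REGIONS, scores):
                if s > 0:
                    rows.append({"mouse_id": mouse, "group": group, "region_id": region, "score": int(s)})
            if tgt == 0:  # keep the animal visible with an explicit zero row
                rows.append({"mouse_id": mouse, "group": group, "region_id": SUGARBAKER_REGIONS[0], "score": 0})
    return pd.DataFrame(rows, columns=["mouse_id", "group", "region_id", "score"])


def generate_growth_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw bioluminescence trajectories (mouse_id, group, day, total_flux).

    flux(day) = baseline * exp(rate * g * day) * lognormal noise, with
    g = treatment_rate_multiplier for the PRIT group and 1 otherwise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    gs = config.growth
    if not (math.isfinite(gs.growth_rate_per_day) and gs.treatment_rate_multiplier >= 0):
        raise ValueError("growth rates must be finite and the multiplier >= 0")
    groups = list(config.pci_group_specs) or ["NaCl", "Tz-only", "PRIT"]
    noise_sigma = math.sqrt(math.log1p(gs.lognormal_cv**2))
    rows = []
    for group in groups:
        g = gs.treatment_rate_multiplier if group == "PRIT" else 1.0
        for i in range(gs.n_per_group):
            mouse = f"{group}-m{i + 1:02d}"
            for day in gs.days:
                flux = gs.baseline_flux * math.exp(gs.growth_rate_per_day * g * day)
                if noise_sigma > 0:
                    flux *= math.exp(rng.normal(-noise_sigma**2 / 2.0, noise_sigma))
                rows.append({"mouse_id": mouse, "group": group, "day": day, "total_flux": flux})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# config (de)serialisation for the CLI


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["organ_specs"] = {
        organ: {
            "mass_g_mean": spec.mass_g_mean,
            "mass_g_sd": spec.mass_g_sd,
            "pct_ia_per_g": {float(t): list(ms) for t, ms in spec.pct_ia_per_g.items()},
        }
        for organ, spec in config.organ_specs.items()
    }
    d["pci_group_specs"] = {g: list(ms) for g, ms in config.pci_group_specs.items()}
    d["growth"] = asdict(config.growth)
    d["growth"]["days"] = list(config.growth.days)
    d["time_points_h"] = list(config.time_points_h)
    return d


def config_from_dict(d: dict) -> CohortConfig:
    base = default_study_config()
    organ_specs = {
        organ: OrganSpec(
            mass_g_mean=float(s["mass_g_mean"]),
            mass_g_sd=float(s["mass_g_sd"]),
            pct_ia_per_g={float(t): tuple(map(float, ms)) for t, ms in s["pct_ia_per_g"].items()},
        )
        for organ, s in d.get("organ_specs", {}).items()
    } or base.organ_specs
    growth_d = d.get("growth", {})
    growth = GrowthSpec(
        baseline_flux=float(growth_d.get("baseline_flux", GrowthSpec.baseline_flux)),
        growth_rate_per_day=float(growth_d.get("growth_rate_per_day", GrowthSpec.growth_rate_per_day)),
        treatment_rate_multiplier=float(
            growth_d.get("treatment_rate_multiplier", GrowthSpec.treatment_rate_multiplier)
        ),
        lognormal_cv=float(growth_d.get("lognormal_cv", GrowthSpec.lognormal_cv)),
        days=tuple(growth_d.get("days", GrowthSpec.days)),
        n_per_group=int(growth_d.get("n_per_group", GrowthSpec.n_per_group)),
    )
    pci = {g: tuple(map(float, ms)) for g, ms in d.get("pci_group_specs", {}).items()} or base.pci_group_specs
    return CohortConfig(
        n_mice=int(d.get("n_mice", base.n_mice)),
        tracer=str(d.get("tracer", base.tracer)),
        organ_specs=organ_specs,
        time_points_h=tuple(map(float, d.get("time_points_h", base.time_points_h))),
        injected_MBq=float(d.get("injected_MBq", base.injected_MBq)),
        counting_efficiency=float(d.get("counting_efficiency", base.counting_efficiency)),
        pci_group_specs=pci,
        pci_n_per_group=int(d.get("pci_n_per_group", base.pci_n_per_group)),
        growth=growth,
        seed=int(d.get("seed", base.seed)),
    )
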