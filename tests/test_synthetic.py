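import math

import numpy as np
import pandas as pd
import pytest

from mirdose import (
    LU177,
    CohortConfig,
    MIRDDoseModel,
    OrganSpec,
    cumulated_activity,
    absorbed_dose,
    default_study_config,
    generate_biodist_cohort,
    generate_growth_cohort,
    generate_pci_cohort,
    lognormal_params,
    quantify,
    tac_from_biodist,
)
from mirdose.pci import maps_from_frame, pci_total
from mirdose.svalues import s_entries_from_table, load_s_table
from mirdose.synthetic import allocate_pci_target, config_from_dict, config_to_dict


class TestLognormalParams:
    def test_degenerate_sd_zero(self):
        mu, sigma = lognormal_params(5.0, 0.0)
        assert sigma == 0.0
        assert mu == pytest.approx(math.log(5.0))

    def test_closed_form_unit_cv(self):
        _, sigma = lognormal_params(1.0, 1.0)
        assert sigma**2 == pytest.approx(math.log(2.0), rel=1e-12)

    def test_moment_round_trip(self):
        """Reconstructed lognormal moments equal the tumor spec to machine precision."""
        mu, sigma = lognormal_params(6.29, 4.27)
        mean = math.exp(mu + sigma**2 / 2)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert mean == pytest.approx(6.29, rel=1e-12)
        assert math.sqrt(var) == pytest.approx(4.27, rel=1e-12)

    def test_invalid_mean(self):
        with pytest.raises(ValueError):
            lognormal_params(0.0, 1.0)


class TestBiodistCohort:
    def test_seed_determinism(self):
        cfg = default_study_config(seed=11)
        a = generate_biodist_cohort(cfg)
        b = generate_biodist_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)
        c = generate_biodist_cohort(cfg, seed=12)
        assert not a.equals(c)

    def test_noiseless_round_trip_recovers_means_exactly(self):
        """sd = 0 everywhere: quantification recovers the configured %IA/g."""
        specs = {
            "Tumors": OrganSpec(0.016, 0.0, {24.0: (6.29, 0.0), 144.0: (3.80, 0.0)}),
            "Blood": OrganSpec(1.5, 0.0, {24.0: (0.22, 0.0)}),
        }
        cfg = CohortConfig(n_mice=3, organ_specs=specs, seed=0)
        bd = quantify(generate_biodist_cohort(cfg), LU177, decay_correct=True)
        tumors24 = bd[(bd.organ == "Tumors") & (bd.time_h == 24.0)]
        np.testing.assert_allclose(tumors24["pct_ia_per_g"], 6.29, rtol=1e-12)
        blood = bd[bd.organ == "Blood"]
        np.testing.assert_allclose(blood["pct_ia_per_g"], 0.22, rtol=1e-12)

    def test_counting_efficiency_round_trip(self):
        specs = {"Tumors": OrganSpec(0.016, 0.0, {24.0: (6.29, 0.0)})}
        cfg = CohortConfig(n_mice=2, organ_specs=specs, counting_efficiency=0.35, seed=0)
        raw = generate_biodist_cohort(cfg)
        bd = quantify(raw, LU177, efficiency=0.35)
        np.testing.assert_allclose(bd["pct_ia_per_g"], 6.29, rtol=1e-12)

    def test_large_cohort_mean_within_3se(self):
        specs = {"Tumors": OrganSpec(0.016, 0.003, {24.0: (6.29, 4.27)})}
        cfg = CohortConfig(n_mice=2000, organ_specs=specs, seed=5)
        bd = quantify(generate_biodist_cohort(cfg), LU177)
        x = bd["pct_ia_per_g"]
        se = x.std(ddof=1) / math.sqrt(len(x))
        assert abs(x.mean() - 6.29) < 3 * se

    def test_emitted_quantities_nonnegative(self):
        df = generate_biodist_cohort(default_study_config(seed=2))
        assert (df["activity_Bq"] >= 0).all()
        assert (df["mass_g"] > 0).all()

    def test_noiseless_end_to_end_matches_hand_dose(self):
        """Noiseless cohort: every mouse's dose equals the hand-computed dose
        of the configured mean curve."""
        specs = {"Tumors": OrganSpec(0.016, 0.0, {24.0: (6.29, 0.0), 144.0: (3.80, 0.0)})}
        cfg = CohortConfig(n_mice=3, organ_specs=specs, seed=0)
        bd = quantify(generate_biodist_cohort(cfg), LU177)
        res = MIRDDoseModel(bd).fit()
        lam = LU177.lambda_phys_per_h
        f = np.array([6.29, 3.80]) * 0.016 / 100 * np.exp(-lam * np.array([24.0, 144.0]))
        lam_tail = max(np.log(f[0] / f[1]) / 120.0, lam)
        area_h = 0.5 * 24 * f[0] + 0.5 * (f[0] + f[1]) * 120 + f[1] / lam_tail
        s = s_entries_from_table(load_s_table())["Tumors"].s_gy_per_bq_s
        expected = area_h * 3600e6 * s
        row = res.dose_table.iloc[0]
        assert row.dose_gy_per_MBq == pytest.approx(expected, rel=1e-9)
        assert row.sd_gy_per_MBq == pytest.approx(0.0, abs=1e-12)


class TestPciCohort:
    def test_allocation_extremes(self):
        rng = np.random.default_rng(0)
        assert allocate_pci_target(39, rng).tolist() == [3] * 13
        assert allocate_pci_target(0, rng).sum() == 0
        with pytest.raises(ValueError):
            allocate_pci_target(40, rng)

    def test_allocation_sums_to_target_capped_at_3(self):
        rng = np.random.default_rng(1)
        for target in range(0, 40, 3):
            scores = allocate_pci_target(target, rng)
            assert scores.sum() == target
            assert scores.max() <= 3

    def test_totals_match_drawn_targets(self):
        cfg = default_study_config(seed=3)
        df = generate_pci_cohort(cfg)
        maps = maps_from_frame(df)
        totals = [pci_total(m) for m in maps]
        assert all(0 <= t <= 39 for t in totals)
        assert len(maps) == 3 * cfg.pci_n_per_group

    def test_group_mean_recovered_large_n(self):
        cfg = CohortConfig(pci_group_specs={"PRIT": (15.5, 2.3)}, pci_n_per_group=800, seed=6)
        df = generate_pci_cohort(cfg)
        totals = np.array([pci_total(m) for m in maps_from_frame(df)], float)
        se = totals.std(ddof=1) / math.sqrt(totals.size)
        assert abs(totals.mean() - 15.5) < 3 * se

    def test_infeasible_group_mean_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(pci_group_specs={"g": (45.0, 1.0)})


class TestGrowthCohort:
    def test_noise_off_multiplier_one_identical_groups(self):
        cfg = default_study_config(seed=0)
        gs = cfg.growth.__class__(lognormal_cv=0.0, treatment_rate_multiplier=1.0)
        cfg = CohortConfig(pci_group_specs=cfg.pci_group_specs, growth=gs, organ_specs=cfg.organ_specs)
        df = generate_growth_cohort(cfg)
        by_day = df.groupby("day")["total_flux"].nunique()
        assert (by_day == 1).all()

    def test_multiplier_zero_flat_treated(self):
        cfg = default_study_config(seed=0)
        gs = cfg.growth.__class__(lognormal_cv=0.0, treatment_rate_multiplier=0.0)
        cfg = CohortConfig(pci_group_specs=cfg.pci_group_specs, growth=gs, organ_specs=cfg.organ_specs)
        df = generate_growth_cohort(cfg)
        prit = df[df.group == "PRIT"]
        np.testing.assert_allclose(prit["total_flux"], gs.baseline_flux, rtol=1e-12)

    def test_rate_recovered_by_log_linear_regression(self):
        cfg = default_study_config(seed=0)
        gs = cfg.growth.__class__(lognormal_cv=0.0, growth_rate_per_day=0.25)
        cfg = CohortConfig(pci_group_specs=cfg.pci_group_specs, growth=gs, organ_specs=cfg.organ_specs)
        df = generate_growth_cohort(cfg)
        ctrl = df[df.group == "NaCl"]
        slope = np.polyfit(ctrl["day"], np.log(ctrl["total_flux"]), 1)[0]
        assert slope == pytest.approx(0.25, rel=1e-9)

    def test_treatment_effect_matches_configured_multiplier(self):
        cfg = default_study_config(seed=9)
        df = generate_growth_cohort(cfg)
        gs = cfg.growth
        prit = df[df.group == "PRIT"]
        slope = np.polyfit(prit["day"], np.log(prit["total_flux"]), 1)[0]
        expected = gs.growth_rate_per_day * gs.treatment_rate_multiplier
        # lognormal noise with CV 0.3 over 24 observations: generous sampling bound
        assert slope == pytest.approx(expected, abs=0.05)


class TestConfigSerialisation:
    def test_yaml_round_trip(self):
        cfg = default_study_config(seed=7)
        assert config_from_dict(config_to_dict(cfg)) == cfg
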