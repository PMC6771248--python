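import numpy as np
import pandas as pd
import pytest

from mirdose import (
    LU177,
    CumulatedActivity,
    DoseResult,
    MIRDDoseModel,
    SValueEntry,
    absorbed_dose,
    cohort_dose_table,
    cumulated_activity,
    load_reference_dose_table,
    load_s_table,
    quantify,
    scale_to_administration,
    tac_from_biodist,
)
from mirdose.synthetic import default_study_config, generate_biodist_cohort


def _at(organ, a_tilde):
    return CumulatedActivity(organ=organ, a_tilde_s_per_MBq=a_tilde, scheme="trapezoid_tail", lambda_eff_per_h=0.005)


def _s(organ, s):
    return SValueEntry(organ=organ, s_gy_per_bq_s=s, ref_mass_g=0.016)


class TestAbsorbedDose:
    def test_zero_cumulated_activity(self):
        assert absorbed_dose(_at("Tumors", 0.0), _s("Tumors", 1.32e-9)).dose_gy_per_MBq == 0.0

    def test_unit_product(self):
        d = absorbed_dose(_at("Tumors", 1e9), _s("Tumors", 1.32e-9))
        assert d.dose_gy_per_MBq == pytest.approx(1.32, rel=1e-12)

    def test_organ_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            absorbed_dose(_at("Liver", 1e9), _s("Tumors", 1.32e-9))

    def test_end_to_end_hand_chain(self):
        """One synthetic mouse: quantify -> TAC -> A-tilde -> dose equals the
        fully hand-chained computation."""
        lam = LU177.lambda_phys_per_h
        counting = pd.DataFrame(
            {
                "mouse_id": ["m1"] * 2,
                "organ": ["Tumors"] * 2,
                "mass_g": [0.016] * 2,
                "activity_Bq": [5.0e3 * np.exp(-lam * 24), 3.0e3 * np.exp(-lam * 144)],
                "time_h": [24.0, 144.0],
                "injected_MBq": [10.0] * 2,
            }
        )
        bd = quantify(counting, LU177)
        curve = tac_from_biodist(bd, "Tumors", LU177)
        at = cumulated_activity(curve, LU177)
        s = 1.32e-9
        dose = absorbed_dose(at, _s("Tumors", s)).dose_gy_per_MBq

        # hand computation: physical fractions are the undecayed activities / injected
        f1, f2 = 5.0e3 * np.exp(-lam * 24) / 1e7, 3.0e3 * np.exp(-lam * 144) / 1e7
        lam_tail = max(np.log(f1 / f2) / 120.0, lam)
        area_h = 0.5 * 24 * f1 + 0.5 * (f1 + f2) * 120.0 + f2 / lam_tail
        assert dose == pytest.approx(area_h * 3600 * 1e6 * s, rel=1e-9)


class TestScaleToAdministration:
    def test_identity_at_one_mbq(self):
        d = DoseResult(organ="Tumors", dose_gy_per_MBq=0.592, sd_gy_per_MBq=0.522)
        out = scale_to_administration(d, 1.0)
        assert (out.dose_gy, out.sd_gy) == (0.592, 0.522)

    @pytest.mark.parametrize(
        "tracer, printed_mean, printed_sd",
        [("Tz-2", 23.692, 20.87), ("Tz-4", 25.23, 22.38)],
    )
    def test_therapy_dose_regression(self, tracer, printed_mean, printed_sd):
        """40 MBq x the reference per-MBq tumor doses reproduces the reported
        therapy doses within 0.1%."""
        ref = load_reference_dose_table()
        row = ref[(ref.organ == "Tumors") & (ref.tracer == tracer)].iloc[0]
        d = DoseResult(
            organ="Tumors",
            dose_gy_per_MBq=row.dose_gy_per_MBq,
            sd_gy_per_MBq=row.sd_gy_per_MBq,
            tracer=tracer,
        )
        out = scale_to_administration(d, 40.0)
        assert out.dose_gy == pytest.approx(printed_mean, rel=1e-3)
        assert out.sd_gy == pytest.approx(printed_sd, rel=1e-3)

    def test_invalid_activity(self):
        with pytest.raises(ValueError):
            scale_to_administration(DoseResult("Tumors", 1.0), 0.0)


class TestCohortDoseTable:
    def _frame(self, doses, organ="Tumors"):
        return pd.DataFrame(
            {
                "mouse_id": [f"m{i}" for i in range(len(doses))],
                "organ": organ,
                "tracer": "Tz-2",
                "dose_gy_per_MBq": doses,
            }
        )

    def test_singleton_group_sd_zero(self):
        out = cohort_dose_table(self._frame([0.5]))
        assert out.loc[0, "sd_gy_per_MBq"] == 0.0
        assert out.loc[0, "n_mice"] == 1

    def test_equal_doses(self):
        out = cohort_dose_table(self._frame([0.4, 0.4]))
        assert out.loc[0, "dose_gy_per_MBq"] == pytest.approx(0.4)
        assert out.loc[0, "sd_gy_per_MBq"] == 0.0

    def test_textbook_sample_sd(self):
        out = cohort_dose_table(self._frame([1.0, 2.0, 3.0]))
        assert out.loc[0, "dose_gy_per_MBq"] == pytest.approx(2.0)
        assert out.loc[0, "sd_gy_per_MBq"] == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cohort_dose_table(self._frame([]))

    def test_organ_ordering_follows_s_table(self):
        df = pd.concat([self._frame([0.1], organ="Tumors"), self._frame([0.2], organ="Heart")])
        out = cohort_dose_table(df)
        assert list(out["organ"]) == ["Heart", "Tumors"]

    def test_permutation_invariance(self):
        df = self._frame([0.1, 0.7, 0.3, 0.5])
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(cohort_dose_table(df), cohort_dose_table(shuffled))


@pytest.fixture(scope="module")
def counting():
    return generate_biodist_cohort(default_study_config(seed=4))


class TestMIRDDoseModel:
    def test_unmatched_organs_dropped_with_record(self, counting):
        model = MIRDDoseModel.from_counting(counting)
        assert model.unmatched_organs == ["Blood"]

    def test_strict_mode_lists_unmatched(self, counting):
        with pytest.raises(ValueError, match="Blood"):
            MIRDDoseModel.from_counting(counting, strict=True)

    def test_fit_produces_all_reference_organs(self, counting):
        res = MIRDDoseModel.from_counting(counting).fit()
        assert list(res.dose_table["organ"]) == list(load_s_table()["organ"])
        assert (res.dose_table["n_mice"] == 9).all()
        assert (res.dose_table["dose_gy_per_MBq"] > 0).all()

    def test_per_mouse_fit_permutation_invariant(self, counting):
        res = MIRDDoseModel.from_counting(counting).fit()
        shuffled = counting.sample(frac=1.0, random_state=0).reset_index(drop=True)
        res2 = MIRDDoseModel.from_counting(shuffled).fit()
        pd.testing.assert_frame_equal(res.dose_table, res2.dose_table)

    def test_mean_curve_path(self, counting):
        res = MIRDDoseModel.from_counting(counting).fit(per_mouse=False)
        assert res.dose_table["sd_gy_per_MBq"].isna().all()
        per_mouse = MIRDDoseModel.from_counting(counting).fit()
        # both paths agree to within the cohort spread
        merged = res.dose_table.merge(per_mouse.dose_table, on=["organ", "tracer"], suffixes=("_mc", "_pm"))
        spread = merged["sd_gy_per_MBq_pm"].where(merged["sd_gy_per_MBq_pm"] > 0, merged["dose_gy_per_MBq_pm"])
        assert (abs(merged["dose_gy_per_MBq_mc"] - merged["dose_gy_per_MBq_pm"]) < 2 * spread).all()

    def test_scale_to_and_summary(self, counting):
        res = MIRDDoseModel.from_counting(counting).fit()
        scaled = res.scale_to(40.0)
        tumor = scaled[scaled.organ == "Tumors"].iloc[0]
        base = res.dose_table[res.dose_table.organ == "Tumors"].iloc[0]
        assert tumor.dose_gy == pytest.approx(40 * base.dose_gy_per_MBq)
        text = res.summary(administered_MBq=40.0)
        assert "Tumors" in text and "Lu-177" in text and "Blood" in text
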