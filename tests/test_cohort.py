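"""Cohort I/O, lesion aggregation, imputation and cohort-level fitting."""

import math

import numpy as np
import pandas as pd
import pytest

from oligogrowth import (
    CohortConfig,
    CohortValidationError,
    ImputationPolicy,
    aggregate_lesions,
    build_cohort,
    compute_cohort_growth_rates,
    generate_cohort,
    impute_pretreatment,
    load_cohort,
)
from oligogrowth.growth_models import InvalidInputError


class TestLoad:
    def test_well_formed_fixture_round_trip(self, tiny_cohort_files):
        cohort = load_cohort(*tiny_cohort_files)
        assert cohort.n_patients == 3
        assert set(cohort.timelines) == {"A", "B", "C"}
        assert cohort.timelines["A"].total_volumes["TP0"] == pytest.approx(28.4)
        assert cohort.timelines["B"].de_novo

    def test_zero_volume_names_the_row(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        lesions.loc[1, "volume_cc"] = 0.0
        with pytest.raises(CohortValidationError, match="row 3.*non-positive"):
            build_cohort(lesions, patients)

    def test_missing_tp0_names_the_patient(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        lesions = lesions[~((lesions.patient_id == "B") &
                            (lesions.timepoint == "TP0"))]
        with pytest.raises(CohortValidationError, match="patient B.*no TP0"):
            build_cohort(lesions.reset_index(drop=True), patients)

    def test_duplicate_lesion_key_rejected(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        lesions = pd.concat([lesions, lesions.iloc[[0]]], ignore_index=True)
        with pytest.raises(CohortValidationError, match="duplicate lesion key"):
            build_cohort(lesions, patients)

    def test_unknown_timepoint_rejected(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        lesions.loc[0, "timepoint"] = "TP-2"
        with pytest.raises(CohortValidationError, match="unknown timepoint"):
            build_cohort(lesions, patients)

    def test_missing_column_rejected(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        with pytest.raises(CohortValidationError, match="missing required column"):
            build_cohort(lesions.drop(columns=["volume_cc"]), patients)

    def test_all_violations_reported_at_once(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        lesions.loc[0, "volume_cc"] = -1.0
        lesions.loc[3, "timepoint"] = "bogus"
        patients.loc[0, "best_response"] = "XX"
        with pytest.raises(CohortValidationError) as exc:
            build_cohort(lesions, patients)
        assert len(exc.value.errors) >= 3

    def test_pfs_exceeding_os_rejected(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        patients.loc[0, "pfs_days"] = 999.0
        with pytest.raises(CohortValidationError, match="pfs_days > os_days"):
            build_cohort(lesions, patients)

    def test_implausible_interval_warns_but_loads(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        patients.loc[0, "tp_minus1_offset_days"] = -500.0
        with pytest.warns(UserWarning, match="outside the typical"):
            cohort = build_cohort(lesions, patients)
        assert cohort.n_patients == 3


class TestAggregate:
    @pytest.mark.parametrize(
        "volumes, expected",
        [([10.0, 18.4], 28.4), ([0.4], 0.4), ([1.0] * 73, 73.0)],
    )
    def test_exact_sum(self, volumes, expected):
        df = pd.DataFrame({
            "patient_id": "X", "timepoint": "TP0",
            "lesion_id": [f"L{i}" for i in range(len(volumes))],
            "volume_cc": volumes, "site": "lung",
        })
        assert aggregate_lesions(df, "TP0") == pytest.approx(expected, abs=0)

    def test_absent_timepoint_signals_none(self):
        df = pd.DataFrame({"patient_id": ["X"], "timepoint": ["TP0"],
                           "lesion_id": ["L0"], "volume_cc": [1.0],
                           "site": ["lung"]})
        assert aggregate_lesions(df, "TP+2") is None


class TestImputation:
    def test_de_novo_gets_default_policy(self, cohort_default):
        tl = next(t for t in cohort_default.timelines.values() if t.de_novo)
        out = impute_pretreatment(tl)
        assert out.offsets["TP-1"] == -90.0
        assert out.total_volumes["TP-1"] == 0.1
        assert "TP-1" in out.imputed and out.imputation_applied

    def test_measured_patient_unchanged(self, cohort_default):
        tl = next(t for t in cohort_default.timelines.values() if not t.de_novo)
        out = impute_pretreatment(tl)
        assert out is tl
        assert not out.imputation_applied

    def test_custom_policy(self, cohort_default):
        tl = next(t for t in cohort_default.timelines.values() if t.de_novo)
        out = impute_pretreatment(tl, ImputationPolicy(0.01, -150.0))
        assert out.offsets["TP-1"] == -150.0
        assert out.total_volumes["TP-1"] == 0.01

    def test_idempotent(self, cohort_default):
        tl = next(t for t in cohort_default.timelines.values() if t.de_novo)
        once = impute_pretreatment(tl)
        twice = impute_pretreatment(once)
        assert twice == once

    def test_alpha_increases_with_smaller_imputed_volume_and_interval(
        self, cohort_default
    ):
        tl = next(t for t in cohort_default.timelines.values() if t.de_novo)
        v0 = tl.total_volumes["TP0"]

        def alpha(policy):
            out = impute_pretreatment(tl, policy)
            (t0, vp, _), (_, vb, _) = out.pretreatment_observations()
            return math.log(vb / vp) / -t0

        base = alpha(ImputationPolicy(0.1, -90.0))
        assert alpha(ImputationPolicy(0.01, -90.0)) > base
        if v0 > 0.1:  # shorter interval amplifies only a positive numerator
            assert alpha(ImputationPolicy(0.1, -30.0)) > base

    def test_policy_above_baseline_volume_warns(self, tiny_cohort_frames):
        lesions, patients = tiny_cohort_frames
        cohort = build_cohort(lesions, patients)
        tl = cohort.timelines["B"]
        with pytest.warns(UserWarning, match="minimal detectable"):
            impute_pretreatment(tl, ImputationPolicy(50.0, -90.0))

    def test_invalid_policy_rejected(self):
        with pytest.raises(InvalidInputError):
            ImputationPolicy(volume=0.0)
        with pytest.raises(InvalidInputError):
            ImputationPolicy(offset=10.0)


class TestCohortGrowthRates:
    def test_single_patient_closed_form(self, tiny_cohort_files):
        cohort = load_cohort(*tiny_cohort_files)
        fits = compute_cohort_growth_rates(cohort).set_index("patient_id")
        # A: measured 2.0 -> 28.4 cc over 90 d
        assert fits.loc["A", "alpha"] == pytest.approx(
            math.log(28.4 / 2.0) / 90.0, rel=1e-12
        )
        # B: de-novo, imputed 0.1 cc at -90 d
        assert fits.loc["B", "alpha"] == pytest.approx(
            math.log(28.4 / 0.1) / 90.0, rel=1e-12
        )
        assert bool(fits.loc["B", "imputed"]) and not bool(fits.loc["A", "imputed"])

    def test_on_treatment_scans_never_enter_alpha(self, tiny_cohort_files):
        cohort = load_cohort(*tiny_cohort_files)
        fits = compute_cohort_growth_rates(cohort).set_index("patient_id")
        # C has a shrinking TP+1 scan; alpha uses only TP-1/TP0 (flat at 5 cc)
        assert fits.loc["C", "alpha"] == pytest.approx(0.0, abs=1e-15)
        assert fits.loc["C", "n_obs"] == 2

    def test_noise_free_recovery_exact(self):
        sc = generate_cohort(CohortConfig(seed=3, noise_sigma=0.0))
        cohort = sc.to_cohort()
        fits = compute_cohort_growth_rates(cohort).set_index("patient_id")
        truth = sc.truth.set_index("patient_id")
        measured = cohort.patients.loc[cohort.patients["de_novo"] == 0, "patient_id"]
        assert len(measured) > 10
        np.testing.assert_allclose(
            fits.loc[measured, "alpha"], truth.loc[measured, "alpha_true"],
            rtol=0, atol=1e-10,
        )

    def test_save_load_round_trip_preserves_fits(self, tmp_path, synthetic_default):
        paths = synthetic_default.write(tmp_path)
        reloaded = load_cohort(paths["lesions"], paths["patients"])
        direct = compute_cohort_growth_rates(synthetic_default.to_cohort())
        via_disk = compute_cohort_growth_rates(reloaded)
        pd.testing.assert_frame_equal(direct, via_disk)
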