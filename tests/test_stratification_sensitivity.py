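"""Quartile stratification, subgrouping and the imputation sensitivity grid."""

import math

import numpy as np
import pandas as pd
import pytest

from oligogrowth import (
    CohortConfig,
    ImputationPolicy,
    assign_groups,
    compute_cohort_growth_rates,
    generate_cohort,
    impute_pretreatment,
    pairwise_quartile_comparisons,
    quartile_thresholds,
    run_sensitivity_grid,
    subgroup_by_met_count,
)
from oligogrowth.endpoints_survival import logrank_test
from oligogrowth.growth_models import InvalidInputError


class TestQuartiles:
    def test_linear_interpolation_convention(self):
        q1, q2, q3 = quartile_thresholds([1, 2, 3, 4, 5, 6, 7, 8])
        assert q3 == pytest.approx(6.25)
        assert (q1, q2, q3) == pytest.approx(
            tuple(np.quantile(np.arange(1, 9), [0.25, 0.5, 0.75]))
        )

    def test_constant_input(self):
        assert quartile_thresholds([3.0] * 6) == (3.0, 3.0, 3.0)

    def test_lower_quartile_of_skewed_input(self):
        q1, _, _ = quartile_thresholds([0.0, 0.0, 0.0, 100.0])
        assert q1 == 0.0

    def test_too_few_values_rejected(self):
        with pytest.raises(InvalidInputError):
            quartile_thresholds([1.0, 2.0, 3.0])


class TestGroups:
    def test_boundary_alpha_is_slow(self):
        strata = assign_groups(["a", "b", "c", "d"],
                               [0.01, 0.02, 0.076, 0.0761], threshold=0.076)
        by_id = strata.set_index("patient_id")["group"]
        assert by_id["c"] == "slow"  # exactly at the threshold
        assert by_id["d"] == "fast"  # strict exceedance

    def test_eight_distinct_alphas_split_six_two(self):
        alphas = [1, 2, 3, 4, 5, 6, 7, 8]
        strata = assign_groups(list("abcdefgh"), alphas)
        assert (strata["group"] == "slow").sum() == 6
        assert (strata["group"] == "fast").sum() == 2

    def test_fast_group_size_at_n86_distinct(self):
        rng = np.random.default_rng(5)
        alphas = rng.normal(0.05, 0.03, 86)
        assert np.unique(alphas).size == 86
        strata = assign_groups([f"P{i}" for i in range(86)], alphas)
        assert (strata["group"] == "fast").sum() in (21, 22)
        # upper-quartile threshold makes fast coincide with Q4
        assert set(strata.loc[strata["group"] == "fast", "quartile"]) == {"Q4"}

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(9)
        alphas = rng.normal(0.0, 1.0, 37)
        strata = assign_groups([str(i) for i in range(37)], alphas)
        assert strata["quartile"].isin(["Q1", "Q2", "Q3", "Q4"]).all()
        assert strata["group"].isin(["slow", "fast"]).all()
        sizes = strata["group"].value_counts()
        assert sizes.sum() == 37


class TestSubgroups:
    @pytest.mark.parametrize("n_met, expected",
                             [(5, "oligo"), (6, "poly"), (73, "poly"), (1, "oligo")])
    def test_oligo_cutoff_membership(self, cohort_default, n_met, expected):
        groups = subgroup_by_met_count(cohort_default)
        counts = cohort_default.met_counts()
        matching = counts.index[counts == n_met]
        for pid in matching:
            assert pid in groups[expected]

    def test_partition(self, cohort_default):
        groups = subgroup_by_met_count(cohort_default)
        all_ids = set(groups["oligo"]) | set(groups["poly"])
        assert all_ids == set(cohort_default.patient_ids)
        assert not set(groups["oligo"]) & set(groups["poly"])


class TestPairwiseComparisons:
    def test_structure_one_patient_per_quartile(self, cohort_default):
        patients = cohort_default.patients.iloc[:4].copy()
        strata = assign_groups(patients["patient_id"], [0.01, 0.02, 0.05, 0.2])
        table = pairwise_quartile_comparisons(patients, strata, "OS")
        assert len(table) == 7  # 6 quartile pairs + Q4 vs pooled Q1-3
        pair_rows = table[table["comparison"] != "Q1-3_vs_Q4"]
        assert (pair_rows[["n_a", "n_b"]] == 1).all().all()

    def test_fast_quartile_separates_more_than_neighbours(self):
        """With hazard increasing in alpha, Q4-vs-Q1 separates survival more
        often than Q2-vs-Q1 across seeded replicates."""
        wins = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng([77, seed])
            n = 86
            alphas = np.sort(rng.lognormal(math.log(0.0471), 1.0, n))
            rate = (1 / 1500) * np.exp(15.0 * alphas)
            t = rng.exponential(1 / rate)
            c = rng.uniform(365, 1765, n)
            times, events = np.minimum(t, c), t <= c
            strata = assign_groups([str(i) for i in range(n)], alphas)
            q = strata["quartile"].to_numpy()
            p41 = logrank_test(times[q == "Q4"], events[q == "Q4"],
                               times[q == "Q1"], events[q == "Q1"]).p_value
            p21 = logrank_test(times[q == "Q2"], events[q == "Q2"],
                               times[q == "Q1"], events[q == "Q1"]).p_value
            wins += p41 < p21
        assert wins / n_rep >= 0.90

    def test_null_pvalues_uniform(self):
        """Identical survival generation in all quartiles gives uniform
        Q4-vs-Q1 p-values (KS test not rejected at 0.01)."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(500):
            rng = np.random.default_rng([78, seed])
            n = 44
            alphas = rng.lognormal(math.log(0.0471), 1.0, n)
            t = rng.exponential(500.0, n)  # hazard independent of alpha
            c = rng.uniform(365, 1765, n)
            times, events = np.minimum(t, c), t <= c
            strata = assign_groups([str(i) for i in range(n)], alphas)
            q = strata["quartile"].to_numpy()
            pvals.append(logrank_test(times[q == "Q4"], events[q == "Q4"],
                                      times[q == "Q1"], events[q == "Q1"]).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSensitivityGrid:
    def test_default_axes_shape(self, cohort_default):
        grid = run_sensitivity_grid(cohort_default)
        assert len(grid.table) == 3 * 5 * 3
        assert grid.table["p_value"].dropna().between(0, 1).all()
        for ep in ("OS", "PFS", "PFS2"):
            assert (grid.table["endpoint"] == ep).sum() == 15

    def test_no_de_novo_cohort_gives_constant_grid(self):
        sc = generate_cohort(CohortConfig(seed=4, de_novo_fraction=0.0))
        grid = run_sensitivity_grid(sc.to_cohort())
        for ep in ("OS", "PFS", "PFS2"):
            ps = grid.table.loc[grid.table["endpoint"] == ep, "p_value"]
            assert ps.nunique() == 1

    def test_cell_alpha_monotone_in_imputation_assumptions(self, cohort_default):
        """Per de-novo patient: alpha strictly decreasing in imputed volume;
        in |offset|, |alpha| shrinks toward 0 (sign fixed by V0 vs volume)."""
        tl = next(t for t in cohort_default.timelines.values() if t.de_novo)
        v0 = tl.total_volumes["TP0"]

        def cell_alpha(vol, off):
            out = impute_pretreatment(tl, ImputationPolicy(vol, off))
            (t0, vp, _), (_, vb, _) = out.pretreatment_observations()
            return math.log(vb / vp) / -t0

        for off in (-150.0, -90.0, -30.0):
            alphas = [cell_alpha(v, off) for v in (0.01, 0.1, 1.0)]
            assert alphas[0] > alphas[1] > alphas[2]
        for vol in (0.01, 0.1, 1.0):
            a_by_offset = [cell_alpha(vol, o) for o in (-150.0, -90.0, -30.0)]
            if v0 > vol:  # positive numerator: shorter interval => faster rate
                assert a_by_offset[0] < a_by_offset[1] < a_by_offset[2]
            elif v0 < vol:
                assert a_by_offset[0] > a_by_offset[1] > a_by_offset[2]

    def test_measured_alpha_constant_across_cells(self, cohort_default):
        base = compute_cohort_growth_rates(cohort_default).set_index("patient_id")
        measured = base.index[~base["imputed"]]
        for policy in (ImputationPolicy(0.01, -30.0), ImputationPolicy(1.0, -150.0)):
            fits = compute_cohort_growth_rates(
                cohort_default, policy=policy).set_index("patient_id")
            pd.testing.assert_series_equal(fits.loc[measured, "alpha"],
                                           base.loc[measured, "alpha"])

    def test_grid_is_deterministic(self, cohort_default):
        g1 = run_sensitivity_grid(cohort_default)
        g2 = run_sensitivity_grid(cohort_default)
        pd.testing.assert_frame_equal(g1.table, g2.table)
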