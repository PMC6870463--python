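"""Per-gene screens: detection filter, max/min ratios, Venn, dosage groups,
Z sex ratios, LPS response."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sibxpress import SimulationConfig, simulate_cohort
from sibxpress.expression import (
    ExpressionError,
    classify_dosage_groups,
    extreme_variation_flags,
    extreme_variation_sets,
    filter_expressed,
    lps_response,
    max_min_ratio,
    null_candidate_screen,
    sex_ratio_analysis,
)
from conftest import make_expression


class TestFilterExpressed:
    def test_boundary_below_removed_at_equality_retained(self):
        m = make_expression(np.array([[9.99, 9.99], [10.0, 0.0], [50.0, 1.0]]))
        kept = filter_expressed(m)
        assert list(kept) == ["g1", "g2"]

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(8)
        vals = rng.gamma(2.0, 8.0, size=(100, 12))
        m = make_expression(vals)
        kept = set(filter_expressed(m))
        expected = {f"g{i}" for i in range(100) if vals[i].max() >= 10.0}
        assert kept == expected


class TestMaxMinRatio:
    def test_constant_gene_ratio_one(self):
        m = make_expression(np.full((1, 5), 42.0))
        assert max_min_ratio(m).loc["g0", "ratio"] == 1.0

    def test_avidin_style_spread(self):
        # a gene ranging 5 to 121 TPM gives a 24.2-fold difference
        m = make_expression(np.array([[5.0, 33.0, 121.0]]))
        assert max_min_ratio(m).loc["g0", "ratio"] == pytest.approx(24.2)

    def test_zero_minimum_reports_infinite_with_extremes(self):
        m = make_expression(np.array([[0.0, 30.0]]))
        row = max_min_ratio(m).loc["g0"]
        assert np.isinf(row["ratio"]) and row["max"] == 30.0 and row["min"] == 0.0

    def test_housekeeping_regime_matches_order_statistics_oracle(self):
        # invariant genes with log-normal noise: the median max/min ratio
        # equals 2**(sd * median range of n standard normals), estimated
        # here by direct Monte Carlo on the order statistics
        n_samples, sd = 17, 0.1
        rng = np.random.default_rng(42)
        vals = 50.0 * 2 ** rng.normal(0, sd, size=(300, n_samples))
        m = make_expression(vals)
        observed = float(np.median(max_min_ratio(m)["ratio"]))

        oracle_rng = np.random.default_rng(7)
        draws = oracle_rng.standard_normal((20_000, n_samples))
        med_range = np.median(draws.max(axis=1) - draws.min(axis=1))
        expected = 2 ** (sd * med_range)
        assert observed == pytest.approx(expected, abs=0.05)
        assert 1.2 < observed < 1.6  # the reference-gene regime


class TestExtremeVariationSets:
    @staticmethod
    def _pair(cv, lv):
        return make_expression(cv), make_expression(lv)

    def test_identical_matrices_all_shared(self):
        vals = np.array([[25.0, 0.5, 30.0, 40.0], [5.0, 5.0, 5.0, 5.0]])
        c, l = self._pair(vals, vals)
        venn = extreme_variation_sets(c, l)
        assert venn.shared == {"g0"} and not venn.control_only and not venn.lps_only

    def test_disjoint_constructed_qualifiers(self):
        base = np.full((20, 4), 10.0)
        cv, lv = base.copy(), base.copy()
        cv[:10, 0], cv[:10, 1] = 0.0, 25.0     # genes 0-9 qualify in control
        lv[10:, 0], lv[10:, 1] = 0.0, 25.0     # genes 10-19 qualify in LPS
        c, l = self._pair(cv, lv)
        venn = extreme_variation_sets(c, l)
        assert venn.counts() == {"control_only": 10, "lps_only": 10,
                                 "shared": 0, "total": 20}
        assert venn.percentages()["control_only"] == 50.0

    def test_random_fixture_matches_set_algebra(self):
        rng = np.random.default_rng(5)
        cv = rng.gamma(1.0, 15.0, size=(60, 6))
        lv = rng.gamma(1.0, 15.0, size=(60, 6))
        c, l = self._pair(cv, lv)
        venn = extreme_variation_sets(c, l)
        cq = {f"g{i}" for i in range(60) if cv[i].max() > 20 and cv[i].min() < 1}
        lq = {f"g{i}" for i in range(60) if lv[i].max() > 20 and lv[i].min() < 1}
        assert venn.control_only == cq - lq
        assert venn.lps_only == lq - cq
        assert venn.shared == cq & lq

    def test_mismatched_universe_rejected(self):
        c = make_expression(np.ones((3, 4)))
        l = make_expression(np.ones((2, 4)))
        with pytest.raises(ExpressionError, match="universes differ"):
            extreme_variation_sets(c, l)

    def test_extreme_subset_of_expressed(self, default_cohort):
        ctrl = default_cohort.expression.stratum("control")
        extreme = set(ctrl.gene_ids[extreme_variation_flags(ctrl)])
        expressed = set(filter_expressed(ctrl))
        assert extreme <= expressed  # max > 20 implies max >= 10


class TestDosageGroups:
    def test_exact_additive_classes_recovered(self):
        vals = pd.Series([0.0, 0.0, 5.0, 5.0, 5.0, 10.0, 10.0],
                         index=[f"b{i}" for i in range(7)])
        dg = classify_dosage_groups(vals)
        assert dg.k == 3
        assert dg.group_means == [0.0, 5.0, 10.0]
        assert dg.additivity_score == 0.0
        assert dg.candidate_null
        assert set(dg.assignments[dg.assignments == 0].index) == {"b0", "b1"}

    def test_all_equal_single_group(self):
        dg = classify_dosage_groups(pd.Series([7.0] * 6))
        assert dg.k == 1 and not dg.candidate_null

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            copies = rng.integers(0, 3, size=9)
            vals = 6.0 * copies * 2 ** rng.normal(0, 0.2, 9)
            s = pd.Series(vals)
            dg = classify_dosage_groups(s)

            # brute-force the penalised score over all contiguous partitions
            logv = np.sort(np.log2(vals + 0.5))
            n = len(logv)
            best = (np.inf, None)
            for k in (1, 2, 3):
                for bounds in combinations(range(1, n), k - 1):
                    edges = (0, *bounds, n)
                    sse = sum(((logv[a:b] - logv[a:b].mean()) ** 2).sum()
                              for a, b in zip(edges, edges[1:]))
                    score = n * np.log(sse / n + 1e-12) + k * np.log(n)
                    if score < best[0] - 1e-12:
                        best = (score, k)
            assert dg.k == best[1]

    def test_continuous_gradient_not_called_null(self):
        # a smooth contamination-like gradient (log-uniform spread, the scale
        # the classifier works on) must not yield a null call
        vals = pd.Series(np.geomspace(0.5, 40.0, 12))
        dg = classify_dosage_groups(vals)
        assert not dg.candidate_null

    def test_too_few_samples_refused(self):
        with pytest.raises(ExpressionError, match=">= 4"):
            classify_dosage_groups(pd.Series([1.0, 2.0, 3.0]))


class TestNullCandidateScreen:
    def test_screen_recovers_planted_nulls(self, default_cohort):
        c = default_cohort
        ctrl = c.expression.stratum("control")
        screen = null_candidate_screen(ctrl)
        called = set(screen.index[screen["candidate_null"]])
        assert called  # the default design plants recoverable nulls
        assert called <= set(c.truth.null_genes)

    def test_w_genes_not_called(self, default_cohort):
        ctrl = default_cohort.expression.stratum("control")
        screen = null_candidate_screen(ctrl)
        w_genes = set(ctrl.gene_ids[(ctrl.genes["chromosome"] == "chrW").to_numpy()])
        assert not (set(screen.index) & w_genes)


class TestSexRatio:
    @staticmethod
    def _zw_matrix(male_vals, female_vals, n_genes=5):
        vals = np.column_stack([male_vals] * 3 + [female_vals] * 3)
        vals = np.tile(vals, (n_genes, 1))
        return make_expression(
            vals, sexes=["M"] * 3 + ["F"] * 3, chroms=["chrZ"] * n_genes)

    def test_closed_form_no_compensation(self):
        m = self._zw_matrix(20.0, 10.0)
        res = sex_ratio_analysis(m, "Z", bootstrap_reps=50)
        assert res.median_ratio == pytest.approx(2.0)
        assert (res.table["mf_ratio"] == 2.0).all()

    def test_compensated_flag_discriminates(self):
        # genes with a true M/F ratio of 1 are flagged far more often than
        # genes with a true twofold male excess, which are never flagged
        rng = np.random.default_rng(2)
        base = 2 ** rng.normal(0, 0.15, size=(20, 16))
        vals = 30.0 * base
        vals[10:, :8] *= 2.0  # genes 10-19: true ratio 2
        m = make_expression(vals, sexes=["M"] * 8 + ["F"] * 8,
                            chroms=["chrZ"] * 20)
        res = sex_ratio_analysis(m, "Z", bootstrap_reps=1000, seed=1)
        flagged = res.table["compensated"]
        assert flagged.iloc[:10].mean() > 0.5
        assert flagged.iloc[10:].sum() == 0

    def test_recovery_of_partial_compensation(self):
        cfg = SimulationConfig(seed=6, dosage_compensation_factor=4 / 3,
                               noise_sd_log2=0.2)
        c = simulate_cohort(cfg)
        res = sex_ratio_analysis(c.expression.stratum("control"), "Z", seed=6)
        assert res.median_ratio == pytest.approx(1.5, abs=0.1)

    def test_monotone_in_compensation_factor(self):
        medians = []
        for f in (1.0, 4 / 3, 2.0):
            c = simulate_cohort(SimulationConfig(seed=7, noise_sd_log2=0.1,
                                                 dosage_compensation_factor=f))
            medians.append(sex_ratio_analysis(
                c.expression.stratum("control"), "Z", seed=7).median_ratio)
        assert medians[0] > medians[1] > medians[2]

    def test_single_sex_refused(self):
        m = make_expression(np.ones((2, 4)) * 20, sexes=["M"] * 4,
                            chroms=["chrZ"] * 2)
        with pytest.raises(ExpressionError, match="each sex"):
            sex_ratio_analysis(m, "Z")


class TestLpsResponse:
    @staticmethod
    def _paired(control_vals, lps_vals):
        n = control_vals.shape[1]
        vals = np.column_stack([control_vals, lps_vals])
        return make_expression(
            vals,
            treatments=["control"] * n + ["LPS"] * n,
            individuals=[f"bird{i}" for i in range(n)] * 2,
        )

    def test_exact_twofold_not_induced(self):
        # (mean_lps + 0.5) / (mean_control + 0.5) == 2 exactly -> excluded
        m = self._paired(np.full((1, 3), 15.0), np.full((1, 3), 30.5))
        res = lps_response(m)
        assert res.table.loc["g0", "fold"] == 2.0
        assert res.n_induced == 0

    def test_identical_strata_no_calls(self):
        vals = np.random.default_rng(1).gamma(3, 10, size=(30, 4))
        m = self._paired(vals, vals)
        res = lps_response(m)
        assert res.n_induced == 0 and res.n_repressed == 0

    def test_planted_counts_recovered_exactly(self):
        cfg = SimulationConfig(seed=2, noise_sd_log2=0.0, trans_module_size=0,
                               mesenchyme_module_size=0)
        c = simulate_cohort(cfg)
        res = lps_response(c.expression)
        assert res.n_induced == cfg.n_lps_induced
        assert res.n_repressed == cfg.n_lps_repressed

    def test_unpaired_samples_warned_and_excluded(self):
        m = self._paired(np.full((2, 3), 20.0), np.full((2, 3), 20.0))
        m2 = make_expression(
            m.values.to_numpy()[:, :5],
            treatments=["control"] * 3 + ["LPS"] * 2,
            individuals=["bird0", "bird1", "bird2", "bird0", "bird1"],
        )
        with pytest.warns(UserWarning, match="unpaired"):
            res = lps_response(m2)
        assert res.n_pairs == 2


class TestOrderInvariance:
    def test_statistics_invariant_to_sample_and_gene_order(self):
        rng = np.random.default_rng(10)
        vals = rng.gamma(2, 10, size=(30, 8))
        m = make_expression(vals)
        perm_g = rng.permutation(30)
        perm_s = rng.permutation(8)
        m2 = make_expression(vals[np.ix_(perm_g, perm_s)])
        a = max_min_ratio(m)
        b = max_min_ratio(m2)
        # gene g{i} of m2 carries the values of gene g{perm_g[i]} of m
        for i in range(30):
            np.testing.assert_allclose(b.iloc[i], a.iloc[perm_g[i]])
        kept_m = {f"g{i}" for i, g in enumerate(perm_g)
                  if f"g{g}" in set(filter_expressed(m))}
        assert set(filter_expressed(m2)) == kept_m
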