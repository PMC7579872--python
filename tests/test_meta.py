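"""Pooling, heterogeneity statistics, model selection, significance filter.

Brute-force oracles (direct sums, statsmodels' independent implementation)
back the closed-form estimators; simulation checks the null distribution
of Q and the type-I error of the significance filter.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import lfcmeta as lm
from lfcmeta.meta import meta_analyze, meta_analyze_gene


def _effects_frame(lfc, variance, gene="g"):
    return pd.DataFrame(
        {
            "gene_id": gene,
            "study_id": [f"S{i}" for i in range(len(lfc))],
            "lfc": lfc,
            "variance": variance,
        }
    )


class TestCochranQ:
    def test_identical_effects_give_zero(self):
        q, df = lm.cochran_q([1.3, 1.3, 1.3], [0.5, 0.2, 0.1])
        assert q == pytest.approx(0.0)
        assert df == 2

    def test_two_study_hand_example(self):
        q, df = lm.cochran_q([0.0, 2.0], [1.0, 1.0])
        assert q == pytest.approx(2.0)
        assert df == 1

    def test_single_study_is_an_error(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            lm.cochran_q([1.0], [1.0])

    def test_null_distribution_is_chi_square(self):
        """With no heterogeneity and large groups, Q ~ chi2(k-1)."""
        cohorts = [
            lm.StudyMeta(geo_id=f"S{i}", study_name=f"s{i}", n_control=100,
                         n_case=100, country="USA", study_age=1.0)
            for i in range(8)
        ]
        cfg = lm.SyntheticConfig(n_genes=500, tau2=0.0, seed=17, studies=cohorts)
        results = meta_analyze(lm.effects_table(lm.generate_studies(cfg)))
        ks = stats.kstest(results["Q"], stats.chi2(7).cdf)
        assert ks.pvalue > 0.01


class TestIsq:
    @pytest.mark.parametrize(
        "q, df, expected",
        [(20.0, 10, 50.0), (5.0, 10, 0.0), (0.0, 1, 0.0), (10.0, 10, 0.0)],
    )
    def test_formula_and_clamp(self, q, df, expected):
        assert lm.isq(q, df) == pytest.approx(expected)

    def test_round_trip_through_printed_heterogeneity(self):
        # Q recovered by inverting the I^2 formula at 45.86% with df = 10
        q = 10.0 / (1.0 - 0.4586)
        assert lm.isq(q, 10) == pytest.approx(45.86, abs=1e-9)

    @given(
        q=st.floats(0.0, 1e6, allow_nan=False),
        df=st.integers(1, 50),
    )
    def test_always_in_unit_interval_of_percent(self, q, df):
        val = lm.isq(q, df)
        assert 0.0 <= val < 100.0


class TestQPvalue:
    def test_zero_statistic_gives_certainty(self):
        assert lm.q_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_printed_heterogeneity_p(self):
        q = 10.0 / (1.0 - 0.4586)
        assert lm.q_pvalue(q, 10) == pytest.approx(0.048, abs=5e-4)

    def test_monotone_decreasing_in_q(self):
        assert lm.q_pvalue(3.0, 4) > lm.q_pvalue(8.0, 4) > lm.q_pvalue(20.0, 4)


class TestSelectModel:
    @pytest.mark.parametrize(
        "q, df, expected",
        [(10.0, 10, "fixed"), (9.99, 10, "fixed"), (18.47, 10, "random")],
    )
    def test_rule_is_fixed_iff_q_at_most_df(self, q, df, expected):
        assert lm.select_model(q, df) == expected


class TestPooling:
    def test_single_study_is_identity(self):
        pooled, se = lm.pool_fixed([1.7], [0.25])
        assert pooled == pytest.approx(1.7)
        assert se == pytest.approx(0.5)

    def test_symmetric_two_study_average(self):
        pooled, se = lm.pool_fixed([1.0, 3.0], [1.0, 1.0])
        assert pooled == pytest.approx(2.0)
        assert se == pytest.approx(np.sqrt(0.5))

    def test_random_with_zero_tau2_reduces_to_fixed(self, rng):
        lfc, var = rng.normal(size=6), rng.uniform(0.1, 2.0, 6)
        assert lm.pool_random(lfc, var, 0.0) == pytest.approx(lm.pool_fixed(lfc, var))

    def test_huge_tau2_approaches_unweighted_mean(self, rng):
        lfc, var = rng.normal(size=6), rng.uniform(0.1, 2.0, 6)
        pooled, _ = lm.pool_random(lfc, var, 1e9)
        assert pooled == pytest.approx(lfc.mean(), abs=1e-6)

    def test_brute_force_direct_sum_oracle(self, rng):
        for _ in range(100):
            k = rng.integers(2, 8)
            lfc = rng.normal(size=k)
            var = rng.uniform(0.05, 3.0, k)
            tau2 = rng.uniform(0.0, 1.0)
            w = 1.0 / var
            mu = sum(wi * yi for wi, yi in zip(w, lfc)) / sum(w)
            assert lm.pool_fixed(lfc, var)[0] == pytest.approx(mu, abs=1e-12)
            q_direct = sum(wi * (yi - mu) ** 2 for wi, yi in zip(w, lfc))
            assert lm.cochran_q(lfc, var)[0] == pytest.approx(q_direct, abs=1e-10)
            wr = 1.0 / (var + tau2)
            mur = sum(wi * yi for wi, yi in zip(wr, lfc)) / sum(wr)
            assert lm.pool_random(lfc, var, tau2)[0] == pytest.approx(mur, abs=1e-12)

    def test_fixed_pooling_invariant_to_study_order(self, rng):
        lfc, var = rng.normal(size=7), rng.uniform(0.1, 2.0, 7)
        perm = rng.permutation(7)
        assert lm.pool_fixed(lfc[perm], var[perm]) == pytest.approx(
            lm.pool_fixed(lfc, var)
        )

    def test_duplicating_a_study_at_double_variance_preserves_fixed_pool(self):
        lfc, var = [1.0, 2.0, 0.5], [0.3, 0.6, 0.2]
        split_lfc = lfc + [lfc[0]]
        split_var = [var[0] * 2, var[1], var[2], var[0] * 2]
        assert lm.pool_fixed(split_lfc, split_var)[0] == pytest.approx(
            lm.pool_fixed(lfc, var)[0]
        )


class TestDLTau2:
    def test_homogeneous_effects_truncate_to_zero(self):
        assert lm.dl_tau2([1.0, 1.0, 1.0], [0.5, 0.5, 0.5]) == 0.0

    def test_two_study_hand_example(self):
        # Q=2, df=1, S1=2, S2/S1=1 -> tau2 = 1
        assert lm.dl_tau2([0.0, 2.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_agrees_with_statsmodels_independent_implementation(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        for _ in range(20):
            k = rng.integers(3, 10)
            lfc = rng.normal(size=k)
            var = rng.uniform(0.05, 2.0, k)
            res = combine_effects(lfc, var, method_re="dl")
            # statsmodels reports the untruncated moment estimate
            tau2_sm = max(0.0, res.tau2)
            assert lm.dl_tau2(lfc, var) == pytest.approx(tau2_sm, abs=1e-10)
            assert lm.pool_fixed(lfc, var)[0] == pytest.approx(
                res.mean_effect_fe, abs=1e-10
            )
            if res.tau2 > 0:  # RE mean comparable only when estimates coincide
                assert lm.pool_random(lfc, var, tau2_sm)[0] == pytest.approx(
                    res.mean_effect_re, abs=1e-10
                )

    def test_moment_recovery_of_simulated_heterogeneity(self, rng):
        """Median DL estimate over replicates near the simulated tau2."""
        true_tau2, k = 0.25, 50
        estimates = []
        for _ in range(200):
            theta = rng.normal(0.0, np.sqrt(true_tau2), k)
            var = np.full(k, 0.01)
            y = theta + rng.normal(0.0, np.sqrt(var))
            estimates.append(lm.dl_tau2(y, var))
        assert np.median(estimates) == pytest.approx(true_tau2, rel=0.2)


class TestMetaAnalyzeGene:
    def test_insufficient_coverage_excluded(self):
        eff = _effects_frame([1.0] * 5, [0.1] * 5)
        assert meta_analyze_gene(eff, total_studies=11) is None

    def test_majority_threshold_of_eleven_is_six(self):
        assert lm.min_studies(11) == 6
        eff = _effects_frame(list(np.linspace(0.5, 1.5, 6)), [0.1] * 6)
        assert meta_analyze_gene(eff, total_studies=11) is not None

    def test_floor_of_two_studies(self):
        assert lm.min_studies(2, min_fraction=0.1) == 2

    def test_identical_tiny_variance_effects_are_overwhelming(self):
        eff = _effects_frame([2.0] * 8, [1e-6] * 8)
        res = meta_analyze_gene(eff)
        assert res.model == "fixed"
        assert res.p_value < 1e-300
        assert res.pooled_lfc == pytest.approx(2.0)

    def test_result_invariants(self, rng):
        lfc, var = rng.normal(1.0, 1.0, 9), rng.uniform(0.05, 0.6, 9)
        res = meta_analyze_gene(_effects_frame(lfc, var))
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert res.df == res.k - 1
        assert 0.0 <= res.isq < 100.0
        assert res.tau2 >= 0.0
        assert res.ci95[0] <= res.pooled_lfc <= res.ci95[1]
        assert res.std_lfc == pytest.approx(np.std(lfc, ddof=1))

    def test_vectorised_table_matches_per_gene_path(self, cohorts, rng):
        cfg = lm.SyntheticConfig(
            n_genes=25, true_lfc={"SPP1": 2.0}, tau2=0.1, coverage=0.8,
            seed=29, studies=cohorts,
        )
        table = lm.effects_table(lm.generate_studies(cfg))
        vec = meta_analyze(table, total_studies=11)
        for _, row in vec.iterrows():
            sub = table[table["gene_id"] == row["gene_id"]]
            scalar = meta_analyze_gene(sub, total_studies=11)
            assert row["pooled_lfc"] == pytest.approx(scalar.pooled_lfc, abs=1e-12)
            assert row["se"] == pytest.approx(scalar.se, abs=1e-12)
            assert row["Q"] == pytest.approx(scalar.Q, abs=1e-10)
            assert row["tau2"] == pytest.approx(scalar.tau2, abs=1e-12)
            assert row["p_value"] == pytest.approx(scalar.p_value, rel=1e-10)
            assert row["model"] == scalar.model
        # genes below the majority threshold are absent from the table
        short = table.groupby("gene_id").size()
        assert set(vec["gene_id"]) == set(short[short >= 6].index)

    def test_isq_invariant_under_common_rescaling(self, rng):
        lfc, var = rng.normal(size=6), rng.uniform(0.1, 1.0, 6)
        q1, df = lm.cochran_q(lfc, var)
        q2, _ = lm.cochran_q(lfc * 3.0, var * 9.0)
        assert lm.isq(q2, df) == pytest.approx(lm.isq(q1, df))


class TestSignificantGenes:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "p_value", "pooled_lfc"])

    def test_filter_boundaries(self):
        df = self._frame(
            [("kept", 0.004, 1.2), ("weak", 0.004, 0.9), ("insig", 0.006, 3.0)]
        )
        out = lm.significant_genes(df)
        assert list(out["gene_id"]) == ["kept"]

    def test_sorted_by_p_ascending(self):
        df = self._frame([("b", 0.003, 2.0), ("a", 0.001, -1.5), ("c", 0.9, 2.0)])
        assert list(lm.significant_genes(df)["gene_id"]) == ["a", "b"]

    def test_negative_lfc_passes_on_magnitude(self):
        df = self._frame([("down", 1e-4, -2.5)])
        assert len(lm.significant_genes(df)) == 1

    def test_type_one_error_of_p_filter_on_null_genes(self):
        """Null genes pass p < 0.005 at close to the nominal rate."""
        cohorts = [
            lm.StudyMeta(geo_id=f"S{i}", study_name=f"s{i}", n_control=50,
                         n_case=50, country="USA", study_age=1.0)
            for i in range(8)
        ]
        cfg = lm.SyntheticConfig(n_genes=20000, tau2=0.0, seed=101, studies=cohorts)
        results = meta_analyze(lm.effects_table(lm.generate_studies(cfg)))
        rate = (results["p_value"] < 0.005).mean()
        se = np.sqrt(0.005 * 0.995 / len(results))
        assert abs(rate - 0.005) < 3 * se


class TestForestTable:
    def test_equal_variances_split_weight_evenly(self):
        eff = _effects_frame([1.0, 2.0], [0.5, 0.5])
        res = meta_analyze_gene(eff, min_fraction=0.1)
        table = lm.forest_table(res, eff)
        study = table[table["study_id"] != "POOLED"]
        np.testing.assert_allclose(study["weight_percent"], [50.0, 50.0])

    def test_weights_sum_to_hundred_and_summary_row_matches(self, rng):
        lfc, var = rng.normal(1, 1, 7), rng.uniform(0.1, 0.8, 7)
        eff = _effects_frame(lfc, var)
        res = meta_analyze_gene(eff)
        table = lm.forest_table(res, eff)
        study = table[table["study_id"] != "POOLED"]
        assert study["weight_percent"].sum() == pytest.approx(100.0, abs=1e-6)
        summary = table[table["study_id"] == "POOLED"].iloc[0]
        assert summary["lfc"] == pytest.approx(res.pooled_lfc)
        assert (summary["ci95_low"], summary["ci95_high"]) == pytest.approx(res.ci95)

    def test_random_model_weights_more_uniform_than_fixed(self):
        # heterogeneous 3-study instance forces the random model
        eff = _effects_frame([0.0, 2.0, 5.0], [0.05, 0.2, 1.0])
        res = meta_analyze_gene(eff, min_fraction=0.1)
        assert res.model == "random"
        w_fixed = (1 / eff["variance"]) / (1 / eff["variance"]).sum()
        assert max(res.weights.values()) < w_fixed.max()

    def test_per_study_interval_uses_study_variance(self):
        eff = _effects_frame([1.0, 2.0], [0.25, 0.25])
        res = meta_analyze_gene(eff, min_fraction=0.1)
        row = lm.forest_table(res, eff).iloc[0]
        assert row["ci95_low"] == pytest.approx(1.0 - 1.96 * 0.5)
        assert row["ci95_high"] == pytest.approx(1.0 + 1.96 * 0.5)


def test_bh_fdr_column_is_informational(rng):
    res = pd.DataFrame(
        {"gene_id": list("abcd"), "p_value": [0.001, 0.01, 0.5, 0.04],
         "pooled_lfc": [2.0, 1.5, 0.1, -1.2]}
    )
    out = lm.add_bh_fdr(res)
    assert "bh_fdr" in out.columns
    expected = stats.false_discovery_control(res["p_value"], method="bh")
    np.testing.assert_allclose(out["bh_fdr"], expected)
    # the significance filter ignores the FDR column
    assert list(lm.significant_genes(out)["gene_id"]) == ["a"]
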