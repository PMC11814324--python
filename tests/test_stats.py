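"""Normalization, z-scores, dispersion, NB Wald test, BH and rank tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from chromage import stats
from chromage.io import CountMatrix


def _cm(array, normalized=False, samples=None):
    a = np.asarray(array)
    df = pd.DataFrame(
        a,
        index=[f"r{i}" for i in range(a.shape[0])],
        columns=samples or [f"s{i}" for i in range(a.shape[1])],
    )
    return CountMatrix(df, mark="H3K27ac", normalized=normalized)


def brute_force_size_factors(x):
    """Independent transcription of the median-of-ratios definition."""
    x = np.asarray(x, dtype=float)
    keep = [g for g in range(x.shape[0]) if (x[g] > 0).all()]
    refs = {g: np.prod(x[g]) ** (1.0 / x.shape[1]) for g in keep}
    return np.array(
        [np.median([x[g, s] / refs[g] for g in keep]) for s in range(x.shape[1])]
    )


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[5, 5, 5], [9, 9, 9]])
        assert np.allclose(stats.size_factors_median_of_ratios(cm), 1.0)

    def test_hand_example_two_samples(self):
        cm = _cm([[2, 8], [2, 8]])
        sf = stats.size_factors_median_of_ratios(cm)
        assert np.allclose(sf, [0.5, 2.0])

    def test_rows_with_zero_are_excluded_from_reference(self):
        cm = _cm([[0, 5], [4, 4]])
        assert np.allclose(stats.size_factors_median_of_ratios(cm), [1.0, 1.0])

    def test_no_all_positive_row_raises(self):
        cm = _cm([[0, 5], [4, 0]])
        with pytest.raises(ValueError, match="pseudo-reference"):
            stats.size_factors_median_of_ratios(cm)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x = rng.integers(0, 500, size=(30, 5))
            if not (x > 0).all(axis=1).any():
                continue
            got = stats.size_factors_median_of_ratios(_cm(x)).to_numpy()
            assert np.allclose(got, brute_force_size_factors(x))

    @given(c=st.sampled_from([0.25, 0.5, 2.0, 4.0, 8.0]))
    def test_scale_equivariance_of_factor_ratios(self, c):
        # scaling a column by c also scales the geometric-mean reference by
        # c^(1/n), so equivariance holds for factor RATIOS: sf_1/sf_0 moves
        # by exactly c (exact scaling keeps counts integral for c chosen here)
        rng = np.random.default_rng(3)
        x = (4 * rng.integers(1, 75, size=(20, 4))).astype(float)
        base = stats.size_factors_median_of_ratios(_cm(x)).to_numpy()
        x2 = x.copy()
        x2[:, 1] = x2[:, 1] * c
        scaled = stats.size_factors_median_of_ratios(_cm(x2)).to_numpy()
        assert (scaled[1] / scaled[0]) / (base[1] / base[0]) == pytest.approx(c)


class TestNormalize:
    def test_unit_factors_are_identity(self, small_counts):
        sf = pd.Series(1.0, index=small_counts.sample_ids)
        norm = stats.normalize_counts(small_counts, sf)
        assert np.allclose(norm.data, small_counts.data)
        assert norm.normalized

    def test_factor_two_halves_column(self, small_counts):
        sf = pd.Series(1.0, index=small_counts.sample_ids)
        sf.iloc[0] = 2.0
        norm = stats.normalize_counts(small_counts, sf)
        assert np.allclose(norm.data.iloc[:, 0], small_counts.data.iloc[:, 0] / 2.0)

    def test_normalizing_scaled_columns_recovers_original(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 100, size=(10, 3)).astype(float)
        sf = np.array([0.5, 1.0, 2.0])
        scaled = _cm(np.round(x * sf), normalized=True)
        norm = stats.normalize_counts(scaled, pd.Series(sf, index=scaled.sample_ids))
        assert np.allclose(norm.data, np.round(x * sf) / sf)

    def test_missing_factor_raises(self, small_counts):
        with pytest.raises(ValueError, match="missing"):
            stats.normalize_counts(small_counts, pd.Series({"s0": 1.0}))


class TestZScores:
    def test_closed_form_three_samples(self):
        cm = _cm([[1, 2, 3]], normalized=True)
        z = stats.gene_zscores(cm)
        assert np.allclose(z.data.iloc[0], [-1.2247448, 0.0, 1.2247448])
        # brute-force mean/population-SD oracle
        v = np.array([1.0, 2.0, 3.0])
        assert np.allclose(z.data.iloc[0], (v - v.mean()) / v.std())

    def test_constant_row_becomes_zeros(self):
        z = stats.gene_zscores(_cm([[7, 7, 7]], normalized=True))
        assert np.allclose(z.data.iloc[0], 0.0)

    def test_rows_have_zero_mean_unit_population_sd(self, default_study):
        counts = default_study.counts["H3K27ac"]
        sf = stats.size_factors_median_of_ratios(counts)
        z = stats.gene_zscores(stats.normalize_counts(counts, sf))
        x = z.data.to_numpy()
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-12)
        sds = x.std(axis=1)
        assert np.all(np.isclose(sds, 1.0) | np.isclose(sds, 0.0))

    def test_reflecting_inputs_negates_outputs(self):
        # z of (c - x) for constant c equals -z of x (affine equivariance)
        df = pd.DataFrame([[1.0, 4.0, 7.0]], index=["r0"], columns=["a", "b", "c"])
        z_pos = stats.gene_zscores(CountMatrix(df, "m", normalized=True))
        z_neg = stats.gene_zscores(CountMatrix(10.0 - df, "m", normalized=True))
        assert np.allclose(z_neg.data.to_numpy(), -z_pos.data.to_numpy())

    def test_subset_smaller_than_two_raises(self):
        with pytest.raises(ValueError):
            stats.gene_zscores(_cm([[1, 2]], normalized=True), sample_subset=["s0"])


class TestDispersion:
    def test_poisson_data_floors_toward_alpha_min(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(200, size=(300, 40))
        cm = _cm(x)
        sf = pd.Series(1.0, index=cm.sample_ids)
        alpha = stats.estimate_dispersion_mom(
            cm, sf, {"g": cm.sample_ids}, shrink_weight=0.0
        )
        # Poisson has alpha = 0; median estimate should be close to the floor
        assert np.median(alpha) < 0.01

    def test_nb_alpha_recovery_within_20pct(self):
        rng = np.random.default_rng(1)
        alpha_true = 0.1
        size = 1.0 / alpha_true
        mu = 150
        x = rng.negative_binomial(size, size / (size + mu), size=(400, 200))
        cm = _cm(x)
        sf = pd.Series(1.0, index=cm.sample_ids)
        alpha = stats.estimate_dispersion_mom(
            cm, sf, {"g": cm.sample_ids}, shrink_weight=0.0
        )
        assert alpha.mean() == pytest.approx(alpha_true, rel=0.2)

    def test_underdispersed_rows_hit_floor(self):
        cm = _cm([[10, 10, 10, 10]])
        sf = pd.Series(1.0, index=cm.sample_ids)
        alpha = stats.estimate_dispersion_mom(
            cm, sf, {"g": cm.sample_ids}, alpha_min=1e-8, shrink_weight=0.0
        )
        assert alpha.iloc[0] == 1e-8

    def test_all_singleton_groups_raise(self, small_counts):
        sf = pd.Series(1.0, index=small_counts.sample_ids)
        groups = {s: [s] for s in small_counts.sample_ids}
        with pytest.raises(ValueError):
            stats.estimate_dispersion_mom(small_counts, sf, groups)


class TestBH:
    def test_stepup_by_hand(self):
        got = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, pvals):
        def brute(p):
            p = np.asarray(p, dtype=float)
            m = len(p)
            order = np.argsort(p, kind="mergesort")
            adj = np.empty(m)
            for rank_pos, idx in enumerate(order, start=1):
                candidates = [
                    p[order[j]] * m / (j + 1)
                    for j in range(rank_pos - 1, m)
                ]
                adj[idx] = min(1.0, min(candidates))
            return adj

        assert np.allclose(stats.bh_adjust(pvals), brute(pvals))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_statsmodels(self, pvals):
        expected = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(stats.bh_adjust(pvals), expected)


class TestNbWald:
    def test_identical_group_means_are_null(self):
        cm = _cm([[10, 10, 20, 20]], normalized=True)
        sf = pd.Series(1.0, index=cm.sample_ids)
        res = stats.nb_wald_differential(cm, sf, ["s0", "s2"], ["s1", "s3"], 0.05)
        assert res["log2fc"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0
        assert res["status"].iloc[0] == "ns"

    def test_single_region_formula_oracle(self):
        # muA = 10, muB = 40, n = 3 each, alpha = 0.05, pc = 1
        cm = _cm([[10, 10, 10, 40, 40, 40]], normalized=True)
        sf = pd.Series(1.0, index=cm.sample_ids)
        res = stats.nb_wald_differential(
            cm, sf, ["s0", "s1", "s2"], ["s3", "s4", "s5"], alpha=0.05
        )
        lfc = np.log2(41 / 11)
        var = (1 / 3) * (1 / 11 + 0.05) + (1 / 3) * (1 / 41 + 0.05)
        se = np.sqrt(var) / np.log(2)
        z = lfc / se
        assert res["log2fc"].iloc[0] == pytest.approx(lfc)
        assert res["log2fc"].iloc[0] == pytest.approx(1.898, abs=1e-3)
        assert res["se"].iloc[0] == pytest.approx(se)
        assert res["pvalue"].iloc[0] == pytest.approx(2 * sps.norm.sf(abs(z)))

    def test_status_follows_sign_and_threshold(self):
        rng = np.random.default_rng(2)
        base = rng.integers(50, 150, size=(50, 6)).astype(float)
        base[0, 3:] *= 8
        base[1, 3:] /= 8
        cm = _cm(base, normalized=True)
        sf = pd.Series(1.0, index=cm.sample_ids)
        res = stats.nb_wald_differential(
            cm, sf, cm.sample_ids[:3], cm.sample_ids[3:], 0.05
        )
        assert res["status"].iloc[0] == "up"
        assert res["status"].iloc[1] == "down"

    def test_empty_group_and_misaligned_alpha_raise(self, small_counts):
        sf = pd.Series(1.0, index=small_counts.sample_ids)
        with pytest.raises(ValueError):
            stats.nb_wald_differential(small_counts, sf, [], ["s0"], 0.05)
        bad_alpha = pd.Series([0.1], index=["zzz"])
        with pytest.raises(ValueError):
            stats.nb_wald_differential(
                small_counts, sf, ["s0", "s1"], ["s2", "s3"], bad_alpha
            )

    def test_power_monotone_in_replicates(self):
        rng = np.random.default_rng(5)
        alpha = 0.05
        size = 1 / alpha

        def rate(n_rep):
            mu_a, mu_b = 100, 200
            a = rng.negative_binomial(size, size / (size + mu_a), size=(800, n_rep))
            b = rng.negative_binomial(size, size / (size + mu_b), size=(800, n_rep))
            cm = _cm(np.hstack([a, b]))
            sf = pd.Series(1.0, index=cm.sample_ids)
            res = stats.nb_wald_differential(
                cm, sf, cm.sample_ids[:n_rep], cm.sample_ids[n_rep:], alpha
            )
            return (res["pvalue"] < 0.05).mean()

        assert rate(2) < rate(6)


class TestRankTests:
    def test_exact_mwu_enumeration_example(self):
        rep = stats.rank_tests([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert rep.pvalue == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        rep = stats.rank_tests([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert rep.pvalue > 0.9

    def test_kw_three_identical_groups_statistic_zero(self):
        rep = stats.rank_tests(
            [5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3, test="kruskal_wallis"
        )
        assert rep.statistic == 0.0
        assert (rep.pairwise["p_bonferroni"] == 1.0).all()

    def test_kw_pairwise_bonferroni_capped(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10),
                               rng.normal(5, 1, 10)])
        grp = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        rep = stats.rank_tests(vals, grp, test="kruskal_wallis")
        assert rep.pvalue < 0.01
        pw = rep.pairwise.set_index(["group_a", "group_b"])["p_bonferroni"]
        assert pw[("a", "c")] < 0.05 and pw[("b", "c")] < 0.05
        assert (rep.pairwise["p_bonferroni"] <= 1.0).all()

    def test_wrong_group_count_raises(self):
        with pytest.raises(ValueError):
            stats.rank_tests([1, 2, 3], ["a", "b", "c"])


class TestPercentChange:
    @pytest.mark.parametrize(
        "a,b,pc,expected",
        [([4.0], [4.0], 0.0, 0.0), ([4.0], [6.0], 0.0, 50.0), ([0.0], [5.0], 1.0, 500.0)],
    )
    def test_rule_application(self, a, b, pc, expected):
        assert stats.percent_signal_change(a, b, pc)[0] == pytest.approx(expected)

    def test_zero_denominator_raises(self):
        with pytest.raises(ValueError):
            stats.percent_signal_change([0.0], [1.0], 0.0)
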