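"""Variant filters, category frequencies, t-tests, Holm-Sidak correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import amplijoin as aj
from amplijoin.stats import (
    category_frequencies,
    compare_groups,
    filter_variant_sequences,
    fold_effect,
    holm_sidak,
    unpaired_t,
    variant_pool,
)


class TestVariantFilter:
    def test_threshold_boundary_point_one_percent(self):
        # 10/10000 = 0.10% retained; 9/10000 = 0.09% removed
        counts = pd.Series({"keep": 10, "drop": 9, "big": 9981})
        retained, removed = filter_variant_sequences(counts, pool_total=10_000)
        assert "keep" in retained.index and "big" in retained.index
        assert "drop" not in retained.index
        assert removed == pytest.approx(9 / 10_000)

    def test_zero_threshold_is_identity(self):
        counts = pd.Series({"a": 1, "b": 2})
        retained, removed = filter_variant_sequences(counts, threshold=0.0)
        assert retained.sum() == 3 and removed == 0.0

    def test_all_below_threshold(self):
        counts = pd.Series({"a": 1, "b": 1})
        retained, removed = filter_variant_sequences(counts, pool_total=10_000)
        assert len(retained) == 0 and removed == pytest.approx(2 / 10_000)

    def test_empty_pool_warns(self):
        with pytest.warns(UserWarning, match="empty pool"):
            retained, removed = filter_variant_sequences(pd.Series(dtype=float))
        assert len(retained) == 0

    def test_pools_partition_calls(self, clean_calls):
        del_counts, del_total = variant_pool(clean_calls, "deletions")
        ins_counts, ins_total = variant_pool(clean_calls, "insertions_plus_complex")
        assert del_counts.sum() == del_total
        assert ins_counts.sum() == ins_total
        n_cat = clean_calls["category"].value_counts()
        assert del_total == n_cat.get(aj.DELETION, 0)
        assert ins_total == n_cat.get(aj.INSERTION, 0) + n_cat.get(aj.COMPLEX_INDEL, 0)


class TestCategoryFrequencies:
    def test_arithmetic(self):
        calls = pd.DataFrame(
            {"category": [aj.NO_INDEL_EJ] * 40 + [aj.INSERTION] * 20 + [aj.DELETION] * 35 + [aj.COMPLEX_INDEL] * 5}
        )
        freqs = category_frequencies(calls)
        assert freqs.tolist() == pytest.approx([0.40, 0.20, 0.35, 0.05])
        assert freqs.sum() == pytest.approx(1.0)

    def test_all_one_category(self):
        calls = pd.DataFrame({"category": [aj.NO_INDEL_EJ] * 7})
        freqs = category_frequencies(calls)
        assert freqs[aj.NO_INDEL_EJ] == 1.0

    def test_unclassified_excluded_but_accounted(self):
        calls = pd.DataFrame({"category": [aj.NO_INDEL_EJ, aj.UNCLASSIFIED]})
        freqs = category_frequencies(calls)
        assert freqs[aj.NO_INDEL_EJ] == 1.0
        assert freqs.attrs["n_unclassified"] == 1

    def test_zero_classified_reads_raise_with_sample_name(self):
        calls = pd.DataFrame({"category": [aj.UNCLASSIFIED]})
        with pytest.raises(ValueError, match="s1"):
            category_frequencies(calls, sample="s1")

    def test_simulated_mix_recovery(self, clean_sim, clean_calls):
        cfg, _, _ = clean_sim
        freqs = category_frequencies(clean_calls)
        for cat, p in zip(aj.CATEGORIES, cfg.category_mix):
            sigma = np.sqrt(p * (1 - p) / cfg.n_reads)
            assert abs(freqs[cat] - p) < 3 * sigma + 1e-12


class TestUnpairedT:
    def test_identical_groups_p_one(self):
        assert unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_shifted_groups_closed_form(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        p = unpaired_t(a, b)
        t = 10 / np.sqrt(1.0 * (1 / 3 + 1 / 3))  # pooled variance = 1, df = 4
        assert p == pytest.approx(2 * sps.t.sf(t, df=4))
        assert p < 0.01

    def test_symmetry(self):
        a, b = [0.1, 0.4, 0.3], [0.5, 0.9, 0.7]
        assert unpaired_t(a, b) == pytest.approx(unpaired_t(b, a))

    def test_degenerate_zero_variance(self):
        assert unpaired_t([2.0, 2.0], [2.0, 2.0]) == 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            assert unpaired_t([2.0, 2.0], [3.0, 3.0]) == 0.0

    def test_welch_differs_under_unequal_variance(self):
        a = [1.0, 1.1, 0.9, 1.05]
        b = [2.0, 4.0, 0.5, 3.5]
        assert unpaired_t(a, b, welch=True) != pytest.approx(unpaired_t(a, b, welch=False))


class TestHolmSidak:
    def test_single_p_identity(self):
        assert holm_sidak([0.05]) == pytest.approx([0.05])

    def test_closed_form_pair(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_equal_ps_monotone(self):
        adj = holm_sidak([0.5, 0.5, 0.5])
        assert np.allclose(adj, 1 - 0.5**3)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(1e-6, 1, size=20)
        _, adj_sm, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(holm_sidak(p), adj_sm)

    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=15))
    @settings(max_examples=100, derandomize=True)
    def test_bounds_and_permutation_equivariance(self, ps):
        adj = holm_sidak(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0).all()
        perm = np.argsort(ps, kind="stable")[::-1]
        adj_perm = holm_sidak(list(np.asarray(ps)[perm]))
        assert np.allclose(adj_perm, adj[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_sidak([0.0, 0.5])
        with pytest.raises(ValueError):
            holm_sidak([1.5])

    def test_family_wise_error_controlled_monte_carlo(self):
        # 2,000 null families of m=5 Student t-tests (n=3 vs 3): the
        # step-down Sidak procedure keeps FWER at alpha = 0.05
        rng = np.random.default_rng(2024)
        m, fams, n = 5, 2000, 3
        a = rng.standard_normal((fams, m, n))
        b = rng.standard_normal((fams, m, n))
        p = sps.ttest_ind(a, b, axis=2).pvalue
        rejections = np.array([(holm_sidak(row) <= 0.05).any() for row in p])
        fwer = rejections.mean()
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / fams)


class TestFoldEffect:
    @pytest.mark.parametrize(
        "a,b,ratio,direction",
        [(0.4, 0.2, 2.0, "decrease"), (0.3, 0.3, 1.0, "none"), (0.21, 0.40, 0.40 / 0.21, "increase")],
    )
    def test_ratio_and_direction(self, a, b, ratio, direction):
        fe = fold_effect(a, b)
        assert fe.ratio == pytest.approx(ratio)
        assert fe.direction == direction

    def test_near_two_fold_formats_as_1p9(self):
        assert str(fold_effect(0.21, 0.40)) == "1.9-fold increase"

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_effect(0.0, 0.5)


class TestCompareGroups:
    def test_family_table(self):
        rng = np.random.default_rng(7)
        rows = []
        for grp, mu in (("ctrl", 0.40), ("ko", 0.21), ("ko_drug", 0.10)):
            for v in mu + 0.01 * rng.standard_normal(3):
                rows.append({"group": grp, "freq": v})
        df = pd.DataFrame(rows)
        out = compare_groups(df, "freq", "group", [("ctrl", "ko"), ("ctrl", "ko_drug")])
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        assert out["n_a"].tolist() == [3, 3]
        assert (out["direction"] == "decrease").all()
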