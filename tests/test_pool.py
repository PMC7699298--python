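"""TMM normalisation, fold changes and group tests on pooled count tables."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirtrend as mt
from mirtrend.datasets import STOOL_MEAN_CONTROL, STOOL_MEAN_CRC, serum_pool_example
from mirtrend.pool import PoolCountTable

# edgeR 4.0.16 calcNormFactors(method="TMM") on the deterministic fixture
# simulate_pool_counts(PoolSimConfig(n_mirnas=120, dispersion=0.1, seed=7));
# independent oracle for the TMM implementation.
_EDGER_FACTORS = {
    "healthy_1": 1.0534667252,
    "healthy_2": 1.0502762344,
    "tumor_1": 0.8642068501,
    "tumor_2": 1.1480053095,
    "metastatic_1": 0.9143697884,
    "metastatic_2": 0.9963046788,
}


def _table(counts: dict, groups: dict) -> PoolCountTable:
    return PoolCountTable(counts=pd.DataFrame(counts), groups=pd.Series(groups))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        t = _table(
            {"s1": [10, 20, 30, 40], "s2": [10, 20, 30, 40]},
            {"s1": "A", "s2": "B"},
        )
        f = mt.tmm_factors(t)
        assert np.allclose(f, [1.0, 1.0])

    def test_pure_depth_difference_absorbed_by_library_size(self):
        # column B = 2 x column A: every M value equals the depth ratio, so the
        # trimmed mean of M cancels against the library-size term
        t = _table(
            {"s1": [10, 20, 30, 40, 55], "s2": [20, 40, 60, 80, 110]},
            {"s1": "A", "s2": "B"},
        )
        assert np.allclose(mt.tmm_factors(t), [1.0, 1.0])

    def test_factors_invariant_to_row_permutation(self):
        table, _ = mt.simulate_pool_counts(mt.PoolSimConfig(n_mirnas=60, seed=11))
        f1 = mt.tmm_factors(table)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(table.counts))
        shuffled = PoolCountTable(counts=table.counts.iloc[perm], groups=table.groups)
        f2 = mt.tmm_factors(shuffled)
        assert np.allclose(f1.to_numpy(), f2.to_numpy())

    def test_matches_edger_on_frozen_fixture(self):
        table, _ = mt.simulate_pool_counts(
            mt.PoolSimConfig(n_mirnas=120, dispersion=0.1, seed=7)
        )
        f = mt.tmm_factors(table)
        for sample, expected in _EDGER_FACTORS.items():
            assert f[sample] == pytest.approx(expected, abs=1e-9)

    def test_geometric_mean_is_one(self):
        table, _ = mt.simulate_pool_counts(mt.PoolSimConfig(seed=2))
        f = mt.tmm_factors(table)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_depth_rescaling_leaves_normalized_values_unchanged(self):
        # M values are depth-free, but the inverse-variance weights shrink
        # with depth, so weighted TMM absorbs a depth change only to first
        # order; normalized values agree to well under a percent
        table, _ = mt.simulate_pool_counts(mt.PoolSimConfig(n_mirnas=80, seed=5))
        norm1 = mt.normalize(table).normalized
        scaled_counts = table.counts.astype(float).copy()
        scaled_counts.iloc[:, 0] = scaled_counts.iloc[:, 0] * 4.0
        norm2 = mt.normalize(PoolCountTable(counts=scaled_counts, groups=table.groups)).normalized
        assert np.allclose(norm1.iloc[:, 0], norm2.iloc[:, 0], rtol=5e-3)

    def test_all_zero_sample_rejected(self):
        t = _table(
            {"s1": [0, 0], "s2": [1, 2], "s3": [2, 1]},
            {"s1": "A", "s2": "A", "s3": "B"},
        )
        with pytest.raises(ValueError, match="s1"):
            mt.tmm_factors(t)

    def test_fewer_than_two_samples_rejected(self):
        t = _table({"s1": [1, 2]}, {"s1": "A"})
        with pytest.raises(ValueError):
            mt.tmm_factors(t)


class TestLog2GroupFc:
    def test_serum_worked_example_reproduces_printed_fold_changes(self):
        """Raw pool averages reproduce the published serum group contrasts."""
        t = serum_pool_example()
        mid = "hsa-miR-486-5p"
        fc = mt.log2_group_fc(t, mid, "tumor", "metastatic", use_normalized=False)
        assert round(fc, 2) == -0.22
        fc = mt.log2_group_fc(t, mid, "healthy", "metastatic", use_normalized=False)
        assert fc == pytest.approx(-0.85, abs=0.015)
        fc = mt.log2_group_fc(t, mid, "healthy", "tumor", use_normalized=False)
        assert fc == pytest.approx(-0.63, abs=0.015)

    def test_stool_worked_example(self):
        assert round(float(np.log2(STOOL_MEAN_CRC / STOOL_MEAN_CONTROL)), 2) == 2.36

    def test_identical_groups_give_zero(self, two_group_table):
        t = two_group_table
        sym = PoolCountTable(
            counts=pd.concat([t.counts[["a1", "a2"]], t.counts[["a1", "a2"]].set_axis(["b1", "b2"], axis=1)], axis=1),
            groups=t.groups,
        )
        assert mt.log2_group_fc(sym, "m1", "A", "B", use_normalized=False) == 0.0

    def test_antisymmetry(self, two_group_table):
        ab = mt.log2_group_fc(two_group_table, "m1", "A", "B")
        ba = mt.log2_group_fc(two_group_table, "m1", "B", "A")
        assert ab == pytest.approx(-ba)

    def test_zero_mean_raises(self):
        t = _table(
            {"a1": [0, 5], "a2": [0, 6], "b1": [3, 7], "b2": [4, 8]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        with pytest.raises(ValueError, match="undefined"):
            mt.log2_group_fc(t, 0, "A", "B", use_normalized=False)

    def test_planted_effects_recovered_at_large_library_size(self):
        cfg = mt.PoolSimConfig(
            n_mirnas=100,
            library_size=5e7,
            dispersion=0.0,
            planted=((0, (1.0, 0.64, 0.55)),),
            seed=21,
        )
        table, truth = mt.simulate_pool_counts(cfg)
        fc_tumor = mt.log2_group_fc(table, "mir0000", "healthy", "tumor")
        fc_met = mt.log2_group_fc(table, "mir0000", "healthy", "metastatic")
        assert fc_tumor == pytest.approx(np.log2(0.64), abs=0.05)
        assert fc_met == pytest.approx(np.log2(0.55), abs=0.05)


class TestGroupTests:
    def test_ttest_identical_groups_give_p_one(self):
        t = _table(
            {"a1": [1.0], "a2": [2.0], "b1": [1.0], "b2": [2.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        assert mt.per_mirna_ttest(t, "A", "B", use_normalized=False).iloc[0] == 1.0

    def test_ttest_closed_form_value(self):
        # groups (1,2) vs (3,4): t = -2.828, df = 2, two-sided p ~ 0.106
        t = _table(
            {"a1": [1.0], "a2": [2.0], "b1": [3.0], "b2": [4.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        p = mt.per_mirna_ttest(t, "A", "B", use_normalized=False).iloc[0]
        assert p == pytest.approx(0.10557, abs=1e-4)

    def test_ttest_zero_variance_distinct_means(self):
        t = _table(
            {"a1": [1.0], "a2": [1.0], "b1": [2.0], "b2": [2.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        assert mt.per_mirna_ttest(t, "A", "B", use_normalized=False).iloc[0] == 0.0

    def test_anova_closed_form_value(self):
        # (1,2),(3,4),(5,6): SSB = 16 on 2 df, SSW = 1.5 on 3 df,
        # F = 8 / 0.5 = 16, two-sided p = 0.0251 by the F survival function
        t = _table(
            {"a1": [1.0], "a2": [2.0], "b1": [3.0], "b2": [4.0], "c1": [5.0], "c2": [6.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"},
        )
        p = mt.per_mirna_anova(t, use_normalized=False).iloc[0]
        assert p == pytest.approx(0.02509, abs=1e-4)

    def test_anova_degenerate_limits(self):
        t = _table(
            {"a1": [1.0, 1.0], "a2": [1.0, 1.0], "b1": [1.0, 2.0], "b2": [1.0, 2.0],
             "c1": [1.0, 3.0], "c2": [1.0, 3.0]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"},
        )
        p = mt.per_mirna_anova(t, use_normalized=False)
        assert p.iloc[0] == 1.0  # all groups identical
        assert p.iloc[1] == 0.0  # zero within-variance, distinct means

    def test_serum_anova_reproduces_published_value(self):
        """Three-group ANOVA on the raw worked-example row gives p ~ 0.008."""
        t = serum_pool_example()
        p = mt.per_mirna_anova(t, use_normalized=False).loc["hsa-miR-486-5p"]
        assert p == pytest.approx(0.008, abs=5e-4)


class TestBhAdjust:
    def test_step_up_hand_example(self):
        out = mt.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert mt.bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(mt.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        assert np.all(mt.bh_adjust(p) >= p)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mt.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_invariant_to_input_order(self, pvals, rnd):
        p = np.asarray(pvals)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = mt.bh_adjust(p)
        adj_perm = mt.bh_adjust(p[perm])
        assert np.allclose(adj[perm], adj_perm)


class TestAbundanceFilter:
    def test_rule_applied_with_strict_inequality(self):
        t = _table(
            {"a1": [21, 20], "a2": [21, 20], "b1": [0, 20], "b2": [0, 20]},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        # row 0: median 21 > 20 in group A -> retained even though absent in B
        # row 1: median exactly 20 everywhere -> removed (strict inequality)
        assert mt.filter_min_median_reads(t, threshold=20) == [0]

    def test_high_abundance_groups_retained(self):
        t = _table(
            {"a1": [43.65], "a2": [43.65], "b1": [223.67], "b2": [223.67]},
            {"a1": "ctrl", "a2": "ctrl", "b1": "crc", "b2": "crc"},
        )
        assert mt.filter_min_median_reads(t, threshold=20) == [0]
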