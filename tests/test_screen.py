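"""The genome-wide trend screen: direction calls, per-context and combined
trend p-values, consistency flags and multiple-testing options."""
import numpy as np
import pandas as pd
import pytest

import mirtrend as mt
from mirtrend.screen import DegenerateGene, ExpressionStudy
from conftest import make_study


class TestClassifyDirection:
    def test_rising_means_in_both_contexts_are_promoted(self):
        study = make_study((1, 2, 3), (1, 2, 3))
        assert mt.classify_direction(study, "g0") == "promoted"

    def test_falling_means_in_both_contexts_are_inhibited(self):
        study = make_study((3, 2, 1), (3, 2, 1))
        assert mt.classify_direction(study, "g0") == "inhibited"

    def test_flat_gene_is_degenerate(self):
        study = make_study((2, 2, 2), (2, 2, 2))
        with pytest.raises(DegenerateGene):
            mt.classify_direction(study, "g0")

    def test_exact_tie_breaks_toward_promoted(self):
        study = make_study((1, 2, 1), (2, 1, 2))
        assert mt.classify_direction(study, "g0") in ("promoted", "inhibited")
        balanced = make_study((1, 3, 1), (3, 1, 3))
        assert mt.classify_direction(balanced, "g0") == "promoted"


class TestCombinedTransitionTrend:
    def test_strict_six_group_staircase_attains_minimal_p(self):
        study = make_study((0, 1, 2), (3, 4, 5), replicates=2, noise_sd=0.01, seed=1)
        p = mt.combined_transition_trend(study, "g0", n_perm=10_000, seed=0)
        assert p < 1e-3

    def test_transition_break_weakens_combined_trend(self):
        """Trends inside each context but a CSC baseline below the monolayer
        maximum: the combined p captures the missing progressive regulation."""
        study = make_study((0, 2, 4), (0.5, 1.5, 2.5), replicates=2, noise_sd=0.01, seed=2)
        v = study.values("g0")
        trt = study.treatment_codes()
        ctx = study.context_codes()
        p_mono = mt.jt_permutation_p(v[ctx == 0], trt[ctx == 0], "increasing", n_perm=10_000, seed=3)
        p_comb = mt.combined_transition_trend(study, "g0", n_perm=10_000, seed=3)
        assert p_comb > p_mono

    def test_missing_context_rejected(self):
        study = make_study((0, 1, 2), (3, 4, 5))
        mono_only = study.expression.filter(like="monolayer_")
        partial = ExpressionStudy(
            expression=mono_only, design=study.design.loc[mono_only.columns]
        )
        with pytest.raises(ValueError, match="context"):
            mt.combined_transition_trend(partial, "g0", n_perm=100, seed=0)


class TestScreen:
    def test_opposite_directions_never_consistent(self):
        cfg = mt.TrendSimConfig(
            n_genes=30,
            noise_sd=0.3,
            planted_promoted=tuple((i, 2.0, False) for i in range(10)),
            seed=8,
        )
        study, truth = mt.simulate_expression(cfg)
        res = mt.screen(study, n_perm=500, seed=0, correction="none")
        planted = truth.index[truth["label"] == "promoted"]
        assert not res.table.loc[planted, "consistent_with_hypothesis"].any()

    def test_planted_consistent_genes_recovered(self):
        """50 planted consistent genes at effect 2 x noise_sd among 950 nulls:
        >= 40 recovered, null flags within the nominal alpha budget."""
        n_planted = 50
        cfg = mt.TrendSimConfig(
            n_genes=1000,
            noise_sd=0.5,
            planted_promoted=tuple((i, 1.0, True) for i in range(25)),
            planted_inhibited=tuple((25 + i, 1.0, True) for i in range(25)),
            seed=13,
        )
        study, truth = mt.simulate_expression(cfg)
        res = mt.screen(study, n_perm=1000, seed=0, correction="none")
        planted = truth.index[truth["label"] != "null"]
        nulls = truth.index[truth["label"] == "null"]
        flagged = res.table["consistent_with_hypothesis"]
        assert flagged.loc[planted].sum() >= 40
        assert flagged.loc[nulls].sum() <= 0.05 * len(nulls)
        # recovered directions match the planted labels
        hits = res.table.loc[planted][flagged.loc[planted]]
        assert (hits["direction"] == truth.loc[hits.index, "label"].map(
            {"promoted": "promoted", "inhibited": "inhibited"})).all()

    def test_degenerate_genes_excluded_not_fatal(self):
        study = make_study((1, 2, 3), (1, 2, 3), n_genes=2)
        expr = study.expression.copy()
        expr.iloc[1] = 5.0  # flat gene
        study2 = ExpressionStudy(expression=expr, design=study.design)
        res = mt.screen(study2, n_perm=200, seed=0, correction="none")
        assert res.counts["n_degenerate"] == 1
        assert bool(res.table.iloc[1]["degenerate"]) is True

    def test_results_invariant_to_gene_and_sample_order(self):
        cfg = mt.TrendSimConfig(
            n_genes=12, noise_sd=0.4,
            planted_promoted=((0, 1.0, True),), seed=4,
        )
        study, _ = mt.simulate_expression(cfg)
        res1 = mt.screen(study, n_perm=300, seed=5, correction="none")

        rng = np.random.default_rng(0)
        gene_perm = rng.permutation(study.expression.index)
        col_perm = rng.permutation(study.expression.columns)
        shuffled = ExpressionStudy(
            expression=study.expression.loc[gene_perm, col_perm],
            design=study.design,
        )
        res2 = mt.screen(shuffled, n_perm=300, seed=5, correction="none")
        cols = ["p_trend_mono", "p_trend_csc", "p_trend"]
        pd.testing.assert_frame_equal(
            res1.table[cols].sort_index(), res2.table[cols].sort_index()
        )

    def test_curated_list_intersection_counts(self):
        study = make_study((1, 2, 3), (1, 2, 3), replicates=3, noise_sd=0.05, seed=6, n_genes=3)
        res = mt.screen(study, gene_list=["g0", "absent"], n_perm=500, seed=0, correction="none")
        assert res.counts["n_curated_measured"] == 1
        disjoint = mt.screen(study, gene_list=["absent"], n_perm=200, seed=0, correction="none")
        assert disjoint.counts["n_curated_measured"] == 0
        assert disjoint.counts["n_consistent_in_curated"] == 0

    def test_bh_correction_is_monotone_and_reduces_calls(self):
        cfg = mt.TrendSimConfig(
            n_genes=200, noise_sd=0.5,
            planted_promoted=tuple((i, 1.0, True) for i in range(5)), seed=3,
        )
        study, _ = mt.simulate_expression(cfg)
        raw = mt.screen(study, n_perm=500, seed=1, correction="none")
        bh = mt.screen(study, n_perm=500, seed=1, correction="bh")
        assert (bh.table["q_trend_mono"].dropna() >= bh.table["p_trend_mono"].dropna() - 1e-12).all()
        assert bh.counts["n_consistent"] <= raw.counts["n_consistent"]

    def test_maxt_correction_controls_family_and_keeps_strong_signal(self):
        cfg = mt.TrendSimConfig(
            n_genes=60, noise_sd=0.3,
            planted_promoted=tuple((i, 1.5, True) for i in range(3)), seed=5,
        )
        study, truth = mt.simulate_expression(cfg)
        res = mt.screen(study, n_perm=500, seed=2, correction="maxt")
        planted = truth.index[truth["label"] == "promoted"]
        assert (res.table["fwe_p_mono"].dropna() >= res.table["p_trend_mono"].dropna() - 1e-12).all()
        assert res.table.loc[planted, "consistent_with_hypothesis"].sum() >= 2

    def test_summary_mentions_counts(self):
        study = make_study((1, 2, 3), (1, 2, 3), replicates=3, noise_sd=0.1, seed=9)
        res = mt.screen(study, n_perm=200, seed=0, correction="none")
        assert "consistent with the working hypothesis" in res.summary()


class TestFourArmDesign:
    def test_control_arms_tie_at_the_middle_activity_level(self):
        rng = np.random.default_rng(0)
        rows, cols = [], []
        for trt in ("inhibitor", "inhibitor_control", "mimic_control", "mimic"):
            for ctx in ("monolayer", "csc"):
                for r in (1, 2):
                    sid = f"{ctx}_{trt}_r{r}"
                    rows.append({"sample_id": sid, "context": ctx, "treatment": trt, "replicate": r})
                    cols.append(rng.normal(size=2))
        expr = pd.DataFrame(
            np.column_stack(cols), index=["g0", "g1"], columns=[r["sample_id"] for r in rows]
        )
        study = ExpressionStudy(
            expression=expr,
            design=pd.DataFrame(rows).set_index("sample_id"),
            treatment_order=("inhibitor", "inhibitor_control", "mimic_control", "mimic"),
        )
        codes = study.treatment_codes()
        by_trt = dict(zip(study.design["treatment"], codes))
        assert by_trt["inhibitor"] == 0
        assert by_trt["inhibitor_control"] == by_trt["mimic_control"] == 1
        assert by_trt["mimic"] == 2
        res = mt.screen(study, n_perm=200, seed=0, correction="none")
        assert res.counts["n_tested"] == 2


class TestRanking:
    def test_rank_scores_signed_by_direction(self):
        study = make_study((1, 2, 3), (1, 2, 3), replicates=3, noise_sd=0.05, seed=10, n_genes=2)
        expr = study.expression.copy()
        expr.iloc[1] = expr.iloc[1].to_numpy()[::-1]  # reverse: inhibited gene
        res = mt.screen(ExpressionStudy(expression=expr, design=study.design),
                        n_perm=500, seed=0, correction="none")
        scores = res.rank_scores()
        assert scores.iloc[0] > 0 > scores.iloc[1]

    def test_sample_permutation_scores_shape_and_determinism(self):
        cfg = mt.TrendSimConfig(n_genes=8, noise_sd=0.4, seed=2)
        study, _ = mt.simulate_expression(cfg)
        res = mt.screen(study, n_perm=200, seed=0, correction="none")
        genes1, m1 = res.sample_permutation_scores(50, seed=3)
        genes2, m2 = res.sample_permutation_scores(50, seed=3)
        assert genes1 == genes2
        assert np.array_equal(m1, m2)
        assert m1.shape == (50, 8)
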