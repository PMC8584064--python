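"""Additive-effect screen: z-scoring, scoring, median split, enumeration."""

import itertools

import numpy as np
import pandas as pd
import pytest

import panelscan as ps
from panelscan.panel_search import ScoreVector


def _log_expr(vals, samples=None):
    vals = np.asarray(vals, float)
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    return ps.ExpressionMatrix([f"g{i}" for i in range(vals.shape[0])],
                               samples, vals, ps.ExpressionUnit.log2_normalized)


class TestZScore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        expr = _log_expr(rng.normal(5, 2, size=(3, 50)))
        z = ps.zscore_transform(expr, ["g0", "g1", "g2"], [1, 1, 1])
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1, atol=1e-12)

    def test_down_regulated_gene_sign_flip(self):
        rng = np.random.default_rng(2)
        expr = _log_expr(rng.normal(size=(2, 30)))
        z_pos = ps.zscore_transform(expr, ["g0"], [1])
        z_neg = ps.zscore_transform(expr, ["g0"], [-1])
        np.testing.assert_allclose(z_neg.to_numpy(), -z_pos.to_numpy())
        # signed rows have |sd| 1 still
        assert z_neg.std(axis=1, ddof=0).iloc[0] == pytest.approx(1.0)

    def test_constant_gene_error_names_gene(self):
        expr = _log_expr(np.vstack([np.ones(10), np.arange(10.0)]))
        with pytest.raises(ValueError, match="g0"):
            ps.zscore_transform(expr, ["g0", "g1"], [1, 1])

    def test_direction_signs_follow_fold_change(self, sde_table_path):
        selected = ps.select_sde(ps.read_de_table(sde_table_path))
        signs = {r.gene_id: r.sign for r in selected}
        assert signs == {"RAD51": 1, "RPA4": 1, "SLX1B": 1, "POLN": 1,
                         "EME2": 1, "EXO1": 1, "DNTT": -1, "NEIL3": 1}


class TestMultigeneScore:
    def test_singleton_equals_signed_z(self):
        rng = np.random.default_rng(4)
        expr = _log_expr(rng.normal(size=(3, 20)))
        z = ps.zscore_transform(expr, ["g0", "g1", "g2"], [1, -1, 1])
        sv = ps.multigene_score(z, ["g1"])
        np.testing.assert_allclose(sv.scores, z.loc["g1"].to_numpy())

    def test_additivity_over_disjoint_subsets(self):
        rng = np.random.default_rng(5)
        expr = _log_expr(rng.normal(size=(4, 25)))
        z = ps.zscore_transform(expr, [f"g{i}" for i in range(4)], [1, 1, -1, 1])
        a = ps.multigene_score(z, ["g0", "g2"]).scores
        b = ps.multigene_score(z, ["g1", "g3"]).scores
        ab = ps.multigene_score(z, ["g0", "g1", "g2", "g3"]).scores
        np.testing.assert_allclose(a + b, ab)

    def test_hand_matrix_sums(self):
        z = pd.DataFrame([[1.0, 2, 3, 4], [0.5, -1, 0, 2], [-1, -1, 1, 1]],
                         index=["a", "b", "c"], columns=list("wxyz"))
        sv = ps.multigene_score(z, ["a", "c"])
        assert sv.scores.tolist() == [0.0, 1.0, 4.0, 5.0]

    def test_bad_subsets(self):
        z = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"])
        with pytest.raises(ValueError):
            ps.multigene_score(z, [])
        with pytest.raises(KeyError):
            ps.multigene_score(z, ["nope"])


class TestMedianSplit:
    def test_even_distinct_half_and_half(self):
        sv = ps.median_split(ScoreVector(list("abcdef"), np.array([1., 2, 3, 4, 5, 6])))
        assert (sv.groups == "higher").sum() == 3
        assert sv.median_cutoff == pytest.approx(3.5)

    def test_ties_go_lower(self):
        sv = ps.median_split(ScoreVector(list("abcd"), np.array([1.0, 2, 2, 3])))
        assert sv.median_cutoff == pytest.approx(2.0)
        assert list(sv.groups) == ["lower", "lower", "lower", "higher"]

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=40)
        a = ps.median_split(ScoreVector([str(i) for i in range(40)], s))
        b = ps.median_split(ScoreVector([str(i) for i in range(40)], s + 17.3))
        assert list(a.groups) == list(b.groups)

    def test_degenerate_and_tiny(self):
        with pytest.raises(ValueError, match="degenerate"):
            ps.median_split(ScoreVector(list("abcd"), np.full(4, 2.0)))
        with pytest.raises(ValueError, match="4 samples"):
            ps.median_split(ScoreVector(list("ab"), np.array([1.0, 2.0])))


class TestAdditiveSearch:
    def test_enumeration_complete_and_unique(self, small_cohort):
        expr, clin, gt = small_cohort
        rk = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os")
        assert rk.n_screened == 2 ** 8 - 1 == len(rk.table)
        # bitmask accounting: every subset exactly once
        seen = {frozenset(s.split(",")) for s in rk.table["subset"]}
        expected = {frozenset(c) for r in range(1, 9)
                    for c in itertools.combinations(gt.planted_genes, r)}
        assert seen == expected

    def test_single_candidate_single_row(self, small_cohort):
        expr, clin, gt = small_cohort
        rk = ps.additive_search(expr, clin, gt.planted_genes[:1], gt.signs[:1], "os")
        assert len(rk.table) == 1

    def test_ranking_deterministic(self, small_cohort):
        expr, clin, gt = small_cohort
        a = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os")
        b = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os")
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_normal_samples_do_not_leak_into_zscoring(self, small_cohort):
        expr, clin, gt = small_cohort
        tumor_only = expr.subset_samples(clin.tumor_ids())
        a = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os")
        b = ps.additive_search(tumor_only, clin, gt.planted_genes, gt.signs, "os")
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_planted_panel_wins_on_strong_signal(self, small_cohort):
        expr, clin, gt = small_cohort
        rk = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os")
        assert set(rk.selected) == set(gt.prognostic_genes)

    def test_hr_criterion_reorders(self, small_cohort):
        expr, clin, gt = small_cohort
        rk = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os",
                                criterion="hr")
        ok = rk.table[rk.table["status"] == "ok"]
        assert ok["hr"].is_monotonic_decreasing

    def test_guard_rail_on_large_k(self, small_cohort):
        expr, clin, _ = small_cohort
        genes = expr.gene_ids[:21]
        with pytest.raises(ValueError, match="capped"):
            ps.additive_search(expr, clin, genes, [1] * 21, "os")

    def test_screen_size_and_bonferroni_reported(self, small_cohort):
        expr, clin, gt = small_cohort
        rk = ps.additive_search(expr, clin, gt.planted_genes[:4], gt.signs[:4], "os")
        assert rk.n_screened == 15
        assert rk.bonferroni_alpha == pytest.approx(0.05 / 15)


class TestEvaluatePanel:
    def test_consistent_with_ranking_row(self, small_cohort):
        expr, clin, gt = small_cohort
        rk = ps.additive_search(expr, clin, gt.planted_genes, gt.signs, "os")
        top = rk.table.iloc[0]
        sign_of = dict(zip(gt.planted_genes, gt.signs))
        genes = rk.selected
        panel = ps.PanelDefinition(genes, [sign_of[g] for g in genes])
        _, res, _ = ps.evaluate_panel(expr, clin, panel, "os")
        assert res.p == pytest.approx(top["logrank_p"])
        assert res.hr == pytest.approx(top["hr"])

    def test_km_curves_returned_per_group(self, small_cohort):
        expr, clin, gt = small_cohort
        panel = ps.PanelDefinition(list(gt.prognostic_genes),
                                   [1 if g != gt.planted_genes[6] else -1
                                    for g in gt.prognostic_genes])
        curves, res, sv = ps.evaluate_panel(expr, clin, panel, "os")
        assert set(curves) == {"higher", "lower"}
        assert sv.groups is not None
        # higher-risk group's curve should end lower on this strong signal
        hi, lo = curves["higher"], curves["lower"]
        assert hi.survival[-1] < lo.survival[-1]
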