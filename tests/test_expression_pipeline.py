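"""Expression matrix IO, filtering, gene collapse and the moderated t."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regulonscan.expression_pipeline import (
    ExpressionFormatError,
    ExpressionMatrix,
    ModerationParams,
    bh_adjust,
    collapse_to_genes,
    filter_low_expression,
    moderated_t_test,
    read_expression_table,
    timecourse_contrasts,
    write_expression_table,
)
from regulonscan.synthetic_data import SimConfig, simulate_timecourse


class TestReadWrite:
    def test_round_trip(self, small_matrix, tmp_path):
        m, s = tmp_path / "m.tsv", tmp_path / "s.tsv"
        write_expression_table(small_matrix, m, s)
        back = read_expression_table(m, s)
        pd.testing.assert_frame_equal(back.values, small_matrix.values)
        assert list(back.samples["time_h"]) == list(small_matrix.samples["time_h"])

    def test_duplicate_feature_id_named_in_error(self, tmp_path):
        (tmp_path / "m.tsv").write_text(
            "feature_id\ts1\ts2\n1007_s_at\t1\t2\n1007_s_at\t3\t4\n"
        )
        (tmp_path / "s.tsv").write_text(
            "sample_id\tcondition\ttime_h\treplicate\ns1\tc\t0\t1\ns2\tc\t0\t2\n"
        )
        with pytest.raises(ExpressionFormatError, match="1007_s_at"):
            read_expression_table(tmp_path / "m.tsv", tmp_path / "s.tsv")

    def test_orphan_sample_listed_in_error(self, tmp_path):
        (tmp_path / "m.tsv").write_text("feature_id\ts1\ts2\nf\t1\t2\n")
        (tmp_path / "s.tsv").write_text(
            "sample_id\tcondition\ttime_h\treplicate\ns1\tc\t0\t1\n"
        )
        with pytest.raises(ExpressionFormatError, match="s2"):
            read_expression_table(tmp_path / "m.tsv", tmp_path / "s.tsv")

    def test_non_numeric_cell_located(self, tmp_path):
        (tmp_path / "m.tsv").write_text("feature_id\ts1\nf1\tabc\n")
        (tmp_path / "s.tsv").write_text(
            "sample_id\tcondition\ttime_h\treplicate\ns1\tc\t0\t1\n"
        )
        with pytest.raises(ExpressionFormatError, match="f1"):
            read_expression_table(tmp_path / "m.tsv", tmp_path / "s.tsv")


class TestFilter:
    def _em(self, arr):
        arr = np.asarray(arr, dtype=float)
        values = pd.DataFrame(
            arr, index=[f"f{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        )
        samples = pd.DataFrame(
            {"condition": "c", "time_h": 0.0, "replicate": 1},
            index=values.columns,
        )
        return ExpressionMatrix(values, samples)

    def test_min_fraction_zero_keeps_all(self):
        em = self._em([[1, 1], [9, 9]])
        out = filter_low_expression(em, min_value=5, min_fraction=0.0)
        assert out.feature_ids == ["f0", "f1"]

    def test_all_low_feature_removed(self):
        em = self._em([[1, 2], [9, 9]])
        out = filter_low_expression(em, min_value=5, min_fraction=0.5)
        assert out.feature_ids == ["f1"]

    def test_matches_brute_force_rule(self):
        arr = [
            [7, 7, 7, 7],
            [5, 7, 7, 7],
            [5, 5, 7, 7],
            [5, 5, 5, 7],
            [5, 5, 5, 5],
        ]
        em = self._em(arr)
        out = filter_low_expression(em, min_value=6, min_fraction=0.5)
        expected = [
            f"f{i}"
            for i, row in enumerate(arr)
            if sum(v >= 6 for v in row) / len(row) >= 0.5
        ]
        assert out.feature_ids == expected
        # row order preserved
        assert out.feature_ids == sorted(out.feature_ids, key=expected.index)

    def test_empty_result_warns_not_raises(self):
        em = self._em([[1, 1]])
        with pytest.warns(UserWarning):
            out = filter_low_expression(em, min_value=5, min_fraction=1.0)
        assert out.n_features == 0


class TestCollapse:
    def _em(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(8, 1, size=(6, 5)),
            index=[f"p{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(5)],
        )
        values.loc["p1"] = 7.0  # constant probe
        samples = pd.DataFrame(
            {"condition": "c", "time_h": 0.0, "replicate": 1}, index=values.columns
        )
        return ExpressionMatrix(values, samples)

    def test_single_probe_gene_kept_unchanged(self):
        em = self._em()
        out = collapse_to_genes(em, {"p0": "GA", "p1": "GB", "p2": "GB"})
        assert np.allclose(out.values.loc["GA"], em.values.loc["p0"])

    def test_varying_probe_beats_constant(self):
        em = self._em()
        out = collapse_to_genes(em, {"p1": "G", "p2": "G"})
        assert np.allclose(out.values.loc["G"], em.values.loc["p2"])

    def test_matches_brute_force_max_iqr(self):
        em = self._em()
        mapping = {"p0": "GA", "p1": "GA", "p2": "GB", "p3": "GB", "p4": "GC",
                   "p5": "GC"}
        out = collapse_to_genes(em, mapping)
        for gene in ("GA", "GB", "GC"):
            probes = sorted(p for p, g in mapping.items() if g == gene)
            iqrs = {
                p: np.percentile(em.values.loc[p], 75)
                - np.percentile(em.values.loc[p], 25)
                for p in probes
            }
            best = max(probes, key=lambda p: (iqrs[p], [-ord(c) for c in p]))
            assert np.allclose(out.values.loc[gene], em.values.loc[best])

    def test_empty_mapping_raises(self, small_matrix):
        with pytest.raises(ValueError):
            collapse_to_genes(small_matrix, {})


class TestModeratedT:
    def test_identical_group_means_give_zero_t(self, small_matrix):
        em = small_matrix
        vals = em.values.copy()
        vals.loc["f1"] = [5.0, 6.0, 5.0, 6.0]
        em2 = ExpressionMatrix(vals, em.samples)
        res = moderated_t_test(em2, ["a1", "a2"], ["b1", "b2"])
        assert res.table.loc["f1", "logFC"] == pytest.approx(0.0)
        assert res.table.loc["f1", "t_mod"] == pytest.approx(0.0)
        assert res.table.loc["f1", "p_raw"] == pytest.approx(1.0)

    def test_hand_computed_formula_chain_with_injected_prior(self):
        # 2 vs 2, one gene, d0=4, s0^2=1 injected: every quantity by hand
        values = pd.DataFrame(
            [[1.0, 2.0, 4.0, 5.0]], index=["g"], columns=list("abcd")
        )
        samples = pd.DataFrame(
            {"condition": ["A", "A", "B", "B"], "time_h": 0.0, "replicate": 1},
            index=values.columns,
        )
        em = ExpressionMatrix(values, samples)
        res = moderated_t_test(
            em, ["a", "b"], ["c", "d"], ModerationParams(d0=4.0, s0_sq=1.0)
        )
        logfc = 4.5 - 1.5
        s2 = (0.5 + 0.5) / 2  # pooled var, d_g = 2
        s2_post = (4 * 1.0 + 2 * s2) / (4 + 2)
        t_expected = logfc / math.sqrt(s2_post * (0.5 + 0.5))
        p_expected = 2 * stats.t.sf(abs(t_expected), 6)
        assert res.table.loc["g", "t_mod"] == pytest.approx(t_expected, rel=1e-12)
        assert res.table.loc["g", "df_total"] == 6
        assert res.table.loc["g", "p_raw"] == pytest.approx(p_expected, rel=1e-12)

    def test_matches_independent_eb_oracle(self, limma_matrix):
        """Cross-check against values computed with the reference
        empirical-Bayes implementation (Bioconductor limma) on this fixture."""
        res = moderated_t_test(
            limma_matrix, ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        )
        assert res.params.d0 == pytest.approx(4.985471, rel=1e-5)
        assert res.params.s0_sq == pytest.approx(0.4383382, rel=1e-5)
        expected_t = {
            "g0": -0.975528927120, "g1": 0.604312894332, "g2": -1.938925296054,
            "g3": -0.143511944004, "g4": 3.726515320087, "g5": 1.370340391088,
            "g6": 5.606777879175, "g7": 3.730228052276,
        }
        expected_p = {
            "g0": 0.354827980230, "g1": 0.560582398483, "g2": 0.084507063251,
            "g3": 0.889052776442, "g4": 0.004736224992, "g5": 0.203839411116,
            "g6": 0.000333333841, "g7": 0.004709163073,
        }
        for g, t in expected_t.items():
            assert res.table.loc[g, "t_mod"] == pytest.approx(t, rel=1e-6)
            assert res.table.loc[g, "p_raw"] == pytest.approx(expected_p[g], rel=1e-6)

    def test_d0_zero_reproduces_pooled_t(self, limma_matrix):
        res = moderated_t_test(
            limma_matrix, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
            ModerationParams(d0=0.0, s0_sq=1.0),
        )
        a = limma_matrix.values[["s0", "s1", "s2"]].to_numpy()
        b = limma_matrix.values[["s3", "s4", "s5"]].to_numpy()
        t_ref = stats.ttest_ind(b, a, axis=1).statistic
        np.testing.assert_allclose(res.table["t_mod"], t_ref, rtol=1e-12)
        assert (res.table["df_total"] == 4).all()

    def test_d0_infinite_uses_prior_variance_everywhere(self, limma_matrix):
        s0_sq = 0.7
        res = moderated_t_test(
            limma_matrix, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
            ModerationParams(d0=math.inf, s0_sq=s0_sq),
        )
        se = math.sqrt(s0_sq * (2 / 3))
        np.testing.assert_allclose(
            res.table["t_mod"], res.table["logFC"] / se, rtol=1e-12
        )

    def test_small_group_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            moderated_t_test(small_matrix, ["a1"], ["b1", "b2"])

    def test_column_permutation_invariance(self, limma_matrix):
        res1 = moderated_t_test(limma_matrix, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        perm = ["s4", "s0", "s3", "s2", "s5", "s1"]
        em2 = ExpressionMatrix(
            limma_matrix.values[perm], limma_matrix.samples.loc[perm]
        )
        res2 = moderated_t_test(em2, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_p_adj_never_below_p_raw(self, limma_matrix):
        res = moderated_t_test(limma_matrix, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert (res.table["p_adj"] >= res.table["p_raw"] - 1e-15).all()


class TestBH:
    def test_all_equal(self):
        out = bh_adjust([0.02] * 5)
        np.testing.assert_allclose(out, 0.02)

    def test_step_up_example(self):
        out = bh_adjust([0.005, 0.04, 0.03])
        np.testing.assert_allclose(out, [0.015, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_direct_step_up_and_monotone(self, ps):
        out = bh_adjust(ps)
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        expected = np.empty(m)
        running = 1.0
        for rank_from_top, idx in enumerate(order[::-1]):
            j = m - rank_from_top  # 1-based rank of this p
            running = min(running, m * ps[idx] / j)
            expected[idx] = running
        np.testing.assert_allclose(out, expected, rtol=1e-12, atol=1e-15)
        for i in range(m):
            for j in range(m):
                if ps[i] <= ps[j]:
                    assert out[i] <= out[j] + 1e-12


class TestTimecourse:
    def test_five_time_grid_yields_four_contrasts(self):
        em, _ = simulate_timecourse(SimConfig(seed=0, n_genes=60))
        res = timecourse_contrasts(em)
        assert sorted(res) == [18.0, 36.0, 53.0, 72.0]
        assert res[36.0].label == "36h_vs_0h"

    def test_two_time_design_single_contrast(self):
        em, _ = simulate_timecourse(
            SimConfig(seed=0, n_genes=60, time_points_h=(0.0, 24.0))
        )
        assert list(timecourse_contrasts(em)) == [24.0]

    def test_missing_baseline_raises(self):
        em, _ = simulate_timecourse(SimConfig(seed=0, n_genes=60))
        with pytest.raises(ValueError):
            timecourse_contrasts(em, baseline_time=5.0)

    def test_noise_free_logfc_equals_planted_trajectory(self):
        cfg = SimConfig(seed=3, n_genes=80, noise_sd=0.0, effect_logfc=2.0)
        em, truth = simulate_timecourse(cfg)
        res = timecourse_contrasts(em, params=ModerationParams(d0=1, s0_sq=1e-6))
        for t, contrast in res.items():
            for g in truth.trajectory:
                assert contrast.table.loc[g, "logFC"] == pytest.approx(
                    truth.trajectory[g][t], abs=1e-12
                )
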