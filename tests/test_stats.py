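"""ICC(2,1), Wilcoxon rank-sum and mean ± SD summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from contourvar import (
    icc_2_1,
    summarize_mean_sd,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)

from _oracles import anova_icc_2_1, enumerate_rank_sum_p


class TestIcc:
    def test_identical_raters_give_one(self):
        data = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        res = icc_2_1(data)
        assert res.icc == pytest.approx(1.0)
        assert res.good

    def test_no_subject_variance_gives_zero(self):
        rng = np.random.default_rng(42)
        ests = [icc_2_1(3.0 + rng.normal(0, 1, size=(1000, 2))).icc for _ in range(5)]
        assert np.mean(ests) == pytest.approx(0.0, abs=0.05)
        assert not icc_2_1(3.0 + rng.normal(0, 1, size=(1000, 2))).good

    def test_variance_components_recovery(self):
        # v_ij = mu + p_i + r_ij + e_ij, Var(p)=4, Var(r)=1, Var(e)=1:
        # absolute-agreement ICC = 4 / (4 + 1 + 1) = 2/3
        rng = np.random.default_rng(7)
        n = 1000
        data = (
            10.0
            + rng.normal(0, 2, size=(n, 1))
            + rng.normal(0, 1, size=(n, 2))
            + rng.normal(0, 1, size=(n, 2))
        )
        assert icc_2_1(data).icc == pytest.approx(2 / 3, abs=0.03)

    def test_matches_explicit_anova_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(2, 5))
            data = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 2, size=(n, 1))
            assert icc_2_1(data).icc == pytest.approx(anova_icc_2_1(data), abs=1e-9)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(0, 1, size=(12, 3)) + rng.normal(0, 2, size=(12, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": data.reshape(-1),
            }
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        )
        # absolute agreement, single measures: labelled ICC2 or ICC(A,1)
        row = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = ref.loc[row, "ICC"].iloc[0]
        assert icc_2_1(data).icc == pytest.approx(float(icc2), abs=1e-6)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    def test_invariant_to_affine_rescaling(self, shift, scale):
        rng = np.random.default_rng(3)
        data = rng.normal(0, 1, size=(8, 2)) + rng.normal(0, 2, size=(8, 1))
        base = icc_2_1(data).icc
        assert icc_2_1(data * scale + shift).icc == pytest.approx(base, abs=1e-8)

    def test_consistency_low_bias_at_large_n(self):
        rng = np.random.default_rng(99)
        n = 5000
        ests = []
        for _ in range(8):
            data = (
                rng.normal(0, 2, size=(n, 1))
                + rng.normal(0, 1, size=(n, 2))
                + rng.normal(0, 1, size=(n, 2))
            )
            ests.append(icc_2_1(data).icc)
        assert abs(np.mean(ests) - 2 / 3) < 0.01

    @pytest.mark.parametrize(
        "data,err",
        [
            (np.ones((1, 2)), "subjects"),
            (np.ones((3, 1)), "raters"),
            (np.array([[1.0, np.nan], [2.0, 3.0]]), "missing"),
            (np.ones((2, 2, 2)), "2D"),
        ],
    )
    def test_input_validation(self, data, err):
        with pytest.raises(ValueError, match=err):
            icc_2_1(data)


class TestWilcoxonRankSum:
    def test_textbook_exact_p(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.statistic == 3.0
        assert res.p_value == pytest.approx(1 / 3)
        assert not res.significant

    def test_identical_samples_p_one_exact(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], method="exact")
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_spot_checks(self, rng):
        for _ in range(12):
            n, m = rng.integers(2, 7, size=2)
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.uniform(-1, 1), size=m)
            res = wilcoxon_rank_sum(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_exact_handles_ties_via_permutation(self, rng):
        x = np.array([1.0, 2.0, 2.0, 5.0])
        y = np.array([2.0, 3.0, 3.0])
        res = wilcoxon_rank_sum(x, y, method="exact")
        assert res.p_value == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_auto_switches_to_normal_for_large_or_tied(self, rng):
        big = wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30))
        assert big.method == "normal_approx"
        tied = wilcoxon_rank_sum([1, 1, 2], [2, 3, 3])
        assert tied.method == "normal_approx"

    def test_approx_close_to_exact_at_moderate_n(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(loc=0.8, size=9)
        exact = wilcoxon_rank_sum(x, y, method="exact").p_value
        approx = wilcoxon_rank_sum(x, y, method="approx").p_value
        assert approx == pytest.approx(exact, abs=0.02)

    def test_shift_alternative_detected(self, rng):
        x = rng.normal(0, 1, size=40)
        y = rng.normal(2.0, 1, size=40)
        assert wilcoxon_rank_sum(x, y).significant

    def test_degenerate_all_equal(self):
        res = wilcoxon_rank_sum([2.0] * 20, [2.0] * 20)
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


class TestWilcoxonSignedRank:
    def test_identical_pairs_p_one(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_consistent_shift_detected(self, rng):
        x = rng.normal(0, 1, size=30)
        assert wilcoxon_signed_rank(x, x + 1.5).significant

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestSummarizeMeanSd:
    def _records(self, values, structure="bladder", metric="dsc"):
        return pd.DataFrame(
            {"metric": metric, "structure": structure, "comparison": "c", "value": values}
        )

    def test_constant_values_formatting(self):
        out = summarize_mean_sd(self._records([0.9, 0.9, 0.9]), ["metric", "structure"])
        assert out.loc[0, "formatted"] == "0.900 ± 0.000"
        assert out.loc[0, "n"] == 3

    def test_two_point_sample_sd(self):
        out = summarize_mean_sd(self._records([0.8, 1.0]), ["metric"])
        assert out.loc[0, "mean"] == pytest.approx(0.9)
        assert out.loc[0, "sd"] == pytest.approx(0.14142, abs=1e-4)

    def test_single_record_sd_absent(self):
        out = summarize_mean_sd(self._records([0.8]), ["metric"])
        assert np.isnan(out.loc[0, "sd"])
        assert out.loc[0, "formatted"] == "0.800"

    def test_missing_values_dropped_with_per_cell_n(self):
        df = self._records([0.8, np.nan, 1.0])
        out = summarize_mean_sd(df, ["metric"])
        assert out.loc[0, "n"] == 2

    def test_table_shape_structures_by_comparisons(self, rng):
        rows = []
        for s in ("bladder", "rectum", "anal_canal", "femoral_head_L", "femoral_head_R"):
            for c in ("T1WI-T1dixonc", "T1WI-T2WI", "T2WI-T1dixonc"):
                for _ in range(4):
                    rows.append({"structure": s, "comparison": c, "value": rng.random()})
        out = summarize_mean_sd(pd.DataFrame(rows), ["structure", "comparison"])
        assert len(out) == 15

    def test_empty_input_gives_empty_table_with_header(self):
        out = summarize_mean_sd(pd.DataFrame(), ["metric"])
        assert list(out.columns) == ["metric", "n", "mean", "sd", "formatted"]
        assert out.empty
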