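"""Differential-expression call rules, FPR estimation and IHC scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnaexpr.expression import (
    ExpressionMatrix,
    call_regulation,
    call_regulation_all,
    estimate_fpr,
    filter_changed,
    ihc_log_ratio,
    ihc_paired_test,
    ihc_score,
    summarize_frequency,
)
from cnaexpr.synthetic import CouplingSpec, generate_expression


def _expr(signal_rows, call_rows, tumours, normals, genes=None):
    genes = genes or [f"g{i}" for i in range(len(signal_rows))]
    cols = tumours + normals
    return ExpressionMatrix(
        signals=pd.DataFrame(signal_rows, index=genes, columns=cols, dtype=float),
        calls=pd.DataFrame(call_rows, index=genes, columns=cols),
        tumours=tumours,
        normals=normals,
    )


class TestCallRules:
    def test_present_and_over_twofold_is_up(self):
        e = _expr([[250, 100, 100]], [["P", "P", "P"]], ["T"], ["N1", "N2"])
        assert call_regulation(e, "g0", "T") == "UP"

    def test_all_normals_present_under_half_is_down(self):
        e = _expr([[40, 100, 100]], [["P", "P", "P"]], ["T"], ["N1", "N2"])
        assert call_regulation(e, "g0", "T") == "DOWN"

    def test_absent_tumour_cannot_be_up(self):
        e = _expr([[1000, 100, 100]], [["A", "P", "P"]], ["T"], ["N1", "N2"])
        assert call_regulation(e, "g0", "T") == "NC"

    def test_marginal_treated_as_not_present(self):
        e = _expr([[1000, 100, 100]], [["M", "P", "P"]], ["T"], ["N1", "N2"])
        assert call_regulation(e, "g0", "T") == "NC"

    def test_absent_normal_blocks_down_call(self):
        e = _expr([[40, 100, 100]], [["P", "A", "P"]], ["T"], ["N1", "N2"])
        assert call_regulation(e, "g0", "T") == "NC"

    def test_exact_twofold_boundary_is_nc(self):
        e = _expr([[200, 100, 100]], [["P", "P", "P"]], ["T"], ["N1", "N2"])
        assert call_regulation(e, "g0", "T") == "NC"

    def test_unknown_gene_rejected(self):
        e = _expr([[100, 100, 100]], [["P", "P", "P"]], ["T"], ["N1", "N2"])
        with pytest.raises(KeyError):
            call_regulation(e, "nope", "T")

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_calls_scale_invariant(self, scale):
        rng = np.random.default_rng(0)
        sig = rng.lognormal(4, 1, size=(20, 6))
        calls = np.where(rng.random((20, 6)) < 0.9, "P", "A")
        tum, norm = ["T1", "T2"], ["N1", "N2", "N3", "N4"]
        base = call_regulation_all(
            _expr(sig, calls, tum, norm)
        )
        scaled = call_regulation_all(
            _expr(sig * scale, calls, tum, norm)
        )
        assert (base.values == scaled.values).all()

    def test_truth_recovered_exactly_at_zero_noise(self, annotation, cohort):
        coupling = CouplingSpec(detection_dropout=0.0, expr_noise_sd=0.0, seed=3)
        expr, truth = generate_expression(annotation, cohort["truth_cn"], coupling)
        calls = call_regulation_all(expr)
        assert (calls.values == truth.values).all()


class TestFrequency:
    def test_counts_and_cutoff_filters(self):
        table = pd.DataFrame(
            {"T1": ["UP", "NC"], "T2": ["UP", "NC"], "T3": ["UP", "NC"],
             "T4": ["NC", "NC"], "T5": ["DOWN", "NC"]},
            index=["g1", "g2"],
        )
        freq = summarize_frequency(table)
        assert freq.loc["g1"].tolist() == [3, 1, 1]
        assert (freq.sum(axis=1) == 5).all()
        assert list(filter_changed(freq, "up", 3)) == ["g1"]
        assert list(filter_changed(freq, "up", 4)) == []

    def test_cutoff_beyond_cohort_warns_empty(self):
        freq = summarize_frequency(pd.DataFrame({"T1": ["UP"]}, index=["g"]))
        with pytest.warns(UserWarning):
            assert len(filter_changed(freq, "up", 5)) == 0


class TestFPR:
    def test_identical_normals_zero_fpr(self):
        sig = [[100.0] * 4] * 10
        calls = [["P"] * 4] * 10
        e = _expr(sig, calls, [], ["N1", "N2", "N3", "N4"])
        assert estimate_fpr(e) == (0.0, 0.0)

    def test_exact_twofold_not_counted(self):
        # one normal exactly 2x the mean of the others: strict rule
        sig = [[200.0, 100.0, 100.0, 100.0]]
        calls = [["P"] * 4]
        e = _expr(sig, calls, [], ["N1", "N2", "N3", "N4"])
        assert estimate_fpr(e) == (0.0, 0.0)

    def test_two_normals_rejected(self):
        e = _expr([[100, 100]], [["P", "P"]], [], ["N1", "N2"])
        with pytest.raises(ValueError):
            estimate_fpr(e)

    def test_fpr_monotone_in_fold_threshold(self):
        rng = np.random.default_rng(1)
        sig = rng.lognormal(4, 0.8, size=(3000, 4))
        calls = np.full((3000, 4), "P")
        e = _expr(sig, calls, [], ["N1", "N2", "N3", "N4"])
        rates = [estimate_fpr(e, fold=f) for f in (2, 3, 4)]
        ups = [r[0] for r in rates]
        downs = [r[1] for r in rates]
        assert ups == sorted(ups, reverse=True)
        assert downs == sorted(downs, reverse=True)
        assert all(0 <= v <= 1 for v in ups + downs)


class TestIHC:
    @pytest.mark.parametrize("i,p,expected", [(3, 3, 9), (0, 2, 0), (2, 2, 4)])
    def test_score_product(self, i, p, expected):
        assert ihc_score(i, p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ihc_score(4, 1)
        with pytest.raises(ValueError):
            ihc_score(2, 0)

    @pytest.mark.parametrize(
        "t,n,expected", [(4, 2, 1.0), (5, 0, 4.0), (0, 3, -4.0)]
    )
    def test_log_ratio_with_clamp(self, t, n, expected):
        assert ihc_log_ratio(t, n) == expected

    def test_both_zero_is_na(self):
        assert math.isnan(ihc_log_ratio(0, 0))

    def test_paired_test_all_positive_exact_p(self):
        # 6 pairs, all tumour > normal by distinct margins: p = 2/64
        t = [9, 8, 7, 6, 5, 4]
        n = [3, 4, 2, 1, 2, 0]
        assert math.isclose(ihc_paired_test(t, n), 2 / 64)

    def test_symmetric_differences_p_one(self):
        t = [5, 1, 6, 2, 7, 3]
        n = [1, 5, 2, 6, 3, 7]
        assert math.isclose(ihc_paired_test(t, n), 1.0)

    def test_all_tied_is_na(self):
        assert math.isnan(ihc_paired_test([3, 3, 3], [3, 3, 3]))
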