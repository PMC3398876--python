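"""Copy-number stack: corrections, CBS vs brute-force oracle, gene calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cnaexpr.copy_number import (
    CNThresholds,
    GeneCN,
    ProbeRatioMatrix,
    assign_gene_values,
    call_copy_status,
    center_median,
    combine_enzyme_sets,
    compute_concordance,
    correct_amplification,
    deletion_frequency,
    gain_frequency,
    segment_cbs,
    segment_series,
)


def _matrix(values_by_sample, controls=(), chrom="chr1", spacing=1000):
    n = len(next(iter(values_by_sample.values())))
    probes = pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1) * spacing,
            "enzyme_set": ["A", "B"] * (n // 2) + ["A"] * (n % 2),
        }
    )
    ratios = pd.DataFrame({k: np.asarray(v, float) for k, v in values_by_sample.items()})
    return ProbeRatioMatrix(probes=probes, ratios=ratios, control_samples=controls)


class TestCorrections:
    def test_zero_controls_is_identity(self):
        m = _matrix({"T": [0.5, -0.2, 0.1], "C": [0.0, 0.0, 0.0]}, controls=("C",))
        out = correct_amplification(m)
        assert np.allclose(out.ratios["T"], m.ratios["T"])
        assert out.controls_consumed

    def test_median_of_five_controls_subtracted(self):
        ctrl = {f"C{i}": [v] * 3 for i, v in enumerate([0.1, 0.2, 0.3, 0.4, 0.5])}
        m = _matrix({"T": [1.0, 1.0, 1.0], **ctrl}, controls=tuple(ctrl))
        out = correct_amplification(m)
        assert np.allclose(out.ratios["T"], 1.0 - 0.3)

    def test_no_controls_rejected(self):
        m = _matrix({"T": [0.1, 0.2]})
        with pytest.raises(ValueError):
            correct_amplification(m)

    def test_center_median_enumerated(self):
        m = _matrix({"T": [-1, 0, 1, 2, 3]})
        out = center_median(m)
        assert np.allclose(out.ratios["T"], [-2, -1, 0, 1, 2])
        again = center_median(out)  # idempotent
        assert np.allclose(again.ratios["T"], out.ratios["T"])

    def test_correction_then_centering_commutes_with_closed_form(self):
        rng = np.random.default_rng(5)
        t = rng.normal(0.2, 1, 30)
        c = rng.normal(0, 1, 30)
        m = _matrix({"T": t, "C": c}, controls=("C",))
        out = center_median(correct_amplification(m))
        expected = (t - c) - np.median(t - c)
        assert np.allclose(out.ratios["T"], expected)

    def test_combine_enzyme_sets_interleaves_sorted(self):
        a = _matrix({"T": [1.0, 2.0]}, spacing=2000)  # pos 2000, 4000
        b = _matrix({"T": [9.0]}, spacing=3000)  # pos 3000
        b.probes["probe_id"] = ["q0"]
        out = combine_enzyme_sets(a, b)
        assert list(out.probes["pos"]) == [2000, 3000, 4000]
        assert list(out.ratios["T"]) == [1.0, 9.0, 2.0]

    def test_combine_duplicate_probe_rejected(self):
        a = _matrix({"T": [1.0]})
        b = _matrix({"T": [2.0]}, spacing=7000)
        with pytest.raises(ValueError, match="duplicate"):
            combine_enzyme_sets(a, b)


def _oracle_single_breakpoint(x):
    """Brute-force best single breakpoint by two-sample pooled t."""
    best_t, best_j = 0.0, None
    for j in range(1, len(x)):
        t = stats.ttest_ind(x[:j], x[j:], equal_var=True).statistic
        if np.isnan(t):
            continue
        if abs(t) > best_t:
            best_t, best_j = abs(t), j
    return best_j, best_t


class TestSegmentation:
    def test_constant_series_single_segment(self):
        rng = np.random.default_rng(0)
        segs = segment_series(np.full(50, 0.7), rng=rng)
        assert segs == [(0, 50)]

    def test_step_breakpoint_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.05, 10), rng.normal(1, 0.05, 10)])
        segs = segment_series(x, rng=np.random.default_rng(2))
        cuts = sorted({b for _, b in segs[:-1]})
        assert cuts == [10]
        oracle_j, _ = _oracle_single_breakpoint(x)
        assert oracle_j == 10

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_short_series(self, seed):
        """Whenever a split is accepted on a one-breakpoint series (<=25
        probes), the cut equals the exhaustive max-t breakpoint."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 26))
        bp = int(rng.integers(4, n - 4))
        delta = rng.choice([0.8, 1.5, 3.0])
        x = rng.normal(0, 0.3, n)
        x[bp:] += delta
        segs = segment_series(x, rng=np.random.default_rng(seed + 100))
        if len(segs) == 2:
            oracle_j, _ = _oracle_single_breakpoint(x)
            assert segs[0][1] == oracle_j

    def test_pure_noise_rarely_split(self):
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 30)
            segs = segment_series(x, alpha=0.01, n_perm=100,
                                  rng=np.random.default_rng(seed + 1000))
            hits += len(segs) == 1
        assert hits >= 0.95 * n_seeds

    def test_probe_conservation(self, cohort):
        seg = cohort["segments"]
        probes = cohort["matrix"].probes
        for (sample, chrom), grp in seg.groupby(["sample", "chrom"]):
            assert grp["n_probes"].sum() == (probes["chrom"] == chrom).sum()

    def test_segment_means_match_member_probes(self, cohort):
        seg = cohort["segments"]
        mat = cohort["corrected"]
        sub = seg[seg["sample"] == seg["sample"].iloc[0]]
        for _, s in sub.iterrows():
            sel = (
                (mat.probes["chrom"] == s["chrom"])
                & (mat.probes["pos"] >= s["start"])
                & (mat.probes["pos"] <= s["end"])
            )
            assert math.isclose(
                mat.ratios.loc[sel, s["sample"]].mean(), s["seg_mean"], abs_tol=1e-9
            )

    def test_deterministic_for_fixed_seed(self, cohort):
        seg2 = segment_cbs(cohort["corrected"], seed=2)
        pd.testing.assert_frame_equal(cohort["segments"], seg2)


class TestGeneAssignment:
    def _seg(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "chrom", "start", "end", "n_probes", "seg_mean"]
        )

    def _ann(self, rows):
        return pd.DataFrame(
            rows, columns=["symbol", "chrom", "start", "end"]
        ).set_index("symbol")

    def test_gene_inside_single_segment(self):
        seg = self._seg([("S", "chr1", 1, 1000, 10, -0.8)])
        ann = self._ann([("g1", "chr1", 100, 200)])
        out = assign_gene_values(seg, ann)
        assert out.ratios.at["g1", "S"] == -0.8

    def test_largest_overlap_wins(self):
        seg = self._seg(
            [("S", "chr1", 1, 30_000, 3, 0.0), ("S", "chr1", 30_001, 200_000, 17, -1.0)]
        )
        ann = self._ann([("g1", "chr1", 1, 100_000)])  # 30 kb vs 70 kb overlap
        out = assign_gene_values(seg, ann)
        assert out.ratios.at["g1", "S"] == -1.0

    def test_gene_off_probed_ends_missing(self):
        seg = self._seg([("S", "chr1", 1, 1000, 10, 0.0)])
        ann = self._ann([("g1", "chr1", 5000, 6000), ("g2", "chr2", 1, 100)])
        out = assign_gene_values(seg, ann)
        assert out.ratios[["S"]].isna().all().all()

    def test_tie_broken_toward_midpoint_holder(self):
        seg = self._seg(
            [("S", "chr1", 1, 100, 1, 0.5), ("S", "chr1", 101, 200, 1, -0.5)]
        )
        # gene 51..150: 50 bp overlap with each; midpoint 100 sits in segment 1
        ann = self._ann([("g1", "chr1", 51, 150)])
        out = assign_gene_values(seg, ann)
        assert out.ratios.at["g1", "S"] == 0.5


class TestStatusCalls:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (-0.5, "DEL"),
            (0.40, "GAIN"),
            (-2.5, "HOMDEL"),
            (1.5, "AMP"),
            (0.0, "NEUTRAL"),
            (math.log2(1.5 / 2), "NEUTRAL"),  # boundary equality is strict
            (math.log2(2.5 / 2), "NEUTRAL"),
            (float("nan"), "MISSING"),
        ],
    )
    def test_threshold_rules(self, ratio, expected):
        cn = GeneCN(ratios=pd.DataFrame({"S": [ratio]}, index=["g"]))
        assert call_copy_status(cn).status.at["g", "S"] == expected

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValueError):
            CNThresholds(del_threshold=0.1)

    @given(st.floats(min_value=-0.41, max_value=-0.05))
    @settings(max_examples=25, deadline=None)
    def test_raising_del_threshold_monotone(self, new_thr):
        """DEL call sets only grow as the deletion boundary rises toward 0."""
        ratios = pd.DataFrame({"S": np.linspace(-3, 1, 41)})
        base = call_copy_status(GeneCN(ratios=ratios)).status
        loose = call_copy_status(
            GeneCN(ratios=ratios), CNThresholds(del_threshold=new_thr)
        ).status
        base_del = set(np.flatnonzero(base["S"].isin(["DEL", "HOMDEL"])))
        loose_del = set(np.flatnonzero(loose["S"].isin(["DEL", "HOMDEL"])))
        assert base_del <= loose_del

    def test_frequency_counting(self):
        status = pd.DataFrame(
            {
                "S1": ["DEL", "NEUTRAL"],
                "S2": ["DEL", "NEUTRAL"],
                "S3": ["HOMDEL", "GAIN"],
                "S4": ["NEUTRAL", "AMP"],
            },
            index=["g1", "g2"],
        )
        cn = GeneCN(ratios=status.replace(".", 0).astype(object), status=status)
        assert deletion_frequency(cn).tolist() == [3, 0]
        assert gain_frequency(cn).tolist() == [0, 2]


class TestConcordance:
    def test_identical_vectors(self):
        a = pd.Series(["DEL", "GAIN", "NEUTRAL"], index=list("abc"))
        assert compute_concordance(a, a)[0] == 1.0

    def test_one_mismatch_of_four(self):
        a = pd.Series(["DEL", "GAIN", "NEUTRAL", "DEL"], index=list("abcd"))
        b = pd.Series(["DEL", "GAIN", "NEUTRAL", "NEUTRAL"], index=list("abcd"))
        frac, n_conc, n = compute_concordance(a, b)
        assert (frac, n_conc, n) == (0.75, 3, 4)

    def test_collapse_merges_homdel_and_amp(self):
        a = pd.Series(["HOMDEL", "AMP"], index=list("ab"))
        b = pd.Series(["DEL", "GAIN"], index=list("ab"))
        assert compute_concordance(a, b)[0] == 1.0

    def test_gene_set_mismatch_rejected(self):
        a = pd.Series(["DEL"], index=["x"])
        b = pd.Series(["DEL"], index=["y"])
        with pytest.raises(ValueError):
            compute_concordance(a, b)
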