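"""PTC tallies, length distributions, weighted 3'UTR shifts and subsets."""

import numpy as np
import pandas as pd
import pytest

from isoshift.orf import NO_ORF, PTC_NEGATIVE, PTC_POSITIVE
from isoshift.stats import rank_test
from isoshift.usage import (
    classify_usage_subsets,
    expression_stratified_shift,
    ptc_tally,
    summarize_length_distributions,
    usage_shift_distributions,
    weighted_utr_length,
    weighted_utr_shift_by_subset,
)


def ann_frame(classes, utr5=100, orf=300, utr3=None):
    n = len(classes)
    utr3 = utr3 if utr3 is not None else [500] * n
    idx = pd.Index([f"T{i}" for i in range(n)], name="transcript_id")
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "orf_class": classes,
            "utr5_len": float(utr5),
            "orf_len": float(orf),
            "utr3_len": np.asarray(utr3, dtype=float),
            "junction_distance": np.nan,
        },
        index=idx,
    )


class TestPtcTally:
    def test_seven_percent_of_upregulated(self):
        classes = [PTC_POSITIVE] * 137 + [PTC_NEGATIVE] * (1971 - 137)
        ann = ann_frame(classes)
        status = pd.Series("up", index=ann.index)
        tally = ptc_tally(ann, status)
        assert tally.counts.loc["up", PTC_POSITIVE] == 137
        assert tally.counts.loc["up", "total"] == 1971
        assert round(tally.pct_ptc_positive["up"]) == 7

    def test_no_ptc_anywhere_gives_zero_percent(self):
        ann = ann_frame([PTC_NEGATIVE] * 10)
        status = pd.Series(["up"] * 5 + ["down"] * 5, index=ann.index)
        tally = ptc_tally(ann, status)
        assert (tally.pct_ptc_positive == 0).all()

    def test_unlabelled_transcripts_counted_as_excluded(self):
        ann = ann_frame([PTC_NEGATIVE] * 4)
        status = pd.Series("non", index=ann.index[:2])
        tally = ptc_tally(ann, status)
        assert tally.n_excluded == 2
        assert tally.counts.loc["non", "total"] == 2


class TestLengthDistributions:
    def test_percentile_convention(self):
        ann = ann_frame([PTC_NEGATIVE] * 3, utr3=[100, 200, 300])
        groups = pd.Series("up", index=ann.index)
        summaries, _ = summarize_length_distributions(ann, groups)
        row = summaries[(summaries.group == "up") & (summaries.feature == "utr3")]
        assert row[["p25", "p50", "p75"]].to_numpy().tolist() == [[150, 200, 250]]

    def test_no_orf_transcripts_excluded(self):
        ann = ann_frame([PTC_NEGATIVE, NO_ORF])
        ann.loc[ann.orf_class == NO_ORF, ["utr5_len", "orf_len", "utr3_len"]] = np.nan
        groups = pd.Series("up", index=ann.index)
        summaries, _ = summarize_length_distributions(ann, groups)
        assert (summaries.n == 1).all()

    def test_identical_groups_give_p_one(self):
        ann = ann_frame([PTC_NEGATIVE] * 6, utr3=[1, 2, 3, 1, 2, 3])
        groups = pd.Series(["up"] * 3 + ["down"] * 3, index=ann.index)
        _, pairwise = summarize_length_distributions(ann, groups)
        utr3_row = pairwise[pairwise.feature == "utr3"]
        assert np.allclose(utr3_row["p"], 1.0)

    def test_separated_groups_exact_p(self):
        ann = ann_frame([PTC_NEGATIVE] * 6, utr3=[1, 2, 3, 4, 5, 6])
        groups = pd.Series(["down"] * 3 + ["up"] * 3, index=ann.index)
        _, pairwise = summarize_length_distributions(ann, groups)
        row = pairwise[pairwise.feature == "utr3"].iloc[0]
        assert row["p"] == pytest.approx(0.1)


class TestRankTestOracle:
    def test_exact_p_matches_enumeration_for_small_groups(self, rng, mw_oracle):
        for m in range(1, 7):
            for n in range(1, 7):
                vals = rng.permutation(np.arange(1, m + n + 1, dtype=float))
                x, y = vals[:m], vals[m:]
                _, p = rank_test(x, y)
                assert p == pytest.approx(mw_oracle(x, y), abs=1e-12)

    def test_canonical_example(self):
        _, p = rank_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)


class TestWeightedUtr:
    def test_hand_examples(self):
        assert weighted_utr_length([100, 500], [3, 1]) == pytest.approx(200)
        assert weighted_utr_length([321], [7.5]) == pytest.approx(321)
        assert weighted_utr_length(
            [100, 500], [3, 1], variant="printed_formula"
        ) == pytest.approx(100)

    def test_bounded_by_member_lengths(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 6))
            l = rng.integers(50, 3000, k).astype(float)
            e = rng.random(k) + 1e-6
            w = weighted_utr_length(l, e)
            assert l.min() - 1e-9 <= w <= l.max() + 1e-9

    def test_monotone_toward_upweighted_isoform(self, rng):
        l = np.array([100.0, 900.0, 400.0])
        e = np.array([1.0, 1.0, 1.0])
        w0 = weighted_utr_length(l, e)
        e_up = e.copy()
        e_up[1] *= 3
        assert weighted_utr_length(l, e_up) > w0  # moves toward l_1 = 900

    def test_printed_formula_is_weighted_mean_over_n(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 6))
            l = rng.integers(50, 2000, k).astype(float)
            e = rng.random(k) + 1e-6
            assert weighted_utr_length(l, e, "printed_formula") == pytest.approx(
                weighted_utr_length(l, e) / k
            )

    def test_zero_expression_rejected(self):
        with pytest.raises(ValueError):
            weighted_utr_length([100], [0.0])


def usage_frame(rows):
    """rows: (transcript_id, gene_id, if_wt, if_ko)."""
    idx = pd.Index([r[0] for r in rows], name="transcript_id")
    df = pd.DataFrame(
        {
            "gene_id": [r[1] for r in rows],
            "if_wt": [r[2] for r in rows],
            "if_ko": [r[3] for r in rows],
        },
        index=idx,
    )
    df["dif"] = df["if_ko"] - df["if_wt"]
    return df


class TestUsageSubsets:
    @pytest.mark.parametrize(
        "difs,expected",
        [
            ([0.05, -0.10], "a"),
            ([0.25, -0.25], "d"),
            ([0.20, -0.05], "b"),    # boundary: a 20% change counts
            ([-0.20, 0.05], "c"),
        ],
    )
    def test_subset_rule(self, difs, expected):
        rows = [(f"T{i}", "G1", 0.5, 0.5 + d) for i, d in enumerate(difs)]
        usage = usage_frame(rows)
        usage["dif"] = difs  # exact dIF values, immune to float rounding
        utr3 = pd.Series(100.0, index=usage.index)
        calls = classify_usage_subsets(usage, utr3, pd.Series({"G1": 10.0}))
        assert calls.loc["G1", "subset"] == expected

    def test_single_gene_weighted_shift(self):
        # isoforms l = (100, 500); expression (3,1) -> (1,3)
        usage = usage_frame([("T0", "G1", 0.75, 0.25), ("T1", "G1", 0.25, 0.75)])
        utr3 = pd.Series([100.0, 500.0], index=usage.index)
        calls = classify_usage_subsets(usage, utr3, pd.Series({"G1": 4.0}))
        assert calls.loc["G1", "weighted_utr_wt"] == pytest.approx(200)
        assert calls.loc["G1", "weighted_utr_ko"] == pytest.approx(400)
        assert calls.loc["G1", "delta_weighted_utr"] == pytest.approx(200)
        assert calls.loc["G1", "subset"] == "d"


class TestUsageShiftDistributions:
    def test_no_shift_gives_zero_mean_and_p_near_one(self):
        rows = [(f"T{i}", f"G{i}", f, f) for i, f in enumerate(np.linspace(0.1, 0.9, 12))]
        usage = usage_frame(rows)
        classes = pd.Series("both", index=usage.index)
        out = usage_shift_distributions(usage, classes)
        assert out.loc["both", "mean_dif"] == 0
        assert out.loc["both", "p"] > 0.9

    def test_constant_shift_recovered(self):
        rows = [(f"T{i}", f"G{i}", 0.3, 0.55) for i in range(8)]
        usage = usage_frame(rows)
        classes = pd.Series("KO_only", index=usage.index)
        out = usage_shift_distributions(usage, classes)
        assert out.loc["KO_only", "mean_dif"] == pytest.approx(0.25)


class TestSubsetShiftAndStratification:
    def make_calls(self, rng, n=60):
        subsets = rng.choice(["a", "b", "c", "d"], size=n, p=[0.6, 0.2, 0.1, 0.1])
        delta = np.where(
            subsets == "b", rng.normal(200, 30, n),
            np.where(subsets == "c", rng.normal(-80, 20, n), rng.normal(0, 10, n)),
        )
        return pd.DataFrame(
            {
                "subset": subsets,
                "weighted_utr_wt": 500.0,
                "weighted_utr_ko": 500.0 + delta,
                "delta_weighted_utr": delta,
                "mean_gene_expression": rng.uniform(1, 100, n),
            },
            index=pd.Index([f"G{i}" for i in range(n)], name="gene_id"),
        )

    def test_shift_by_subset_detects_planted_direction(self, rng):
        calls = self.make_calls(rng)
        summary, tests = weighted_utr_shift_by_subset(calls)
        assert summary.loc["b", "median_delta"] > 0 > summary.loc["c", "median_delta"]
        assert tests.loc["b", "p"] < 0.01

    def test_all_same_subset_when_ko_equals_wt(self):
        calls = pd.DataFrame(
            {
                "subset": ["a"] * 4,
                "weighted_utr_wt": [100.0, 200, 300, 400],
                "weighted_utr_ko": [100.0, 200, 300, 400],
                "delta_weighted_utr": [0.0] * 4,
                "mean_gene_expression": [10.0] * 4,
            },
            index=pd.Index(list("WXYZ"), name="gene_id"),
        )
        summary, tests = weighted_utr_shift_by_subset(calls)
        assert summary.loc["a", "median_delta"] == 0
        assert summary.loc["b", "n"] == 0
        assert tests.empty

    def test_degenerate_binning_reproduces_medians(self, rng):
        calls = self.make_calls(rng)
        strat = expression_stratified_shift(calls, bin_edges=(0, np.inf))
        summary, _ = weighted_utr_shift_by_subset(calls)
        for s in "abcd":
            row = strat[(strat.subset == s)].iloc[0]
            if row["n"]:
                assert row["median_delta"] == pytest.approx(
                    summary.loc[s, "median_delta"]
                )

    def test_hand_placed_bins(self):
        calls = pd.DataFrame(
            {
                "subset": ["b", "b", "b"],
                "weighted_utr_wt": [0.0] * 3,
                "weighted_utr_ko": [10.0, 30.0, 100.0],
                "delta_weighted_utr": [10.0, 30.0, 100.0],
                "mean_gene_expression": [2.0, 20.0, 30.0],
            },
            index=pd.Index(["Ga", "Gb", "Gc"], name="gene_id"),
        )
        strat = expression_stratified_shift(calls, bin_edges=(1, 5, 50, np.inf))
        low = strat[(strat.expression_bin == "[1,5)") & (strat.subset == "b")]
        mid = strat[(strat.expression_bin == "[5,50)") & (strat.subset == "b")]
        high = strat[(strat.expression_bin == "[50,inf)") & (strat.subset == "b")]
        assert low.iloc[0]["median_delta"] == 10
        assert mid.iloc[0]["median_delta"] == pytest.approx(65)
        assert high.iloc[0]["n"] == 0 and np.isnan(high.iloc[0]["median_delta"])
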