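"""Isoform-usage and 3'UTR-length shift statistics.

This module carries the analysis endpoints: PTC tallies across
differential-expression classes, UTR/ORF length-distribution comparisons,
isoform-fraction (IF) shift distributions, the 20%-dIF gene subsets, and
average weighted 3'UTR lengths with their WT->KO shifts, overall and
stratified by gene expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression import ExpressionTable, GeneExpressionTable
from .orf import NO_ORF, PTC_POSITIVE
from .stats import bh_adjust, rank_test

logger = logging.getLogger(__name__)

LENGTH_FEATURES = ("full_length", "orf", "utr5", "utr3")
SUBSETS = ("a", "b", "c", "d")
DEFAULT_BIN_EDGES = (1.0, 5.0, 50.0, np.inf)

__all__ = [
    "PtcTally",
    "ptc_tally",
    "length_feature_frame",
    "summarize_length_distributions",
    "usage_records",
    "usage_shift_distributions",
    "weighted_utr_length",
    "classify_usage_subsets",
    "weighted_utr_shift_by_subset",
    "expression_stratified_shift",
]


@dataclass
class PtcTally:
    """Contingency of DE status x ORF class with row PTC percentages."""

    counts: pd.DataFrame       # rows: up/down/non/all; cols: orf classes + total
    pct_ptc_positive: pd.Series
    n_excluded: int


def ptc_tally(annotations: pd.DataFrame, de_status: pd.Series) -> PtcTally:
    """Tally PTC-positive transcripts within each DE status group.

    ``annotations`` is the annotation frame (index transcript_id, column
    orf_class); ``de_status`` maps transcript_id -> up/down/non.
    Transcripts missing either label are excluded and counted.
    """
    df = pd.DataFrame(
        {
            "orf_class": annotations["orf_class"],
            "status": de_status.reindex(annotations.index),
        }
    )
    n_excluded = int(df.isna().any(axis=1).sum())
    df = df.dropna()
    counts = pd.crosstab(df["status"], df["orf_class"])
    counts.loc["all"] = counts.sum(axis=0)
    counts["total"] = counts.sum(axis=1)
    ptc = counts[PTC_POSITIVE] if PTC_POSITIVE in counts else pd.Series(0, index=counts.index)
    pct = 100.0 * ptc / counts["total"]
    return PtcTally(counts, pct.rename("pct_ptc_positive"), n_excluded)


def length_feature_frame(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript length features for ORF-bearing transcripts.

    Columns full_length/orf/utr5/utr3; transcripts without an ORF carry no
    defined UTR lengths and are dropped.
    """
    ann = annotations[annotations["orf_class"] != NO_ORF]
    return pd.DataFrame(
        {
            "full_length": ann["utr5_len"] + ann["orf_len"] + ann["utr3_len"],
            "orf": ann["orf_len"],
            "utr5": ann["utr5_len"],
            "utr3": ann["utr3_len"],
        },
        dtype=float,
    )


def _percentiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear interpolation between order statistics
    p25, p50, p75 = np.percentile(values, [25, 50, 75])
    return float(p25), float(p50), float(p75)


def summarize_length_distributions(
    annotations: pd.DataFrame,
    groups: pd.Series,
    transcripts: pd.Index | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percentile summaries and pairwise rank tests of length features.

    ``groups`` labels transcripts (e.g. up/down/non or the primary-
    expression classes); ``transcripts`` optionally restricts the universe
    (typically to isoforms of multi-isoform genes). Returns
    ``(summaries, pairwise)`` where pairwise holds two-sided Mann-Whitney
    p-values, raw and BH-adjusted within each feature. Groups with fewer
    than 2 transcripts are skipped from comparisons with a warning.
    """
    feats = length_feature_frame(annotations)
    if transcripts is not None:
        feats = feats.loc[feats.index.intersection(transcripts)]
    feats = feats.assign(group=groups.reindex(feats.index)).dropna(subset=["group"])

    rows, tests = [], []
    labels = sorted(feats["group"].unique())
    for feature in LENGTH_FEATURES:
        by_group = {
            g: sub[feature].dropna().to_numpy()
            for g, sub in feats.groupby("group")
        }
        for g in labels:
            v = by_group[g]
            if len(v) == 0:
                continue
            p25, p50, p75 = _percentiles(v)
            rows.append((g, feature, len(v), p25, p50, p75))
        pvals_here = []
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                va, vb = by_group[a], by_group[b]
                if len(va) < 2 or len(vb) < 2:
                    logger.warning(
                        "length comparison %s vs %s on %s skipped (n<2)",
                        a, b, feature,
                    )
                    continue
                u, p = rank_test(va, vb)
                pvals_here.append((feature, a, b, u, p))
        adj = bh_adjust([t[4] for t in pvals_here])
        tests.extend(t + (float(q),) for t, q in zip(pvals_here, adj))

    summaries = pd.DataFrame(
        rows, columns=["group", "feature", "n", "p25", "p50", "p75"]
    )
    pairwise = pd.DataFrame(
        tests, columns=["feature", "group_a", "group_b", "U", "p", "p_bh"]
    )
    return summaries, pairwise


def usage_records(
    x: ExpressionTable,
    g: GeneExpressionTable,
    genes: set[str],
    transcripts: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-transcript isoform fractions in WT and KO plus dIF = KO - WT.

    Restricted to ``genes``; when ``transcripts`` is given (typically the
    ORF-bearing isoforms) gene totals are re-summed over the included
    isoforms only, so fractions always add to 1 per gene per condition.
    Genes whose included expression is zero in either condition are
    dropped.
    """
    cm = x.condition_means()
    keep = x.gene_ids.isin(genes)
    if transcripts is not None:
        keep &= cm.index.isin(transcripts)
    cm = cm[keep]
    gid = x.gene_ids[keep]
    totals = cm.groupby(gid).sum()
    ok = set(totals.index[(totals["WT"] > 0) & (totals["KO"] > 0)])
    cm = cm[gid.isin(ok)]
    gid = gid[gid.isin(ok)]
    if_wt = cm["WT"] / gid.map(totals["WT"])
    if_ko = cm["KO"] / gid.map(totals["KO"])
    return pd.DataFrame(
        {"gene_id": gid, "if_wt": if_wt, "if_ko": if_ko, "dif": if_ko - if_wt}
    )


def usage_shift_distributions(
    usage: pd.DataFrame, classes: pd.Series
) -> pd.DataFrame:
    """dIF distribution per transcript class, with a WT-vs-KO rank test.

    For each class (e.g. primary-expression WT_only/KO_only/both) reports
    n, the mean and quartiles of dIF, and the two-sided Mann-Whitney test
    of the WT against the KO isoform-fraction distributions. Empty classes
    are skipped with a warning.
    """
    cls = classes.reindex(usage.index)
    rows = []
    for label, sub in usage.groupby(cls):
        if len(sub) == 0:
            logger.warning("usage class %s empty; skipped", label)
            continue
        p25, p50, p75 = _percentiles(sub["dif"].to_numpy())
        if len(sub) >= 2:
            u, p = rank_test(sub["if_ko"], sub["if_wt"])
        else:
            u, p = np.nan, np.nan
        rows.append(
            (label, len(sub), float(sub["dif"].mean()), p25, p50, p75, u, p)
        )
    return pd.DataFrame(
        rows,
        columns=["class", "n", "mean_dif", "p25", "p50", "p75", "U", "p"],
    ).set_index("class")


def weighted_utr_length(lengths, expressions, variant: str = "weighted_mean") -> float:
    """Average weighted 3'UTR length of one gene.

    Each isoform's 3'UTR length l_i is weighted by its isoform fraction
    e_i/e_G. The ``weighted_mean`` variant returns sum(l_i * e_i / e_G); the
    ``printed_formula`` variant additionally divides by the isoform count n.
    """
    l = np.asarray(lengths, dtype=float)
    e = np.asarray(expressions, dtype=float)
    if l.size == 0 or l.size != e.size:
        raise ValueError("lengths and expressions must be equal-length, nonempty")
    e_g = e.sum()
    if e_g <= 0:
        raise ValueError("gene expression must be positive")
    w = float(np.dot(l, e) / e_g)
    if variant == "weighted_mean":
        return w
    if variant == "printed_formula":
        return w / l.size
    raise ValueError(f"unknown variant {variant!r}")


def classify_usage_subsets(
    usage: pd.DataFrame,
    utr3_len: pd.Series,
    mean_gene_expression: pd.Series,
    threshold: float = 0.20,
    variant: str = "weighted_mean",
) -> pd.DataFrame:
    """Four-way isoform-usage subset call per gene, with weighted 3'UTRs.

    Subset a: no isoform changes its fraction by >= ``threshold``;
    b: only increases; c: only decreases; d: both directions. The average
    weighted 3'UTR length is computed per condition from the isoform
    fractions, and delta = KO - WT.
    """
    df = usage.join(utr3_len.rename("utr3_len"))
    rows = []
    for gene, sub in df.groupby("gene_id"):
        up = bool((sub["dif"] >= threshold).any())
        down = bool((sub["dif"] <= -threshold).any())
        subset = {(False, False): "a", (True, False): "b",
                  (False, True): "c", (True, True): "d"}[(up, down)]
        l = sub["utr3_len"].to_numpy(dtype=float)
        w_wt = weighted_utr_length(l, sub["if_wt"].to_numpy(), variant)
        w_ko = weighted_utr_length(l, sub["if_ko"].to_numpy(), variant)
        rows.append(
            (gene, subset, w_wt, w_ko, w_ko - w_wt,
             float(mean_gene_expression.get(gene, np.nan)))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "subset", "weighted_utr_wt", "weighted_utr_ko",
            "delta_weighted_utr", "mean_gene_expression",
        ],
    ).set_index("gene_id")


def weighted_utr_shift_by_subset(
    calls: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta-weighted-3'UTR summaries per subset and rank tests vs subset a.

    Returns ``(summary, tests)``: per-subset n and quartiles of the
    WT->KO change, and two-sided Mann-Whitney p-values (raw and BH) of
    subsets b, c, d against the no-change subset a. Tests are skipped when
    subset a is empty.
    """
    rows = []
    deltas = {
        s: calls.loc[calls["subset"] == s, "delta_weighted_utr"].to_numpy()
        for s in SUBSETS
    }
    for s in SUBSETS:
        d = deltas[s]
        if len(d) == 0:
            rows.append((s, 0, np.nan, np.nan, np.nan))
            continue
        p25, p50, p75 = _percentiles(d)
        rows.append((s, len(d), p25, p50, p75))
    summary = pd.DataFrame(
        rows, columns=["subset", "n", "p25", "median_delta", "p75"]
    ).set_index("subset")

    tests = []
    if len(deltas["a"]) >= 2:
        for s in ("b", "c", "d"):
            if len(deltas[s]) < 2:
                continue
            u, p = rank_test(deltas[s], deltas["a"])
            tests.append((s, u, p))
    else:
        logger.warning("subset a empty or too small; shift tests skipped")
    adj = bh_adjust([t[2] for t in tests])
    tests_df = pd.DataFrame(
        [t + (float(q),) for t, q in zip(tests, adj)],
        columns=["subset", "U", "p", "p_bh"],
    ).set_index("subset")
    return summary, tests_df


def expression_stratified_shift(
    calls: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Median delta-weighted-3'UTR per subset within gene-expression bins.

    Genes are binned by mean gene expression (default edges 1, 5, 50, inf,
    i.e. low / midrange / high); empty bin-subset combinations are
    reported with n = 0.
    """
    edges = list(bin_edges)
    labels = [
        f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    binned = pd.cut(
        calls["mean_gene_expression"], bins=edges, labels=labels, right=False
    )
    rows = []
    for label in labels:
        for s in SUBSETS:
            d = calls.loc[
                (binned == label) & (calls["subset"] == s),
                "delta_weighted_utr",
            ].to_numpy()
            med = float(np.median(d)) if len(d) else np.nan
            rows.append((label, s, len(d), med))
    return pd.DataFrame(
        rows, columns=["expression_bin", "subset", "n", "median_delta"]
    )
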