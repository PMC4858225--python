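"""Isoform expression tables: quantile normalization, gene aggregation,
isoform fractions, expression filters and primary-expression classes.

The table is transcripts x samples (FPKM or, after quantile normalization,
normFPKM), each sample labelled WT or KO. Condition-level expression is the
arithmetic mean over that condition's replicate columns.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .stats import bh_adjust, rank_test

logger = logging.getLogger(__name__)

CONDITIONS = ("WT", "KO")

WT_ONLY = "WT_only"
KO_ONLY = "KO_only"
BOTH = "both"
NEITHER = "neither"

DE_COLUMNS = ["log2fc", "pvalue", "fdr", "status"]

__all__ = [
    "ExpressionTable",
    "GeneExpressionTable",
    "quantile_normalize",
    "sum_gene_expression",
    "isoform_fraction",
    "filter_expressed_genes",
    "multi_isoform_genes",
    "classify_primary_expression",
    "ma_summary",
    "call_differential_expression",
    "read_de_calls",
    "write_de_calls",
    "WT_ONLY",
    "KO_ONLY",
    "BOTH",
    "NEITHER",
]


class ExpressionTable:
    """Transcripts x samples expression with gene membership.

    Parameters
    ----------
    values : DataFrame indexed by transcript_id, one column per sample.
    gene_ids : Series mapping transcript_id -> gene_id (same index).
    conditions : mapping sample name -> "WT" | "KO".
    unit_tag : "FPKM" for raw input, "normFPKM" after quantile
        normalization.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        gene_ids: pd.Series,
        conditions: Mapping[str, str],
        unit_tag: str = "FPKM",
    ):
        values = values.astype(float)
        if (values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        gene_ids = gene_ids.reindex(values.index)
        if gene_ids.isna().any():
            missing = list(values.index[gene_ids.isna()])[:5]
            raise ValueError(f"transcripts without gene_id: {missing}")
        conditions = dict(conditions)
        unknown = set(values.columns) - set(conditions)
        if unknown:
            raise ValueError(f"samples without condition label: {sorted(unknown)}")
        bad = {c for c in conditions.values() if c not in CONDITIONS}
        if bad:
            raise ValueError(f"condition labels must be WT/KO, got {sorted(bad)}")
        for cond in CONDITIONS:
            if not any(conditions[s] == cond for s in values.columns):
                raise ValueError(f"no sample labelled {cond}")
        self.values = values
        self.gene_ids = gene_ids
        self.conditions = conditions
        self.unit_tag = unit_tag

    # -- construction / IO -------------------------------------------------

    @classmethod
    def read_tsv(cls, path, samples, unit_tag: str = "FPKM") -> "ExpressionTable":
        """Read "transcript_id gene_id <sample columns>" TSV.

        ``samples`` is either a mapping sample -> condition or the path of
        a YAML sidecar holding that mapping.
        """
        if not isinstance(samples, Mapping):
            with open(samples) as fh:
                samples = yaml.safe_load(fh)
        df = pd.read_csv(path, sep="\t")
        if df.columns[0] != "transcript_id" or df.columns[1] != "gene_id":
            raise ValueError(
                f"{path}: first two columns must be transcript_id, gene_id"
            )
        df = df.set_index("transcript_id")
        return cls(df.drop(columns="gene_id"), df["gene_id"], samples, unit_tag)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene_id", self.gene_ids)
        out.to_csv(path, sep="\t")

    def write_sample_config(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.conditions), fh, sort_keys=True)

    # -- views -------------------------------------------------------------

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]

    def condition_means(self) -> pd.DataFrame:
        """Per-transcript mean expression per condition (columns WT, KO)."""
        return pd.DataFrame(
            {c: self.values[self.samples_for(c)].mean(axis=1) for c in CONDITIONS}
        )

    def n_replicates(self) -> dict[str, int]:
        return {c: len(self.samples_for(c)) for c in CONDITIONS}


class GeneExpressionTable:
    """Per-gene expression: per-sample sums and per-condition means."""

    def __init__(self, per_sample: pd.DataFrame, conditions: Mapping[str, str]):
        self.per_sample = per_sample
        self.conditions = dict(conditions)
        self.condition_means = pd.DataFrame(
            {
                c: per_sample[
                    [s for s in per_sample.columns if self.conditions[s] == c]
                ].mean(axis=1)
                for c in CONDITIONS
            }
        )

    def genes(self) -> pd.Index:
        return self.per_sample.index


def quantile_normalize(x: ExpressionTable) -> ExpressionTable:
    """Quantile-normalize samples so every column shares one distribution.

    The reference distribution is the across-sample mean of the sorted
    columns; each value is replaced by the reference value at its within-
    column rank, and tied values receive the mean of the reference values
    over their tied ranks. Output carries unit_tag "normFPKM".
    """
    if x.values.shape[1] < 2:
        raise ValueError("quantile normalization requires at least 2 samples")
    mat = x.values.to_numpy(dtype=float)
    n = mat.shape[0]
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # ties: average the reference values across each tied group
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=assigned)
        out[:, j] = sums[inverse] / counts[inverse]
    values = pd.DataFrame(out, index=x.values.index, columns=x.values.columns)
    return ExpressionTable(values, x.gene_ids, x.conditions, unit_tag="normFPKM")


def sum_gene_expression(x: ExpressionTable) -> GeneExpressionTable:
    """Sum member transcripts per sample to obtain gene expression."""
    per_sample = x.values.groupby(x.gene_ids).sum()
    per_sample.index.name = "gene_id"
    return GeneExpressionTable(per_sample, x.conditions)


def isoform_fraction(
    x: ExpressionTable,
    g: GeneExpressionTable,
    condition: str,
) -> tuple[pd.Series, set[str]]:
    """Per-transcript share of its gene's expression in one condition.

    Returns ``(fractions, excluded_genes)`` where excluded genes are those
    with zero condition-mean expression (their transcripts receive no
    fraction rather than a division by zero).
    """
    tx_mean = x.condition_means()[condition]
    gene_mean = g.condition_means[condition]
    zero = set(gene_mean.index[gene_mean == 0])
    if zero:
        logger.info(
            "isoform_fraction: %d genes with zero %s expression excluded",
            len(zero), condition,
        )
    keep = ~x.gene_ids.isin(zero)
    frac = tx_mean[keep] / x.gene_ids[keep].map(gene_mean)
    return frac, zero


def filter_expressed_genes(g: GeneExpressionTable, cutoff: float = 1.0) -> set[str]:
    """Genes whose condition-mean expression is at least ``cutoff`` in both
    conditions ("below cutoff in either condition" drops the gene)."""
    cm = g.condition_means
    keep = (cm["WT"] >= cutoff) & (cm["KO"] >= cutoff)
    return set(cm.index[keep])


def multi_isoform_genes(x: ExpressionTable, cutoff: float = 1.0) -> set[str]:
    """Genes with >= 2 isoforms expressed above ``cutoff`` in at least one
    condition mean."""
    cm = x.condition_means()
    expressed = (cm["WT"] > cutoff) | (cm["KO"] > cutoff)
    counts = expressed.groupby(x.gene_ids).sum()
    return set(counts.index[counts >= 2])


def classify_primary_expression(
    x: ExpressionTable, cutoff: float = 1.0
) -> pd.Series:
    """Primary-expression class per transcript.

    WT_only when the WT condition mean is above ``cutoff`` and the KO mean
    below it; KO_only symmetrically; both when both means exceed the
    cutoff; neither otherwise (values exactly at the cutoff never count as
    above or below).
    """
    cm = x.condition_means()
    wt, ko = cm["WT"], cm["KO"]
    cls = pd.Series(NEITHER, index=cm.index, name="primary_class")
    cls[(wt > cutoff) & (ko > cutoff)] = BOTH
    cls[(wt > cutoff) & (ko < cutoff)] = WT_ONLY
    cls[(ko > cutoff) & (wt < cutoff)] = KO_ONLY
    return cls


def ma_summary(
    x: ExpressionTable,
    annotations: pd.DataFrame,
    epsilon: float = 0.01,
    window: int = 50,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """MA coordinates per transcript plus per-ORF-class running mean of M.

    A = log2(mean expression + epsilon) over all samples; M = log2 of the
    (KO mean + epsilon)/(WT mean + epsilon) ratio. The running mean is a
    centred rolling mean of M along A within each ORF class (the "blue
    line" of an MA panel).
    """
    cm = x.condition_means()
    a = np.log2(x.values.mean(axis=1) + epsilon)
    m = np.log2((cm["KO"] + epsilon) / (cm["WT"] + epsilon))
    df = pd.DataFrame({"A": a, "M": m})
    df["orf_class"] = annotations["orf_class"].reindex(df.index)
    trends: dict[str, pd.DataFrame] = {}
    for cls, sub in df.dropna(subset=["orf_class"]).groupby("orf_class"):
        s = sub.sort_values("A")
        w = min(window, len(s))
        trends[cls] = pd.DataFrame(
            {
                "A": s["A"].to_numpy(),
                "M_mean": s["M"].rolling(w, center=True, min_periods=1).mean().to_numpy(),
            }
        )
    return df, trends


def call_differential_expression(
    x: ExpressionTable,
    alpha: float = 0.05,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Plumbing differential-expression test for synthetic exercises.

    Two-sided rank-sum test per transcript on log2-transformed replicate
    values, Benjamini-Hochberg FDR across transcripts, and status up/down
    by fold-change sign when fdr < alpha. This is a convenience for
    simulated data with enough replicates; real-data analyses should
    consume an externally produced differential-expression table instead
    (see :func:`read_de_calls`).
    """
    reps = x.n_replicates()
    if min(reps.values()) < 2:
        raise ValueError(
            "differential expression needs >= 2 replicates per condition; "
            "supply an external DE table (read_de_calls) instead"
        )
    wt_cols = x.samples_for("WT")
    ko_cols = x.samples_for("KO")
    logv = np.log2(x.values + epsilon)
    pvals = np.array(
        [
            rank_test(row[ko_cols], row[wt_cols])[1]
            for _, row in logv.iterrows()
        ]
    )
    cm = x.condition_means()
    log2fc = np.log2((cm["KO"] + epsilon) / (cm["WT"] + epsilon))
    fdr = bh_adjust(pvals)
    status = np.where(
        fdr < alpha, np.where(log2fc > 0, "up", "down"), "non"
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals, "fdr": fdr, "status": status},
        index=x.values.index,
    )


def read_de_calls(path) -> pd.DataFrame:
    """Read a "transcript_id log2fc pvalue fdr status" TSV."""
    df = pd.read_csv(path, sep="\t").set_index("transcript_id")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    return df[DE_COLUMNS]


def write_de_calls(df: pd.DataFrame, path) -> None:
    df[DE_COLUMNS].to_csv(path, sep="\t", index_label="transcript_id")
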