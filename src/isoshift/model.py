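"""Model/Results interface over the isoform-usage analysis.

:class:`IsoformUsageModel` is built from an expression table and an ORF
annotation frame (plus optional externally produced differential-expression
calls); :meth:`IsoformUsageModel.fit` runs normalization, filtering,
isoform-fraction computation and every shift statistic, returning a
:class:`UsageShiftResults` that carries the tables and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from . import expression as xm
from . import usage as us
from .orf import NO_ORF, OrfAnnotation, annotations_to_frame

__all__ = ["IsoformUsageModel", "UsageShiftResults"]


class IsoformUsageModel:
    """Isoform-usage shift analysis of a WT/KO expression experiment.

    Parameters
    ----------
    expression : ExpressionTable
        Transcript-level FPKM with WT/KO sample labels.
    annotations : DataFrame or iterable of OrfAnnotation
        Per-transcript ORF classes and UTR/ORF lengths.
    de_calls : DataFrame, optional
        External differential-expression calls (index transcript_id,
        columns log2fc/pvalue/fdr/status). When absent and the table has
        >= 2 replicates per condition the plumbing rank-sum test is used.
    cutoff : float
        Expression cutoff (FPKM/normFPKM) for the gene filter, the
        multi-isoform rule and the primary-expression classes.
    dif_threshold : float
        |dIF| needed for an isoform to count as changing (gene subsets).
    normalize : bool
        Quantile-normalize the table before analysis (units normFPKM).
    """

    def __init__(
        self,
        expression: xm.ExpressionTable,
        annotations,
        de_calls: pd.DataFrame | None = None,
        *,
        cutoff: float = 1.0,
        dif_threshold: float = 0.20,
        epsilon: float = 0.01,
        alpha: float = 0.05,
        weighted_variant: str = "weighted_mean",
        bin_edges: tuple = us.DEFAULT_BIN_EDGES,
        normalize: bool = True,
    ):
        if not isinstance(annotations, pd.DataFrame):
            annotations = annotations_to_frame(list(annotations))
        self.expression = expression
        self.annotations = annotations
        self.de_calls = de_calls
        self.cutoff = cutoff
        self.dif_threshold = dif_threshold
        self.epsilon = epsilon
        self.alpha = alpha
        self.weighted_variant = weighted_variant
        self.bin_edges = bin_edges
        self.normalize = normalize

    @classmethod
    def from_files(
        cls, expression_tsv, samples, annotation_tsv, de_tsv=None, **kwargs
    ) -> "IsoformUsageModel":
        from .orf import read_annotation_tsv

        expr = xm.ExpressionTable.read_tsv(expression_tsv, samples)
        ann = read_annotation_tsv(annotation_tsv)
        de = xm.read_de_calls(de_tsv) if de_tsv is not None else None
        return cls(expr, ann, de, **kwargs)

    def fit(self) -> "UsageShiftResults":
        x = xm.quantile_normalize(self.expression) if self.normalize else self.expression
        genes = xm.sum_gene_expression(x)

        expressed = xm.filter_expressed_genes(genes, self.cutoff)
        multi = xm.multi_isoform_genes(x, self.cutoff)
        analysis_genes = expressed & multi
        primary = xm.classify_primary_expression(x, self.cutoff)

        ann = self.annotations.reindex(x.values.index)
        orf_tx = ann.index[ann["orf_class"] != NO_ORF]

        usage = us.usage_records(x, genes, analysis_genes, transcripts=orf_tx)
        shift_by_class = us.usage_shift_distributions(usage, primary)
        length_by_class, length_tests_class = us.summarize_length_distributions(
            ann, primary, transcripts=usage.index
        )

        de = self.de_calls
        if de is None and min(x.n_replicates().values()) >= 2:
            de = xm.call_differential_expression(x, self.alpha, self.epsilon)
        if de is not None:
            tally = us.ptc_tally(ann, de["status"])
            multi_tx = ann.index[ann["gene_id"].isin(multi)]
            length_by_de, length_tests_de = us.summarize_length_distributions(
                ann, de["status"], transcripts=multi_tx
            )
        else:
            tally, length_by_de, length_tests_de = None, None, None

        # S5-style gene subsets: every ORF-bearing isoform above the cutoff
        # in both conditions, and at least two of them
        cm = x.condition_means().loc[x.values.index.intersection(orf_tx)]
        gid = x.gene_ids.loc[cm.index]
        above = (cm["WT"] > self.cutoff) & (cm["KO"] > self.cutoff)
        per_gene = above.groupby(gid).agg(["all", "sum"])
        eligible = set(
            per_gene.index[per_gene["all"] & (per_gene["sum"] >= 2)]
        ) & analysis_genes
        usage_sub = us.usage_records(x, genes, eligible, transcripts=orf_tx)
        subset_calls = us.classify_usage_subsets(
            usage_sub,
            ann["utr3_len"].astype(float),
            genes.condition_means.mean(axis=1),
            threshold=self.dif_threshold,
            variant=self.weighted_variant,
        )
        shift_summary, shift_tests = us.weighted_utr_shift_by_subset(subset_calls)
        stratified = us.expression_stratified_shift(subset_calls, self.bin_edges)

        ma, ma_trends = xm.ma_summary(x, ann, self.epsilon)

        return UsageShiftResults(
            model=self,
            normalized=x,
            gene_expression=genes,
            expressed_genes=expressed,
            multi_isoform=multi,
            analysis_genes=analysis_genes,
            primary_class=primary,
            usage=usage,
            shift_by_class=shift_by_class,
            length_by_class=length_by_class,
            length_tests_class=length_tests_class,
            de_calls=de,
            ptc_tally=tally,
            length_by_de=length_by_de,
            length_tests_de=length_tests_de,
            subset_calls=subset_calls,
            subset_shift_summary=shift_summary,
            subset_shift_tests=shift_tests,
            stratified_shift=stratified,
            ma=ma,
            ma_trends=ma_trends,
        )


@dataclass
class UsageShiftResults:
    """Fitted isoform-usage shift analysis.

    All tables are pandas objects; ``summary()`` renders the headline
    numbers (class sizes, median 3'UTR lengths, dIF shifts, subset
    counts and weighted-3'UTR changes with their rank-test p-values).
    """

    model: IsoformUsageModel
    normalized: xm.ExpressionTable
    gene_expression: xm.GeneExpressionTable
    expressed_genes: set
    multi_isoform: set
    analysis_genes: set
    primary_class: pd.Series
    usage: pd.DataFrame
    shift_by_class: pd.DataFrame
    length_by_class: pd.DataFrame
    length_tests_class: pd.DataFrame
    de_calls: pd.DataFrame | None
    ptc_tally: us.PtcTally | None
    length_by_de: pd.DataFrame | None
    length_tests_de: pd.DataFrame | None
    subset_calls: pd.DataFrame
    subset_shift_summary: pd.DataFrame
    subset_shift_tests: pd.DataFrame
    stratified_shift: pd.DataFrame
    ma: pd.DataFrame = field(repr=False, default=None)
    ma_trends: dict = field(repr=False, default=None)

    def median_utr3_by_class(self) -> pd.Series:
        sub = self.length_by_class
        s = sub[sub["feature"] == "utr3"].set_index("group")["p50"]
        return s.rename("median_utr3")

    def subset_counts(self) -> pd.Series:
        return self.subset_calls["subset"].value_counts().reindex(
            list(us.SUBSETS), fill_value=0
        )

    def summary(self) -> str:
        lines = []
        w = lines.append
        w("Isoform usage shift analysis")
        w("=" * 60)
        n_tx = self.normalized.values.shape[0]
        w(f"transcripts: {n_tx}   unit: {self.normalized.unit_tag}")
        w(
            f"genes passing {self.model.cutoff:g}-{self.normalized.unit_tag} "
            f"filter: {len(self.expressed_genes)}   multi-isoform: "
            f"{len(self.multi_isoform)}   analyzed: {len(self.analysis_genes)}"
        )
        w("")
        w("Primary-expression classes (transcripts with ORF, analyzed genes):")
        for cls, row in self.shift_by_class.iterrows():
            w(
                f"  {cls:>8}: n={int(row['n']):5d}  mean dIF={row['mean_dif']:+.3f}"
                f"  median dIF={row['p50']:+.3f}  p(WT vs KO IF)={row['p']:.3g}"
            )
        w("")
        w("Median 3'UTR length (nt) by class:")
        for cls, v in self.median_utr3_by_class().items():
            w(f"  {cls:>8}: {v:.0f}")
        if self.ptc_tally is not None:
            w("")
            w("PTC-positive fraction by DE status:")
            for st, pct in self.ptc_tally.pct_ptc_positive.items():
                n = int(self.ptc_tally.counts.loc[st, "total"])
                w(f"  {st:>5}: {pct:5.1f}% of {n}")
        w("")
        counts = self.subset_counts()
        w(
            "Gene usage subsets (|dIF| >= "
            f"{self.model.dif_threshold:g}): "
            + "  ".join(f"{s}={counts[s]}" for s in us.SUBSETS)
        )
        w("Delta weighted 3'UTR (KO - WT, nt) by subset:")
        for s, row in self.subset_shift_summary.iterrows():
            if int(row["n"]) == 0:
                w(f"  {s}: n=    0")
                continue
            line = f"  {s}: n={int(row['n']):5d}  median={row['median_delta']:+.1f}"
            if s in self.subset_shift_tests.index:
                line += f"  p vs a={self.subset_shift_tests.loc[s, 'p']:.3g}"
            w(line)
        return "\n".join(lines)

    def write_tables(self, out_dir) -> None:
        """Write every analysis table as TSV plus the text run report."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.usage.to_csv(out / "usage_records.tsv", sep="\t")
        self.shift_by_class.to_csv(out / "usage_shift_by_class.tsv", sep="\t")
        self.length_by_class.to_csv(out / "length_by_class.tsv", sep="\t", index=False)
        self.length_tests_class.to_csv(
            out / "length_tests_by_class.tsv", sep="\t", index=False
        )
        self.subset_calls.to_csv(out / "gene_subsets.tsv", sep="\t")
        self.subset_shift_summary.to_csv(out / "subset_shift_summary.tsv", sep="\t")
        self.subset_shift_tests.to_csv(out / "subset_shift_tests.tsv", sep="\t")
        self.stratified_shift.to_csv(
            out / "stratified_shift.tsv", sep="\t", index=False
        )
        if self.ptc_tally is not None:
            self.ptc_tally.counts.to_csv(out / "ptc_tally.tsv", sep="\t")
            self.length_by_de.to_csv(out / "length_by_de.tsv", sep="\t", index=False)
            self.length_tests_de.to_csv(
                out / "length_tests_by_de.tsv", sep="\t", index=False
            )
        (out / "report.txt").write_text(self.summary() + "\n")
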