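"""Self-contained synthetic scenarios with planted NMD-loss signatures.

The generator emits a genome FASTA, a reference GTF (canonical transcript
per gene with CDS and start codon), an "assembled" GTF (all isoforms, exon
features only), replicate WT/KO expression tables and a ground-truth table.

Structural model per gene: all isoforms share a 5'UTR and ORF (split over
1-4 exons); alternative-polyadenylation (APA) isoforms differ only in how
far their final exon extends into the 3' region, with one designated long
variant per multi-isoform gene. PTC-positive isoforms are 3'UTR-splice
variants: an extra exon-exon junction is placed 51-500 nt downstream of the
stop codon (the remaining 3'UTR sits in a separate downstream exon), so the
stop violates the 50-nt rule while the 3'UTR length distribution stays
exchangeable with the non-PTC isoforms.

Expression model: lognormal gene expression, Dirichlet isoform fractions;
in KO, effect genes move ``planted_dif`` of usage onto their longest-3'UTR
isoform with total gene expression conserved in expectation; multiplicative
lognormal replicate noise (unit mean) and per-sample scale factors on top.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq

from .expression import ExpressionTable
from .transcripts import (
    Exon,
    GenomeSequence,
    ReferenceCdsRecord,
    TranscriptModel,
    write_gtf,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = np.array(
    [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOPS
    ]
)

TRUTH_COLUMNS = [
    "transcript_id", "gene_id", "utr5_len", "orf_len", "utr3_len",
    "ptc", "junction_distance", "is_target", "f_wt", "f_ko",
    "gene_expression", "gene_effect", "gene_delta_weighted_utr",
]

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "Scenario",
    "simulate_annotation",
    "simulate_expression",
    "simulate_scenario",
    "write_truth",
    "read_truth",
]


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic scenario; defaults are the study-like
    conditions (two replicates per condition, 15% PTC splice variants, 20%
    effect genes shifting +0.25 isoform fraction onto long-3'UTR isoforms).
    """

    n_genes: int = 100
    min_isoforms: int = 1
    max_isoforms: int = 5
    utr5_median: float = 150.0
    utr5_sigma: float = 0.5
    utr5_min: int = 20
    orf_min_nt: int = 300
    orf_max_nt: int = 3000
    utr3_median: float = 400.0
    utr3_sigma: float = 0.7
    utr3_min: int = 60
    long_utr3_add_min: int = 500
    long_utr3_add_max: int = 2000
    ptc_isoform_fraction: float = 0.15
    ptc_distance_min: int = 51
    ptc_distance_max: int = 500
    effect_gene_fraction: float = 0.2
    planted_dif: float = 0.25
    replicates: int = 2
    noise_sigma: float = 0.2
    scale_min: float = 0.7
    scale_max: float = 1.4
    gene_expr_median: float = 8.0
    gene_expr_sigma: float = 1.2
    dirichlet_conc: float = 2.0
    max_shared_junctions: int = 3
    intron_min: int = 100
    intron_max: int = 500
    genes_per_chrom: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ptc_isoform_fraction", "effect_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 <= self.planted_dif <= 1.0:
            raise ValueError("planted_dif must be in [0,1]")
        if self.orf_min_nt % 3 or self.orf_max_nt % 3:
            raise ValueError("ORF length bounds must be multiples of 3")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per condition")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class ScenarioTruth:
    """Planted parameters, one row per transcript (gene-level fields
    repeated on each member transcript)."""

    transcripts: pd.DataFrame

    @property
    def genes(self) -> pd.DataFrame:
        g = (
            self.transcripts.groupby("gene_id")
            .agg(
                n_isoforms=("gene_id", "size"),
                effect=("gene_effect", "first"),
                gene_expression=("gene_expression", "first"),
                delta_weighted_utr=("gene_delta_weighted_utr", "first"),
            )
        )
        return g


@dataclass
class Scenario:
    config: ScenarioConfig
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    reference: list[ReferenceCdsRecord]
    truth: ScenarioTruth
    expression: ExpressionTable
    de_calls: pd.DataFrame


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_orf(rng: np.random.Generator, orf_len: int) -> str:
    """ORF of ``orf_len`` nt: ATG, non-stop codons, one stop codon."""
    m = orf_len // 3
    body = "".join(_NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS), m - 2)])
    return "ATG" + body + _STOPS[rng.integers(0, 3)]


def _lognormal(rng, median: float, sigma: float, size=None):
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def simulate_annotation(cfg: ScenarioConfig, rng: np.random.Generator | None = None):
    """Build genome, reference and assembled transcript structures.

    Returns ``(genome, transcripts, reference_records, structure)`` where
    structure is a DataFrame of per-transcript planted lengths, PTC flags
    and junction distances plus per-gene isoform bookkeeping used by
    :func:`simulate_expression`.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    chrom_parts: dict[str, list[str]] = {}
    chrom_len: dict[str, int] = {}
    transcripts: list[TranscriptModel] = []
    reference: list[ReferenceCdsRecord] = []
    rows = []

    for gi in range(cfg.n_genes):
        gene_id = f"G{gi + 1:05d}"
        chrom = f"chr{gi // cfg.genes_per_chrom + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(rng.integers(cfg.min_isoforms, cfg.max_isoforms + 1))

        utr5 = max(cfg.utr5_min, int(round(_lognormal(rng, cfg.utr5_median, cfg.utr5_sigma))))
        orf_len = int(rng.integers(cfg.orf_min_nt // 3, cfg.orf_max_nt // 3 + 1)) * 3
        len5 = utr5 + orf_len

        utr3 = np.maximum(
            cfg.utr3_min,
            np.round(_lognormal(rng, cfg.utr3_median, cfg.utr3_sigma, k)).astype(int),
        )
        long_idx = -1
        if k >= 2:
            long_idx = int(rng.integers(0, k))
            utr3[long_idx] += int(
                rng.integers(cfg.long_utr3_add_min, cfg.long_utr3_add_max + 1)
            )

        # first isoform is always the canonical, non-PTC reference structure
        ptc = np.zeros(k, dtype=bool)
        dist = np.full(k, -1, dtype=int)
        for i in range(1, k):
            d_hi = min(cfg.ptc_distance_max, int(utr3[i]) - 1)
            if rng.random() < cfg.ptc_isoform_fraction and d_hi >= cfg.ptc_distance_min:
                ptc[i] = True
                dist[i] = int(rng.integers(cfg.ptc_distance_min, d_hi + 1))

        # ---- locus layout in transcript orientation (0-based, half-open)
        n_junc = int(rng.integers(0, cfg.max_shared_junctions + 1))
        if len5 < 40 * (n_junc + 1):
            n_junc = 0
        cuts = (
            np.sort(rng.choice(np.arange(20, len5 - 20), n_junc, replace=False))
            if n_junc
            else np.array([], dtype=int)
        )

        parts: list[str] = []
        pos = 0
        mrna5 = _random_seq(rng, utr5) + _random_orf(rng, orf_len)
        spans5: list[tuple[int, int]] = []
        prev = 0
        for c in cuts:
            spans5.append((pos, pos + (c - prev)))
            parts.append(mrna5[prev:c])
            pos += c - prev
            ilen = int(rng.integers(cfg.intron_min, cfg.intron_max + 1))
            parts.append(_random_seq(rng, ilen))
            pos += ilen
            prev = int(c)
        last5_start = pos
        parts.append(mrna5[prev:])
        pos += len5 - prev
        shared3_start = pos
        shared3_len = int(max(np.where(ptc, dist, utr3)))
        shared3_seq = _random_seq(rng, shared3_len)
        parts.append(shared3_seq)
        pos += shared3_len
        ilen = int(rng.integers(cfg.intron_min, cfg.intron_max + 1))
        parts.append(_random_seq(rng, ilen))
        pos += ilen
        tail_off = {}
        tail_seq = {}
        for i in range(k):
            if ptc[i]:
                tlen = int(utr3[i]) - dist[i]
                tail_off[i] = pos
                tail_seq[i] = _random_seq(rng, tlen)
                parts.append(tail_seq[i])
                pos += tlen
        locus_len = pos
        locus_seq = "".join(parts)

        offset = chrom_len.get(chrom, 0)
        if strand == "+":
            chrom_parts.setdefault(chrom, []).append(locus_seq)
        else:
            chrom_parts.setdefault(chrom, []).append(
                str(Seq(locus_seq).reverse_complement())
            )
        chrom_parts[chrom].append(_random_seq(rng, 50))
        chrom_len[chrom] = offset + locus_len + 50

        def to_exon(span: tuple[int, int]) -> Exon:
            s, e = span
            if strand == "+":
                return Exon(chrom, offset + s + 1, offset + e, strand)
            return Exon(chrom, offset + locus_len - e + 1, offset + locus_len - s, strand)

        for i in range(k):
            tid = f"{gene_id}.{i + 1}"
            if ptc[i]:
                spans = spans5 + [
                    (last5_start, shared3_start + dist[i]),
                    (tail_off[i], tail_off[i] + int(utr3[i]) - dist[i]),
                ]
            else:
                spans = spans5 + [(last5_start, shared3_start + int(utr3[i]))]
            model = TranscriptModel(tid, gene_id, [to_exon(s) for s in spans])
            transcripts.append(model)
            jd = dist[i] if ptc[i] else (int(cuts[-1]) - len5 if n_junc else None)
            if ptc[i]:
                utr3_seq = shared3_seq[: dist[i]] + tail_seq[i]
            else:
                utr3_seq = shared3_seq[: int(utr3[i])]
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_id": gene_id,
                    "utr5_len": utr5,
                    "orf_len": orf_len,
                    "utr3_len": int(utr3[i]),
                    "ptc": bool(ptc[i]),
                    "junction_distance": jd,
                    "long_idx": long_idx,
                    "isoform_idx": i,
                    "mrna": mrna5 + utr3_seq,
                }
            )

        # reference CDS record from the canonical (first) isoform
        canonical_spans = spans5 + [(last5_start, shared3_start + int(utr3[0]))]
        cds_spans = []
        m0 = 0
        for s, e in canonical_spans:
            seg_len = e - s
            lo = max(utr5, m0)
            hi = min(len5, m0 + seg_len)
            if lo < hi:
                cds_spans.append((s + lo - m0, s + hi - m0))
            m0 += seg_len
        cds_exons = [to_exon(s) for s in cds_spans]
        start_locus = cds_spans[0][0]
        start_codon = (
            offset + start_locus + 1 if strand == "+" else offset + locus_len - start_locus
        )
        reference.append(
            ReferenceCdsRecord(f"{gene_id}.1", gene_id, cds_exons, start_codon)
        )

    genome = GenomeSequence(
        {c: "".join(parts) for c, parts in chrom_parts.items()}
    )
    structure = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "gene_id", "utr5_len", "orf_len", "utr3_len",
            "ptc", "junction_distance", "long_idx", "isoform_idx", "mrna",
        ],
    )
    logger.info(
        "simulated %d genes / %d transcripts (%d PTC-positive)",
        cfg.n_genes, len(transcripts), int(structure["ptc"].sum()),
    )
    return genome, transcripts, reference, structure


def simulate_expression(
    cfg: ScenarioConfig,
    structure: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[ExpressionTable, ScenarioTruth, pd.DataFrame]:
    """Draw expression with the planted usage shift; build truth and
    truth-derived differential-expression calls.

    The DE table is computed from the planted (noise-free) expectation —
    status up/down when the expected KO/WT fold change passes 1.5 — and
    plays the role of the externally supplied DE calls that a real-data
    run would consume.
    """
    samples = [f"WT_{r + 1}" for r in range(cfg.replicates)] + [
        f"KO_{r + 1}" for r in range(cfg.replicates)
    ]
    conditions = {s: s.split("_")[0] for s in samples}
    scales = rng.uniform(cfg.scale_min, cfg.scale_max, len(samples))

    truth_rows = []
    values = np.zeros((len(structure), len(samples)))
    row_pos = {tid: i for i, tid in enumerate(structure["transcript_id"])}

    for gene_id, sub in structure.groupby("gene_id", sort=True):
        k = len(sub)
        e_g = float(_lognormal(rng, cfg.gene_expr_median, cfg.gene_expr_sigma))
        utr3 = sub["utr3_len"].to_numpy(dtype=float)
        target = int(np.argmax(utr3)) if k >= 2 else -1
        effect = bool(k >= 2 and rng.random() < cfg.effect_gene_fraction)

        f_wt = rng.dirichlet(np.full(k, cfg.dirichlet_conc))
        if effect and cfg.planted_dif > 0:
            for _ in range(100):
                if f_wt[target] <= 1.0 - cfg.planted_dif:
                    break
                f_wt = rng.dirichlet(np.full(k, cfg.dirichlet_conc))
            else:
                raise RuntimeError(
                    f"gene {gene_id}: could not place planted dIF of "
                    f"{cfg.planted_dif} after 100 fraction draws"
                )
        f_ko = f_wt.copy()
        if effect and cfg.planted_dif > 0:
            f_ko[target] = f_wt[target] + cfg.planted_dif
            others = np.arange(k) != target
            rest = 1.0 - f_wt[target]
            if rest > 0:
                f_ko[others] = f_wt[others] * (1.0 - f_ko[target]) / rest

        delta_w = float(np.dot(utr3, f_ko - f_wt))
        for j, (_, row) in enumerate(sub.iterrows()):
            i = row_pos[row["transcript_id"]]
            for sj, s in enumerate(samples):
                f = f_ko[j] if conditions[s] == "KO" else f_wt[j]
                if cfg.noise_sigma > 0:
                    noise = float(
                        np.exp(rng.normal(-cfg.noise_sigma**2 / 2, cfg.noise_sigma))
                    )
                else:
                    noise = 1.0
                values[i, sj] = e_g * f * noise * scales[sj]
            truth_rows.append(
                {
                    "transcript_id": row["transcript_id"],
                    "gene_id": gene_id,
                    "utr5_len": row["utr5_len"],
                    "orf_len": row["orf_len"],
                    "utr3_len": row["utr3_len"],
                    "ptc": row["ptc"],
                    "junction_distance": row["junction_distance"],
                    "is_target": bool(effect and j == target),
                    "f_wt": f_wt[j],
                    "f_ko": f_ko[j],
                    "gene_expression": e_g,
                    "gene_effect": effect,
                    "gene_delta_weighted_utr": delta_w,
                }
            )

    tdf = (
        pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
        .set_index("transcript_id")
        .loc[structure["transcript_id"]]
    )
    for col in ("utr5_len", "orf_len", "utr3_len"):
        tdf[col] = tdf[col].astype("int64")
    tdf["junction_distance"] = tdf["junction_distance"].astype("Float64")
    for col in ("ptc", "is_target", "gene_effect"):
        tdf[col] = tdf[col].astype(bool)
    truth = ScenarioTruth(tdf)
    expr = ExpressionTable(
        pd.DataFrame(
            values, index=pd.Index(structure["transcript_id"], name="transcript_id"),
            columns=samples,
        ),
        pd.Series(
            structure["gene_id"].to_numpy(),
            index=pd.Index(structure["transcript_id"], name="transcript_id"),
            name="gene_id",
        ),
        conditions,
    )

    eps = 1e-9
    exp_wt = truth.transcripts["gene_expression"] * truth.transcripts["f_wt"]
    exp_ko = truth.transcripts["gene_expression"] * truth.transcripts["f_ko"]
    fold = (exp_ko + eps) / (exp_wt + eps)
    status = np.where(fold >= 1.5, "up", np.where(fold <= 1 / 1.5, "down", "non"))
    de = pd.DataFrame(
        {
            "log2fc": np.log2(fold),
            "pvalue": np.where(status == "non", 1.0, 0.0),
            "fdr": np.where(status == "non", 1.0, 0.0),
            "status": status,
        },
        index=truth.transcripts.index,
    )
    return expr, truth, de


def simulate_scenario(cfg: ScenarioConfig, out_dir=None) -> Scenario:
    """Run the full generator; optionally write all scenario files.

    Files written under ``out_dir``: genome.fa, reference.gtf,
    assembled.gtf, expression.tsv, samples.yaml, de_calls.tsv, truth.tsv
    and a scenario.yaml echo of the configuration.
    """
    rng = np.random.default_rng(cfg.seed)
    genome, transcripts, reference, structure = simulate_annotation(cfg, rng)
    expr, truth, de = simulate_expression(cfg, structure, rng)
    scenario = Scenario(cfg, genome, transcripts, reference, truth, expr, de)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        genome.to_fasta(out / "genome.fa")
        write_gtf(out / "assembled.gtf", transcripts)
        write_gtf(out / "reference.gtf", [t for t in transcripts if t.transcript_id.endswith(".1")], reference)
        expr.to_tsv(out / "expression.tsv")
        expr.write_sample_config(out / "samples.yaml")
        de.to_csv(out / "de_calls.tsv", sep="\t", index_label="transcript_id")
        write_truth(truth, out / "truth.tsv")
        cfg.to_yaml(out / "scenario.yaml")
    return scenario


def write_truth(truth: ScenarioTruth, path) -> None:
    df = truth.transcripts.copy()
    for col in ("ptc", "is_target", "gene_effect"):
        df[col] = df[col].astype(int)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="transcript_id")


def read_truth(path) -> ScenarioTruth:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id", na_values="NA")
    for col in ("ptc", "is_target", "gene_effect"):
        df[col] = df[col].astype(bool)
    df["junction_distance"] = df["junction_distance"].astype("Float64")
    return ScenarioTruth(df)
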