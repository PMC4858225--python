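"""ORF annotation and PTC classification under the 50-nt rule.

Each assembled transcript is anchored to the most upstream compatible
reference CDS start codon, the downstream reading frame is scanned to the
first in-frame stop, and the transcript is classified PTC-positive when
that stop ends more than ``ptc_distance`` (default 50) nt upstream of the
last exon-exon junction — the positional rule used by exon-junction-complex
dependent nonsense-mediated decay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .transcripts import GenomeSequence, ReferenceCdsRecord, TranscriptModel

logger = logging.getLogger(__name__)

NO_ORF = "NO_ORF"
PTC_NEGATIVE = "PTC_NEGATIVE"
PTC_POSITIVE = "PTC_POSITIVE"

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID_BASES = frozenset("ACGTN")

ANNOTATION_COLUMNS = [
    "transcript_id",
    "gene_id",
    "orf_class",
    "utr5_len",
    "orf_len",
    "utr3_len",
    "junction_distance",
]

__all__ = [
    "NO_ORF",
    "PTC_NEGATIVE",
    "PTC_POSITIVE",
    "OrfAnnotation",
    "find_compatible_cds_start",
    "scan_orf",
    "classify_ptc",
    "annotate_transcript",
    "annotate_transcripts",
    "annotations_to_frame",
    "write_annotation_tsv",
    "read_annotation_tsv",
]


@dataclass
class OrfAnnotation:
    """Per-transcript ORF coordinates, PTC class and UTR/ORF lengths.

    ``orf_len`` runs from the first base of the start codon through the
    last base of the stop codon; ``junction_distance`` is the gap (nt)
    between the end of the stop codon and the first base of the last exon,
    None for mono-exonic transcripts or when no ORF was found.
    """

    transcript_id: str
    gene_id: str
    orf_class: str
    cds_start_mrna: int | None = None
    stop_end_mrna: int | None = None
    utr5_len: int | None = None
    orf_len: int | None = None
    utr3_len: int | None = None
    junction_distance: int | None = None


def find_compatible_cds_start(
    t: TranscriptModel,
    refs: Sequence[ReferenceCdsRecord],
    scope: str = "same_gene",
) -> int | None:
    """mRNA offset of the most upstream compatible reference start codon.

    A reference start codon is compatible when its first base is exonic in
    ``t`` (maps through the spliced coordinates) with at least 3 nt of
    downstream spliced sequence. Candidates come from reference records of
    the same gene_id (``scope="same_gene"``) or all records
    (``scope="genome_wide"``); the smallest offset wins. None = no ORF.
    """
    if scope not in ("same_gene", "genome_wide"):
        raise ValueError(f"unknown scope {scope!r}")
    n = t.spliced_length()
    best: int | None = None
    for rec in refs:
        if scope == "same_gene" and rec.gene_id != t.gene_id:
            continue
        off = t.genomic_to_mrna(rec.start_codon_genomic)
        if off is None or off + 3 > n:
            continue
        if best is None or off < best:
            best = off
    return best


def scan_orf(mrna: str, start: int) -> int | None:
    """Offset one past the first in-frame stop codon from ``start``.

    Codons are read in the frame fixed by ``start``; TAA/TAG/TGA terminate.
    Codons containing N are treated as non-stop. Returns None when the
    frame runs off the 3' end without a stop.
    """
    bad = set(mrna) - _VALID_BASES
    if bad:
        raise ValueError(f"mRNA contains non-ACGTN characters: {sorted(bad)}")
    if start + 3 > len(mrna):
        raise ValueError(
            f"ORF start {start} leaves no room for a codon "
            f"(mRNA length {len(mrna)})"
        )
    for pos in range(start, len(mrna) - 2, 3):
        if mrna[pos : pos + 3] in STOP_CODONS:
            return pos + 3
    return None


def classify_ptc(
    stop_end_mrna: int,
    last_junction: int | None,
    ptc_distance: int = 50,
) -> tuple[str, int | None]:
    """PTC class and junction distance for a stop at ``stop_end_mrna``.

    PTC-positive iff a last junction exists and lies strictly more than
    ``ptc_distance`` nt downstream of the stop codon's end; a distance of
    exactly ``ptc_distance`` is PTC-negative, as is any mono-exonic
    transcript.
    """
    if last_junction is None:
        return PTC_NEGATIVE, None
    distance = last_junction - stop_end_mrna
    if distance > ptc_distance:
        return PTC_POSITIVE, distance
    return PTC_NEGATIVE, distance


def annotate_transcript(
    t: TranscriptModel,
    refs: Sequence[ReferenceCdsRecord],
    genome: GenomeSequence,
    ptc_distance: int = 50,
    scope: str = "same_gene",
) -> OrfAnnotation:
    """Full ORF/PTC annotation of one transcript.

    NO_ORF when no compatible reference start exists or the frame has no
    in-frame stop before the transcript end; such transcripts carry no
    UTR/ORF lengths and are excluded from length analyses downstream.
    """
    start = find_compatible_cds_start(t, refs, scope=scope)
    if start is None:
        return OrfAnnotation(t.transcript_id, t.gene_id, NO_ORF)
    mrna = t.extract_mrna_sequence(genome)
    stop_end = scan_orf(mrna, start)
    if stop_end is None:
        return OrfAnnotation(t.transcript_id, t.gene_id, NO_ORF)
    orf_class, distance = classify_ptc(
        stop_end, t.last_junction_mrna_pos(), ptc_distance
    )
    n = t.spliced_length()
    return OrfAnnotation(
        transcript_id=t.transcript_id,
        gene_id=t.gene_id,
        orf_class=orf_class,
        cds_start_mrna=start,
        stop_end_mrna=stop_end,
        utr5_len=start,
        orf_len=stop_end - start,
        utr3_len=n - stop_end,
        junction_distance=distance,
    )


def annotate_transcripts(
    transcripts: Iterable[TranscriptModel],
    refs: Sequence[ReferenceCdsRecord],
    genome: GenomeSequence,
    ptc_distance: int = 50,
    scope: str = "same_gene",
) -> list[OrfAnnotation]:
    refs_by_gene: dict[str, list[ReferenceCdsRecord]] = {}
    for r in refs:
        refs_by_gene.setdefault(r.gene_id, []).append(r)
    out = []
    for t in transcripts:
        pool = refs if scope == "genome_wide" else refs_by_gene.get(t.gene_id, [])
        out.append(
            annotate_transcript(t, pool, genome, ptc_distance, scope=scope)
        )
    n_orf = sum(a.orf_class != NO_ORF for a in out)
    logger.info(
        "annotated %d transcripts (%d with ORF, %d PTC-positive)",
        len(out), n_orf, sum(a.orf_class == PTC_POSITIVE for a in out),
    )
    return out


def annotations_to_frame(annotations: Iterable[OrfAnnotation]) -> pd.DataFrame:
    rows = [
        (
            a.transcript_id,
            a.gene_id,
            a.orf_class,
            a.utr5_len,
            a.orf_len,
            a.utr3_len,
            a.junction_distance,
        )
        for a in annotations
    ]
    df = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return df.set_index("transcript_id")


def write_annotation_tsv(annotations: Iterable[OrfAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", na_rep="NA")


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id", na_values="NA")
    for col in ("utr5_len", "orf_len", "utr3_len", "junction_distance"):
        df[col] = df[col].astype("Float64")
    return df
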