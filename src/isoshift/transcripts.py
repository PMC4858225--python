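"""Transcript structures and exact spliced-coordinate arithmetic.

Transcripts are exon chains on a genome. GTF coordinates are 1-based
inclusive; every mRNA (spliced) offset in this package is 0-based. Exons are
always stored in transcript (5'->3') orientation: for a minus-strand
transcript the first exon is the one with the largest genomic coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "Exon",
    "TranscriptModel",
    "ReferenceCdsRecord",
    "GenomeSequence",
    "GtfParseError",
    "InvalidTranscriptError",
    "read_gtf",
    "write_gtf",
]


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class InvalidTranscriptError(ValueError):
    """A transcript violates a structural invariant; the message names it."""


@dataclass(frozen=True)
class Exon:
    """A genomic exon, 1-based inclusive on both ends (GTF convention)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvalidTranscriptError(
                f"exon strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start > self.end:
            raise InvalidTranscriptError(
                f"exon start {self.start} > end {self.end} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


def _sort_transcript_orientation(exons: list[Exon], strand: str) -> list[Exon]:
    return sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript with gene membership.

    Exons are re-sorted into transcript orientation on construction and
    validated: shared chrom/strand, non-overlapping, strictly ordered.
    """

    transcript_id: str
    gene_id: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        if not self.exons:
            raise InvalidTranscriptError(
                f"transcript {self.transcript_id}: no exons"
            )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise InvalidTranscriptError(
                f"transcript {self.transcript_id}: exons on mixed "
                f"chromosomes {sorted(chroms)} / strands {sorted(strands)}"
            )
        self.exons = _sort_transcript_orientation(self.exons, self.strand)
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if b.start <= a.end:
                raise InvalidTranscriptError(
                    f"transcript {self.transcript_id}: overlapping or "
                    f"duplicated exons [{a.start},{a.end}] and "
                    f"[{b.start},{b.end}]"
                )

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    def spliced_length(self) -> int:
        """Total mRNA length in nt (sum of exon lengths)."""
        return sum(len(e) for e in self.exons)

    def genomic_to_mrna(self, g: int) -> int | None:
        """Map a 1-based genomic coordinate to its 0-based mRNA offset.

        Returns None when ``g`` is intronic or outside the transcript.
        """
        offset = 0
        for e in self.exons:
            if e.start <= g <= e.end:
                if self.strand == "+":
                    return offset + (g - e.start)
                return offset + (e.end - g)
            offset += len(e)
        return None

    def last_junction_mrna_pos(self) -> int | None:
        """0-based mRNA offset of the first base of the last exon.

        This is the position of the last exon-exon junction on the spliced
        transcript; None for mono-exonic transcripts (no junction).
        """
        if len(self.exons) < 2:
            return None
        return sum(len(e) for e in self.exons[:-1])

    def junction_positions(self) -> list[int]:
        """0-based mRNA offsets of the first base after each junction."""
        out, acc = [], 0
        for e in self.exons[:-1]:
            acc += len(e)
            out.append(acc)
        return out

    def extract_mrna_sequence(self, genome: "GenomeSequence") -> str:
        """Spliced mRNA sequence, minus-strand exons reverse-complemented."""
        parts = []
        for e in self.exons:
            seq = genome.fetch(e.chrom, e.start, e.end, self.transcript_id)
            if self.strand == "-":
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
        return "".join(parts)


@dataclass
class ReferenceCdsRecord:
    """CDS of a reference (annotated) transcript plus its start codon."""

    transcript_id: str
    gene_id: str
    cds_segments: list[Exon]
    start_codon_genomic: int

    def __post_init__(self) -> None:
        if not self.cds_segments:
            raise InvalidTranscriptError(
                f"reference {self.transcript_id}: empty CDS"
            )
        self.cds_segments = _sort_transcript_orientation(
            self.cds_segments, self.cds_segments[0].strand
        )
        first = self.cds_segments[0]
        if not (first.start <= self.start_codon_genomic <= first.end):
            raise InvalidTranscriptError(
                f"reference {self.transcript_id}: start codon at "
                f"{self.start_codon_genomic} outside first CDS segment "
                f"[{first.start},{first.end}]"
            )

    @property
    def strand(self) -> str:
        return self.cds_segments[0].strand


class GenomeSequence:
    """Mapping from sequence name to an A/C/G/T/N nucleotide string."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(s).upper() for name, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        records = SeqIO.parse(str(path), "fasta")
        return cls({r.id: str(r.seq) for r in records})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def names(self) -> list[str]:
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int, owner: str = "?") -> str:
        """1-based inclusive slice with bounds checking."""
        if chrom not in self._seqs:
            raise KeyError(
                f"transcript {owner}: sequence {chrom!r} not in genome"
            )
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq):
            raise IndexError(
                f"transcript {owner}: coordinates [{start},{end}] outside "
                f"{chrom} (length {len(seq)})"
            )
        return seq[start - 1 : end]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def _iter_gtf_records(path) -> Iterator[tuple[int, str, str, int, int, str, dict]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start!r}/{end!r}"
                ) from exc
            if strand not in ("+", "-"):
                raise GtfParseError(
                    f"{path}:{lineno}: strand must be '+' or '-', "
                    f"got {strand!r}"
                )
            yield lineno, chrom, feature, start_i, end_i, strand, _parse_attributes(attrs)


def read_gtf(path, mode: str = "transcripts"):
    """Read transcript models or reference CDS records from a GTF file.

    mode="transcripts"
        Groups ``exon`` features by transcript_id into TranscriptModel
        objects (sorted into transcript orientation).
    mode="reference_cds"
        Additionally groups ``CDS`` (and optional ``start_codon``) features
        into ReferenceCdsRecord objects; returns
        ``(transcripts, cds_records)``.

    Features other than exon/CDS/start_codon are skipped; unknown
    attributes are ignored. Malformed lines raise :class:`GtfParseError`
    naming the line number; transcripts with exons on mixed strands or
    chromosomes raise :class:`InvalidTranscriptError` naming the id.
    """
    if mode not in ("transcripts", "reference_cds"):
        raise ValueError(f"unknown mode {mode!r}")

    exons: dict[str, list[Exon]] = {}
    cds: dict[str, list[Exon]] = {}
    start_codons: dict[str, int] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []

    for lineno, chrom, feature, start, end, strand, attrs in _iter_gtf_records(path):
        if feature not in ("exon", "CDS", "start_codon"):
            continue
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id")
        if tid is None or gid is None:
            raise GtfParseError(
                f"{path}:{lineno}: {feature} feature lacks "
                "transcript_id/gene_id attributes"
            )
        gene_of.setdefault(tid, gid)
        exon = Exon(chrom, start, end, strand)
        if feature == "exon":
            if tid not in exons:
                order.append(tid)
            exons.setdefault(tid, []).append(exon)
        elif feature == "CDS":
            cds.setdefault(tid, []).append(exon)
        elif feature == "start_codon":
            # first base of the start codon in transcript orientation
            start_codons[tid] = start if strand == "+" else end

    transcripts = [
        TranscriptModel(tid, gene_of[tid], exons[tid]) for tid in order
    ]
    logger.info("read_gtf: parsed %d transcripts from %s", len(transcripts), path)
    if mode == "transcripts":
        return transcripts

    records: list[ReferenceCdsRecord] = []
    for tid, segments in cds.items():
        segs = _sort_transcript_orientation(segments, segments[0].strand)
        first = segs[0]
        sc = start_codons.get(
            tid, first.start if first.strand == "+" else first.end
        )
        try:
            records.append(
                ReferenceCdsRecord(tid, gene_of[tid], segs, sc)
            )
        except InvalidTranscriptError as exc:
            logger.warning(
                "read_gtf: reference %s excluded from compatible-CDS "
                "search: %s", tid, exc,
            )
    return transcripts, records


def write_gtf(
    path,
    transcripts: Iterable[TranscriptModel],
    cds_records: Iterable[ReferenceCdsRecord] = (),
    source: str = "isoshift",
) -> None:
    """Write transcripts (exon features) and optional CDS/start_codon rows.

    Exons are emitted in transcript orientation, matching what read_gtf
    reconstructs, so write/read round-trips preserve structure.
    """

    def attr(tid: str, gid: str) -> str:
        return f'gene_id "{gid}"; transcript_id "{tid}";'

    cds_by_tid = {r.transcript_id: r for r in cds_records}
    with open(path, "w") as fh:
        for t in transcripts:
            for e in t.exons:
                fh.write(
                    f"{e.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attr(t.transcript_id, t.gene_id)}\n"
                )
            rec = cds_by_tid.pop(t.transcript_id, None)
            if rec is not None:
                _write_cds(fh, rec, source, attr)
        for rec in cds_by_tid.values():
            _write_cds(fh, rec, source, attr)


def _write_cds(fh, rec: ReferenceCdsRecord, source, attr) -> None:
    a = attr(rec.transcript_id, rec.gene_id)
    for e in rec.cds_segments:
        fh.write(
            f"{e.chrom}\t{source}\tCDS\t{e.start}\t{e.end}\t.\t"
            f"{e.strand}\t.\t{a}\n"
        )
    sc = rec.start_codon_genomic
    first = rec.cds_segments[0]
    if first.strand == "+":
        s, e_ = sc, min(sc + 2, first.end)
    else:
        s, e_ = max(sc - 2, first.start), sc
    fh.write(
        f"{first.chrom}\t{source}\tstart_codon\t{s}\t{e_}\t.\t"
        f"{first.strand}\t.\t{a}\n"
    )
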