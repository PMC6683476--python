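"""Transcript-space coordinate models and interval/coverage file I/O.

All internal coordinates are 0-based half-open. GFF3/GTF input (1-based,
closed) is converted at the parsing boundary; BED and bedGraph are already
0-based half-open. A :class:`TranscriptModel` owns the genomic exon
structure of one mRNA and exposes a bijective mapping between exonic
genomic positions and offsets from the transcript 5' end, which is the
coordinate system every downstream module works in.

Conventions:

* ``cds_start_t``/``cds_end_t`` delimit the coding region *including* the
  stop codon, so the first base of the stop triplet sits at
  ``cds_end_t - 3``.
* Exons are stored sorted by genomic start; transcript orientation is
  derived from the strand.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript with transcript-space offsets.

    Parameters
    ----------
    exons
        Genomic ``(start, end)`` pairs, 0-based half-open, sorted by start,
        non-overlapping. For minus-strand transcripts position 0 of the
        transcript is the 3'-most genomic base.
    cds_start_t, cds_end_t
        Transcript-space offsets of the coding region including the stop
        codon, or ``None`` for non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple
    cds_start_t: int | None = None
    cds_end_t: int | None = None

    def __post_init__(self) -> None:
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: strand must be + or -")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise AnnotationError(f"{self.transcript_id}: bad exon [{s},{e})")
            if s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if (self.cds_start_t is None) != (self.cds_end_t is None):
            raise AnnotationError(f"{self.transcript_id}: partial CDS annotation")
        if self.cds_start_t is not None:
            if not (0 <= self.cds_start_t < self.cds_end_t <= self.length_t):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS outside transcript bounds"
                )

    @property
    def length_t(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start_t is not None

    def _oriented_exons(self):
        # Exons in transcript 5'->3' order.
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def genomic_to_transcript(self, gpos: int) -> int | None:
        """Offset from the transcript 5' end, or None if not exonic."""
        offset = 0
        for s, e in self._oriented_exons():
            if s <= gpos < e:
                return offset + (gpos - s if self.strand == "+" else e - 1 - gpos)
            offset += e - s
        return None

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic position of transcript offset ``tpos``."""
        if not (0 <= tpos < self.length_t):
            raise IndexError(f"{self.transcript_id}: offset {tpos} out of bounds")
        offset = tpos
        for s, e in self._oriented_exons():
            n = e - s
            if offset < n:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= n
        raise AssertionError("unreachable")


@dataclass
class CoverageTrack:
    """Per-nucleotide fragment counts in transcript space for one library."""

    transcript_id: str
    values: np.ndarray
    library_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("coverage values must be 1-D")
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")


# ---------------------------------------------------------------------------
# Annotation parsing
# ---------------------------------------------------------------------------


def _split_attributes(attr: str, gff3: bool) -> dict:
    out: dict[str, list[str]] = {}
    if gff3:
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            if "=" not in part:
                continue
            key, val = part.split("=", 1)
            out[key] = val.split(",")
    else:  # GTF: key "value"; pairs
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            fields = part.split(None, 1)
            if len(fields) != 2:
                continue
            key, val = fields
            out.setdefault(key, []).append(val.strip('"'))
    return out


def parse_annotation(path: str | os.PathLike) -> dict[str, TranscriptModel]:
    """Parse a GFF3 or GTF file into :class:`TranscriptModel` objects.

    Transcripts are keyed by transcript id. Transcripts without an
    annotated CDS are retained with ``cds_start_t is None`` (non-coding);
    segment/metagene callers filter on :attr:`TranscriptModel.is_coding`.

    Raises
    ------
    AnnotationError
        For a malformed line (named by line number) or a CDS that is not
        contained in the transcript's exons (named by transcript).
    """
    exon_by_tx: dict[str, list[tuple[int, int]]] = {}
    cds_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}  # tid -> (contig, strand)
    tx_parent: dict[str, str] = {}  # tid -> gene id (from mRNA features)
    gene_attr: dict[str, str] = {}  # tid -> gene_id attribute seen on records

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"line {lineno}: expected 9 tab-separated fields, got "
                    f"{len(fields)}"
                )
            contig, _src, ftype, start_s, end_s, _score, strand, _frame, attr = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationError(f"line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise AnnotationError(f"line {lineno}: invalid coordinates")
            gff3 = "=" in attr and '"' not in attr.split("=", 1)[0]
            attrs = _split_attributes(attr, gff3=gff3)
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open

            if ftype in ("mRNA", "transcript"):
                tid = (attrs.get("ID") or attrs.get("transcript_id") or [None])[0]
                parent = (attrs.get("Parent") or attrs.get("gene_id") or [None])[0]
                if tid is not None:
                    meta.setdefault(tid, (contig, strand))
                    if parent is not None:
                        tx_parent[tid] = parent
                continue
            if ftype not in ("exon", "CDS"):
                continue
            tids = attrs.get("Parent") or attrs.get("transcript_id")
            if not tids:
                raise AnnotationError(
                    f"line {lineno}: {ftype} feature lacks a transcript identifier"
                )
            gid = (attrs.get("gene_id") or [None])[0]
            for tid in tids:
                meta.setdefault(tid, (contig, strand))
                if gid is not None:
                    gene_attr.setdefault(tid, gid)
                bucket = exon_by_tx if ftype == "exon" else cds_by_tx
                bucket.setdefault(tid, []).append((start, end))

    models: dict[str, TranscriptModel] = {}
    for tid, exons in exon_by_tx.items():
        contig, strand = meta[tid]
        gene_id = gene_attr.get(tid) or tx_parent.get(tid, tid)
        exons = sorted(exons)
        model = TranscriptModel(tid, gene_id, contig, strand, tuple(exons))
        cds = sorted(cds_by_tx.get(tid, []))
        if cds:
            offsets = []
            for s, e in cds:
                t1 = model.genomic_to_transcript(s)
                t2 = model.genomic_to_transcript(e - 1)
                if t1 is None or t2 is None:
                    raise AnnotationError(f"{tid}: CDS not contained in exons")
                offsets.extend((t1, t2))
            cds_start_t, cds_end_t = min(offsets), max(offsets) + 1
            if cds_end_t - cds_start_t != sum(e - s for s, e in cds):
                raise AnnotationError(f"{tid}: CDS is not contiguous in transcript space")
            model.cds_start_t, model.cds_end_t = cds_start_t, cds_end_t
            model.__post_init__()
        models[tid] = model
    return models


def write_annotation(models: Mapping[str, TranscriptModel], path: str | os.PathLike) -> None:
    """Write transcript models as GFF3 (gene/mRNA/exon/CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tid in models:
            m = models[tid]
            span = (min(s for s, _ in m.exons) + 1, max(e for _, e in m.exons))
            attrs_gene = f"ID={m.gene_id}"
            fh.write(
                f"{m.contig}\tm6akit\tgene\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
                f"{attrs_gene}\n"
            )
            fh.write(
                f"{m.contig}\tm6akit\tmRNA\t{span[0]}\t{span[1]}\t.\t{m.strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.contig}\tm6akit\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={tid}\n"
                )
            if m.is_coding:
                # Map the transcript-space CDS (stop codon included) back to
                # genomic intervals, one per overlapped exon.
                g = sorted(
                    m.transcript_to_genomic(t)
                    for t in range(m.cds_start_t, m.cds_end_t)
                )
                runs = []
                run_start = g[0]
                prev = g[0]
                for x in g[1:]:
                    if x != prev + 1:
                        runs.append((run_start, prev + 1))
                        run_start = x
                    prev = x
                runs.append((run_start, prev + 1))
                for s, e in runs:
                    fh.write(
                        f"{m.contig}\tm6akit\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                        f"Parent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# BED / bedGraph / FASTA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid BED interval [{self.start}, {self.end})")


def read_bed(path: str | os.PathLike) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: BED needs >= 3 fields")
            rec = BedRecord(
                f[0],
                int(f[1]),
                int(f[2]),
                f[3] if len(f) > 3 else ".",
                float(f[4]) if len(f) > 4 else 0.0,
                f[5] if len(f) > 5 else ".",
            )
            records.append(rec)
    return records


def write_bed(records: Iterable[BedRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score:g}\t{r.strand}\n"
            )


def read_bedgraph(
    path: str | os.PathLike, lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Read a bedGraph into dense per-nucleotide vectors.

    ``lengths`` gives the transcript (chrom) lengths used to allocate the
    vectors; positions not covered by any run are zero. A run extending
    beyond a transcript's bounds is an error.
    """
    tracks = {tid: np.zeros(n, dtype=np.int64) for tid, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start_s, end_s, val_s = line.split("\t")
            start, end, val = int(start_s), int(end_s), float(val_s)
            if chrom not in tracks:
                raise ValueError(f"line {lineno}: unknown transcript {chrom!r}")
            if not (0 <= start < end <= len(tracks[chrom])):
                raise ValueError(
                    f"line {lineno}: coordinates [{start},{end}) out of transcript "
                    f"bounds for {chrom!r}"
                )
            tracks[chrom][start:end] = int(round(val))
    return tracks


def write_bedgraph(
    tracks: Mapping[str, np.ndarray | CoverageTrack], path: str | os.PathLike
) -> None:
    """Write dense coverage vectors as a bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for tid in tracks:
            values = tracks[tid]
            if isinstance(values, CoverageTrack):
                values = values.values
            values = np.asarray(values)
            if len(values) == 0:
                continue
            # Run-length encode equal adjacent values.
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{tid}\t{s}\t{e}\t{v:g}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
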