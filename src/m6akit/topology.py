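"""Transcript-topology analysis of peak summits.

Coding transcripts are partitioned into five non-overlapping segments —
TSS, 5'UTR, CDS, stop codon, and 3'UTR — where the stop-codon segment is
the 100-nt window centered on the first base of the stop triplet and takes
precedence over the CDS/3'UTR it straddles. The TSS segment is the first
min(100, 5'UTR length) nucleotides. Summit fractions per segment,
transcriptome-normalized relative enrichment, a three-segment rescaled
metagene profile, and per-transcript peak-count statistics complete the
topology picture of where m6A sits on mRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from m6akit.transcript_model import TranscriptModel

SEGMENTS = ("tss", "utr5", "cds", "stop_codon", "utr3")


@dataclass(frozen=True)
class SegmentPartition:
    """Five labeled, disjoint interval sets covering one transcript."""

    transcript_id: str
    length_t: int
    cds_start_t: int
    stop_base_t: int  # first base of the stop triplet
    intervals: dict  # segment -> tuple of (start, end)

    def label_of(self, pos: int) -> str:
        if not (0 <= pos < self.length_t):
            raise IndexError(f"position {pos} outside [0, {self.length_t})")
        for seg, ivals in self.intervals.items():
            for s, e in ivals:
                if s <= pos < e:
                    return seg
        raise AssertionError("partition does not cover transcript")  # pragma: no cover

    def segment_lengths(self) -> dict:
        return {
            seg: sum(e - s for s, e in ivals) for seg, ivals in self.intervals.items()
        }


def _subtract(interval: tuple[int, int], win: tuple[int, int]) -> list[tuple[int, int]]:
    s, e = interval
    ws, we = win
    pieces = []
    if s < min(e, ws):
        pieces.append((s, min(e, ws)))
    if max(s, we) < e:
        pieces.append((max(s, we), e))
    return pieces


def partition(
    model: TranscriptModel, stop_window: int = 100, tss_window: int = 100
) -> SegmentPartition:
    """Partition a coding transcript into the five topology segments.

    The stop-codon segment is ``[c - w/2, c + w/2)`` clipped to the
    transcript, with ``c`` the first base of the stop triplet; it takes
    precedence over CDS and 3'UTR (and, on very short transcripts, over
    the 5' segments). TSS covers the first ``min(tss_window, 5'UTR
    length)`` nucleotides.
    """
    if not model.is_coding:
        raise ValueError(f"{model.transcript_id}: non-coding transcript")
    length = model.length_t
    c = model.cds_end_t - 3
    half = stop_window // 2
    win = (max(0, c - half), min(length, c + (stop_window - half)))

    tss_end = min(tss_window, model.cds_start_t)
    raw = {
        "tss": (0, tss_end),
        "utr5": (tss_end, model.cds_start_t),
        "cds": (model.cds_start_t, model.cds_end_t),
        "utr3": (model.cds_end_t, length),
    }
    intervals = {seg: tuple() for seg in SEGMENTS}
    intervals["stop_codon"] = (win,) if win[0] < win[1] else tuple()
    for seg, (s, e) in raw.items():
        if s < e:
            intervals[seg] = tuple(_subtract((s, e), win))
    return SegmentPartition(
        transcript_id=model.transcript_id,
        length_t=length,
        cds_start_t=model.cds_start_t,
        stop_base_t=c,
        intervals=intervals,
    )


def assign_summits(
    summits: Iterable[tuple[str, int]], partitions: Mapping[str, SegmentPartition]
) -> tuple[dict, dict]:
    """Per-segment summit counts and fractions.

    Each ``(transcript_id, position)`` summit maps to exactly one segment;
    fractions sum to 1 when any summits are given. Summits on transcripts
    absent from ``partitions`` (e.g. non-coding) are skipped.
    """
    counts = {seg: 0 for seg in SEGMENTS}
    for tid, pos in summits:
        part = partitions.get(tid)
        if part is None:
            continue
        counts[part.label_of(pos)] += 1
    total = sum(counts.values())
    fractions = {seg: (counts[seg] / total if total else 0.0) for seg in SEGMENTS}
    return counts, fractions


def segment_nt_fractions(partitions: Mapping[str, SegmentPartition]) -> dict:
    """Fraction of transcriptome nucleotides in each segment."""
    totals = {seg: 0 for seg in SEGMENTS}
    for part in partitions.values():
        for seg, n in part.segment_lengths().items():
            totals[seg] += n
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("empty partition set")
    return {seg: totals[seg] / grand for seg in SEGMENTS}


def relative_enrichment(summit_fractions: Mapping[str, float],
                        nt_fractions: Mapping[str, float]) -> dict:
    """Summit fraction over nucleotide fraction per segment.

    Ratios near 1 mean summits fall where sequence is; ratios far above 1
    flag positional enrichment (the stop-codon signature). Segments with
    zero nucleotide share get ``nan``.
    """
    out = {}
    for seg in SEGMENTS:
        nt = nt_fractions[seg]
        out[seg] = (summit_fractions[seg] / nt) if nt > 0 else float("nan")
    return out


@dataclass(frozen=True)
class MetageneProfile:
    """Summit density over three rescaled segments (5'UTR | CDS | 3'UTR)."""

    densities: np.ndarray
    bins: tuple
    n_summits: int

    def segment_slices(self) -> dict:
        b5, bc, b3 = self.bins
        return {
            "utr5": slice(0, b5),
            "cds": slice(b5, b5 + bc),
            "utr3": slice(b5 + bc, b5 + bc + b3),
        }


def metagene(
    summits: Iterable[tuple[str, int]],
    models: Mapping[str, TranscriptModel],
    bins: tuple[int, int, int] = (30, 100, 30),
) -> MetageneProfile:
    """Metagene profile of summits over rescaled 5'UTR, CDS, and 3'UTR.

    For this profile the TSS segment counts with the 5'UTR and the
    stop-codon window is split at the stop base between CDS and 3'UTR, so
    the three rescaled segments tile the transcript. Each summit is placed
    at its fractional position within its segment; the histogram is
    normalized so the densities sum to 1.
    """
    b5, bc, b3 = bins
    counts = np.zeros(b5 + bc + b3)
    n = 0
    for tid, pos in summits:
        m = models.get(tid)
        if m is None or not m.is_coding:
            continue
        c = m.cds_end_t - 3
        bounds = [(0, m.cds_start_t, 0, b5), (m.cds_start_t, c, b5, bc),
                  (c, m.length_t, b5 + bc, b3)]
        for s, e, offset, width in bounds:
            if s <= pos < e:
                frac = (pos - s) / (e - s)
                counts[offset + min(int(frac * width), width - 1)] += 1
                n += 1
                break
    densities = counts / n if n else counts
    return MetageneProfile(densities=densities, bins=(b5, bc, b3), n_summits=n)


def peaks_per_transcript(consensus_peaks: Sequence) -> tuple[dict, float]:
    """Distribution of peak counts over m6A-containing transcripts.

    Returns fractions over the classes ``{"1", "2", "3", ">3"}`` (summing
    to 1) and the mean number of peaks per peak-containing transcript.
    """
    per_tid: dict[str, int] = {}
    for p in consensus_peaks:
        per_tid[p.transcript_id] = per_tid.get(p.transcript_id, 0) + 1
    n = len(per_tid)
    if n == 0:
        return {"1": 0.0, "2": 0.0, "3": 0.0, ">3": 0.0}, 0.0
    tallies = {"1": 0, "2": 0, "3": 0, ">3": 0}
    for count in per_tid.values():
        tallies[str(count) if count <= 3 else ">3"] += 1
    dist = {key: tally / n for key, tally in tallies.items()}
    return dist, sum(per_tid.values()) / n


def peaks_per_expressed(
    consensus_peaks: Sequence,
    fpkm: Mapping[str, float],
    fpkm_min: float = 1.0,
) -> float:
    """Consensus peaks per actively expressed transcript (FPKM >= floor)."""
    n_expressed = sum(1 for v in fpkm.values() if v >= fpkm_min)
    if n_expressed == 0:
        raise ValueError("no transcript passes the expression floor")
    return len(consensus_peaks) / n_expressed


def plot_metagene(profile: MetageneProfile, path: str) -> None:
    """Plot a metagene profile (5'UTR | CDS | 3'UTR) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(len(profile.densities))
    ax.plot(x, profile.densities, lw=1.5)
    b5, bc, _ = profile.bins
    for boundary in (b5, b5 + bc):
        ax.axvline(boundary, color="grey", ls="--", lw=0.8)
    ax.set_xticks([b5 / 2, b5 + bc / 2, b5 + bc + profile.bins[2] / 2])
    ax.set_xticklabels(["5'UTR", "CDS", "3'UTR"])
    ax.set_ylabel("summit density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
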