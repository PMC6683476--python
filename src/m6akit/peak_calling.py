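"""IP-vs-input m6A peak detection and replicate consensus.

The caller slides fixed windows over each transcript, tests every window
for IP enrichment over input with a one-sided Fisher's exact test on the
2x2 fragment-count table, controls the FDR by Benjamini-Hochberg over all
windows of all transcripts jointly, and merges significant windows into
peaks. High-confidence ("consensus") peaks are the intervals supported by
a peak in every biological replicate; their coordinates are the
intersection of the supporting replicate peaks.

The statistic deliberately works on fragment-count tables in transcript
space: window counts are exchangeable fragments, so the hypergeometric
null (Fisher) is the natural one-sided test of the IP proportion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from m6akit.transcript_model import CoverageTrack

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class Peak:
    """An IP-enriched interval on one transcript (0-based half-open)."""

    transcript_id: str
    start_t: int
    end_t: int
    summit_t: int
    enrichment: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if not (self.start_t < self.end_t):
            raise ValueError("peak start must precede end")
        if not (self.start_t <= self.summit_t < self.end_t):
            raise ValueError("summit must lie inside the peak")


@dataclass(frozen=True)
class ConsensusPeak:
    """A peak interval supported by all required replicates."""

    transcript_id: str
    start_t: int
    end_t: int
    summit_t: int
    replicate_peaks: tuple

    @property
    def p_value(self) -> float:
        return min(p.p_value for p in self.replicate_peaks)


def window_grid(length: int, window: int = 50, step: int = 25) -> list[tuple[int, int]]:
    """Window start/end pairs covering ``[0, length)``.

    Windows of width ``window`` start every ``step`` nt while they fit; a
    final truncated window is appended only when the last full window does
    not reach the transcript end. A transcript shorter than ``window``
    yields a single full-length window.
    """
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    grid = [(s, s + window) for s in starts]
    if grid[-1][1] < length:
        grid.append((length - window, length))
    return grid


def window_counts(
    ip: CoverageTrack, inp: CoverageTrack, window: int = 50, step: int = 25
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Summed IP/input fragment counts per sliding window.

    Returns ``(starts, ip_sums, input_sums)``; window ends are
    ``min(start + window, length)``.
    """
    if ip.transcript_id != inp.transcript_id:
        raise ValueError("IP and input tracks are for different transcripts")
    if len(ip.values) != len(inp.values):
        raise ValueError("IP and input tracks have different lengths")
    grid = window_grid(len(ip.values), window, step)
    cum_ip = np.concatenate(([0], np.cumsum(ip.values)))
    cum_in = np.concatenate(([0], np.cumsum(inp.values)))
    starts = np.array([s for s, _ in grid])
    ends = np.array([e for _, e in grid])
    return starts, cum_ip[ends] - cum_ip[starts], cum_in[ends] - cum_in[starts]


def test_window(
    ip_count: int, input_count: int, n_ip: int, n_in: int
) -> tuple[float, float]:
    """Enrichment and one-sided Fisher p for a single window.

    ``enrichment = ((ip + 0.5)/N_IP) / ((input + 0.5)/N_in)``; the p-value
    is the upper hypergeometric tail of the 2x2 table
    ``[[ip, N_IP - ip], [input, N_in - input]]`` (alternative: IP-enriched).
    """
    enrichment = ((ip_count + PSEUDOCOUNT) / n_ip) / ((input_count + PSEUDOCOUNT) / n_in)
    p = float(
        stats.hypergeom.sf(ip_count - 1, n_ip + n_in, ip_count + input_count, n_ip)
    )
    return enrichment, min(p, 1.0)


def _window_pvalues(
    ip_counts: np.ndarray, input_counts: np.ndarray, n_ip: int, n_in: int
) -> np.ndarray:
    """Vectorized one-sided Fisher p-values over many windows."""
    return np.minimum(
        stats.hypergeom.sf(ip_counts - 1, n_ip + n_in, ip_counts + input_counts, n_ip),
        1.0,
    )


def _summit(
    ip: CoverageTrack, inp: CoverageTrack, start: int, end: int, smooth: int = 25
) -> int:
    """Position of maximum smoothed per-nt normalized enrichment (tie: 5'-most)."""
    ip_s = ndimage.uniform_filter1d(ip.values.astype(float), smooth, mode="nearest")
    in_s = ndimage.uniform_filter1d(inp.values.astype(float), smooth, mode="nearest")
    ratio = ((ip_s[start:end] + PSEUDOCOUNT) / ip.library_size) / (
        (in_s[start:end] + PSEUDOCOUNT) / inp.library_size
    )
    return start + int(np.argmax(ratio))


def call_peaks(
    ip_tracks: Mapping[str, CoverageTrack],
    input_tracks: Mapping[str, CoverageTrack],
    alpha_fdr: float = 0.05,
    window: int = 50,
    step: int = 25,
) -> list[Peak]:
    """Call enriched peaks transcriptome-wide at BH FDR ``alpha_fdr``.

    All windows of all transcripts enter a single BH adjustment. Adjacent
    or overlapping significant windows (gap <= ``step``) merge into one
    peak whose p-value is the minimum window p (q: the BH value of that
    window) and whose summit is the maximum of the smoothed per-nucleotide
    normalized IP/input ratio.
    """
    tids, all_starts, all_ends, all_ip, all_in = [], [], [], [], []
    for tid, ip in ip_tracks.items():
        inp = input_tracks[tid]
        starts, ip_sums, in_sums = window_counts(ip, inp, window, step)
        ends = np.minimum(starts + window, len(ip.values))
        tids.extend([tid] * len(starts))
        all_starts.append(starts)
        all_ends.append(ends)
        all_ip.append(ip_sums)
        all_in.append(in_sums)
    if not tids:
        return []
    starts = np.concatenate(all_starts)
    ends = np.concatenate(all_ends)
    ip_sums = np.concatenate(all_ip).astype(np.int64)
    in_sums = np.concatenate(all_in).astype(np.int64)
    any_tid = next(iter(ip_tracks))
    n_ip = ip_tracks[any_tid].library_size
    n_in = input_tracks[any_tid].library_size

    pvals = _window_pvalues(ip_sums, in_sums, n_ip, n_in)
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha_fdr, method="fdr_bh")

    peaks: list[Peak] = []
    tid_arr = np.array(tids)
    for tid in ip_tracks:
        mask = (tid_arr == tid) & reject
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        order = idx[np.argsort(starts[idx], kind="stable")]
        # Merge windows whose gap is at most `step`.
        groups: list[list[int]] = [[order[0]]]
        for i in order[1:]:
            if starts[i] <= ends[groups[-1][-1]] + step:
                groups[-1].append(i)
            else:
                groups.append([i])
        ip, inp = ip_tracks[tid], input_tracks[tid]
        for grp in groups:
            s = int(min(starts[i] for i in grp))
            e = int(max(ends[i] for i in grp))
            best = min(grp, key=lambda i: (pvals[i], starts[i]))
            ip_sum = int(ip.values[s:e].sum())
            in_sum = int(inp.values[s:e].sum())
            enr = ((ip_sum + PSEUDOCOUNT) / n_ip) / ((in_sum + PSEUDOCOUNT) / n_in)
            peaks.append(
                Peak(
                    transcript_id=tid,
                    start_t=s,
                    end_t=e,
                    summit_t=_summit(ip, inp, s, e),
                    enrichment=float(enr),
                    p_value=float(pvals[best]),
                    q_value=float(qvals[best]),
                )
            )
    return peaks


def consensus(
    peak_sets: Sequence[Sequence[Peak]], min_replicates: int | None = None
) -> list[ConsensusPeak]:
    """Replicate-consensus peaks by interval intersection.

    A consensus peak is emitted for every maximal interval covered by
    peaks from at least ``min_replicates`` distinct replicates (default:
    all). With all replicates required and non-overlapping peaks within
    each replicate, these intervals are exactly the non-empty
    intersections of one peak per replicate. The consensus summit is that
    of the supporting replicate peak with the smallest p-value (tie:
    5'-most summit). Output is invariant to replicate ordering.
    """
    if len(peak_sets) < 2:
        raise ValueError("consensus requires at least two replicate peak sets")
    k = len(peak_sets) if min_replicates is None else min_replicates
    by_tid: dict[str, list[tuple[int, int, int, Peak]]] = {}
    for rep, peaks in enumerate(peak_sets):
        for p in peaks:
            by_tid.setdefault(p.transcript_id, []).append((p.start_t, p.end_t, rep, p))

    out: list[ConsensusPeak] = []
    for tid in sorted(by_tid):
        entries = by_tid[tid]
        # Sweep over breakpoints, tracking how many distinct replicates
        # cover each elementary interval.
        points = sorted({x for s, e, _, _ in entries for x in (s, e)})
        runs: list[tuple[int, int]] = []
        for a, b in zip(points[:-1], points[1:]):
            reps_here = {rep for s, e, rep, _ in entries if s <= a and b <= e}
            if len(reps_here) >= k:
                if runs and runs[-1][1] == a:
                    runs[-1] = (runs[-1][0], b)
                else:
                    runs.append((a, b))
        for s, e in runs:
            support = tuple(
                p for ps, pe, _, p in sorted(entries, key=lambda t: (t[0], t[1]))
                if ps < e and pe > s
            )
            best = min(support, key=lambda p: (p.p_value, p.summit_t))
            out.append(
                ConsensusPeak(
                    transcript_id=tid,
                    start_t=s,
                    end_t=e,
                    summit_t=best.summit_t,
                    replicate_peaks=support,
                )
            )
    return out


def replicate_correlation(
    replicates: Sequence, window: int = 50, step: int = 25
) -> np.ndarray:
    """Pearson r matrix between replicates over log-transformed counts.

    Each replicate may be a mapping of transcript id to
    :class:`CoverageTrack` (windowed counts are used) or a bare count
    vector. Counts are log-transformed with pseudocount 1 before
    correlation.
    """
    vectors = []
    for rep in replicates:
        if isinstance(rep, Mapping):
            parts = []
            for tid in sorted(rep):
                track = rep[tid]
                grid = window_grid(len(track.values), window, step)
                cum = np.concatenate(([0], np.cumsum(track.values)))
                parts.append(
                    cum[[e for _, e in grid]] - cum[[s for s, _ in grid]]
                )
            vectors.append(np.concatenate(parts))
        else:
            vectors.append(np.asarray(rep, dtype=float))
    mat = np.log1p(np.vstack(vectors))
    return np.corrcoef(mat)
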