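"""k-mer motif enrichment in peak sequences.

Target sequences are the peak subsequences of the transcriptome; the
background is the exonic sequence with peak intervals excised, chopped
into peak-length-matched fragments. Each k-mer is scored by the number of
sequences containing at least one occurrence (zero-or-one-per-sequence
counting) and tested with a hypergeometric upper tail over the pooled
sequence population, with Benjamini-Hochberg adjustment across all 4^k
k-mers. Sequence-level counting keeps the sampling unit exchangeable and
sidesteps within-sequence occurrence dependence.

Sequences are handled in the RNA alphabet (T is mapped to U on input).
The plant m6A consensus UGUAYY (IUPAC Y = C or U) is the expected top hit
on methylated-peak sequences.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RNA_ALPHABET = "ACGU"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def match_pattern(kmer: str, iupac_pattern: str) -> bool:
    """True if ``kmer`` matches the IUPAC degenerate ``iupac_pattern``."""
    kmer = to_rna(kmer)
    pattern = to_rna(iupac_pattern)
    if len(kmer) != len(pattern):
        return False
    return all(base in IUPAC[sym] for base, sym in zip(kmer, pattern))


def expand_pattern(iupac_pattern: str) -> list[str]:
    """All concrete RNA k-mers matching an IUPAC pattern."""
    choices = [IUPAC[sym] for sym in to_rna(iupac_pattern)]
    return ["".join(p) for p in itertools.product(*choices)]


def build_sequence_sets(
    peaks: Sequence,
    sequences: Mapping[str, str],
    fragment_length: int | None = None,
    min_len: int = 6,
) -> tuple[list[str], list[str]]:
    """Target (peak) and background (peak-excised exonic) sequence sets.

    Background fragments are length-matched to the peaks: the non-peak
    runs of every transcript are chopped into pieces of the median peak
    length (or ``fragment_length``; 150 nt when there are no peaks), and
    pieces shorter than ``min_len`` are dropped. No peak base reaches the
    background.
    """
    by_tid: dict[str, list[tuple[int, int]]] = {}
    lengths = []
    for p in peaks:
        tid, s, e = p.transcript_id, p.start_t, p.end_t
        if tid not in sequences:
            raise ValueError(f"peak on unknown transcript {tid!r}")
        if not (0 <= s < e <= len(sequences[tid])):
            raise ValueError(
                f"peak [{s},{e}) outside transcript {tid!r} "
                f"(length {len(sequences[tid])})"
            )
        by_tid.setdefault(tid, []).append((s, e))
        lengths.append(e - s)

    if fragment_length is None:
        fragment_length = int(statistics.median(lengths)) if lengths else 150
    fragment_length = max(fragment_length, min_len)

    targets: list[str] = []
    background: list[str] = []
    for tid in sequences:
        seq = to_rna(sequences[tid])
        ivals = sorted(by_tid.get(tid, []))
        pos = 0
        runs = []
        for s, e in ivals:
            if pos < s:
                runs.append(seq[pos:s])
            targets.append(seq[s:e])
            pos = max(pos, e)
        if pos < len(seq):
            runs.append(seq[pos:])
        for run in runs:
            for i in range(0, len(run), fragment_length):
                frag = run[i : i + fragment_length]
                if len(frag) >= min_len:
                    background.append(frag)
    return targets, background


def _presence_counts(seqs: Iterable[str], k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        seen = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for kmer in seen:
            if all(b in RNA_ALPHABET for b in kmer):
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


@dataclass(frozen=True)
class KmerResult:
    kmer: str
    target_count: int
    background_count: int
    p_value: float
    q_value: float
    rank: int


def kmer_enrichment(
    targets: Sequence[str], background: Sequence[str], k: int = 6
) -> pd.DataFrame:
    """Rank all 4^k RNA k-mers by target-set enrichment.

    For each k-mer the number of target and background sequences
    containing it forms a 2x2 table; ``p`` is the hypergeometric upper
    tail of drawing the observed number of k-mer-containing sequences in
    the target draw, and ``q`` the BH adjustment over all 4^k k-mers.
    Result is sorted by (p, kmer) so ranking is deterministic and
    independent of input order.
    """
    targets = [to_rna(s) for s in targets]
    background = [to_rna(s) for s in background]
    n_t, n_b = len(targets), len(background)
    t_counts = _presence_counts(targets, k)
    b_counts = _presence_counts(background, k)

    kmers = ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=k)]
    x = np.array([t_counts.get(m, 0) for m in kmers])
    b = np.array([b_counts.get(m, 0) for m in kmers])
    M, n = n_t + n_b, n_t
    pvals = np.minimum(stats.hypergeom.sf(x - 1, M, x + b, n), 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")

    df = pd.DataFrame(
        {
            "kmer": kmers,
            "target_count": x,
            "background_count": b,
            "p_value": pvals,
            "q_value": qvals,
        }
    )
    df = df.sort_values(["p_value", "kmer"], kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
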