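"""Differential expression, differential m6A, and their quadrant integration.

Expression is quantified as FPKM (fragments per kilobase of exon per
million mapped fragments); differential expression between two
three-replicate conditions uses a Welch t-test on log2(FPKM + 1) with
Benjamini-Hochberg adjustment and the fold-change >= 1.5 / P < 0.05 rule.
Differential m6A per consensus peak compares replicate-summed IP/input
count tables between conditions with a two-sided Fisher's exact test and
the same significance rule on the enrichment fold change. The quadrant
table cross-tabulates m6A direction against expression direction at
transcript level, which is where the negative m6A-expression coupling
shows up.

The Welch-on-log-FPKM statistic is a deliberately simple replicate-aware
stand-in for a full count-model fit; the Fisher 2x2 form of the m6A test
likewise works directly on the count tables the peak caller produces.
Pseudocount 0.5 is used wherever a ratio is formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from m6akit.transcript_model import CoverageTrack

PSEUDOCOUNT = 0.5


def fpkm(fragment_count: float, exonic_length_nt: int, mapped_fragments: int) -> float:
    """FPKM = count / ((length/1e3) * (mapped/1e6))."""
    if exonic_length_nt <= 0:
        raise ValueError("exonic length must be positive")
    if mapped_fragments <= 0:
        raise ValueError("mapped fragment total must be positive")
    return fragment_count / ((exonic_length_nt / 1e3) * (mapped_fragments / 1e6))


def fpkm_matrix(
    counts: pd.DataFrame, lengths: Mapping[str, int], mapped: Sequence[int]
) -> pd.DataFrame:
    """FPKM table from a genes x replicates count table."""
    lens = np.array([lengths[g] for g in counts.index], dtype=float)
    mapped = np.asarray(mapped, dtype=float)
    return counts / (lens[:, None] / 1e3) / (mapped[None, :] / 1e6)


def differential_expression(
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential expression between conditions A and B.

    Welch's two-sided t-test on log2(FPKM + 1) across replicates, BH over
    genes; a gene is significant iff p < ``alpha`` and
    max(FC, 1/FC) >= ``fc_min`` where FC is the pseudocounted B/A mean
    ratio (the boundary FC == fc_min counts). Degenerate rows with zero
    variance in both conditions and equal means get p = 1.
    """
    genes = fpkm_a.index
    if not genes.equals(fpkm_b.index):
        raise ValueError("condition tables must share the same gene index")
    a = np.log2(fpkm_a.to_numpy(dtype=float) + 1.0)
    b = np.log2(fpkm_b.to_numpy(dtype=float) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    mean_a = fpkm_a.mean(axis=1).to_numpy()
    mean_b = fpkm_b.mean(axis=1).to_numpy()
    fc = (mean_b + PSEUDOCOUNT) / (mean_a + PSEUDOCOUNT)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    magnitude = np.maximum(fc, 1.0 / fc)
    significant = (p < alpha) & (magnitude >= fc_min)
    return pd.DataFrame(
        {
            "mean_fpkm_a": mean_a,
            "mean_fpkm_b": mean_b,
            "fold_change": fc,
            "log2_fold_change": np.log2(fc),
            "p_value": p,
            "q_value": q,
            "significant": significant,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=genes,
    )


@dataclass(frozen=True)
class PeakCounts:
    """Replicate-summed IP/input fragment counts for one peak, one condition."""

    ip: int
    input: int
    n_ip: int
    n_in: int


def _peak_counts(
    peak, ip_tracks: Mapping[str, CoverageTrack], in_tracks: Mapping[str, CoverageTrack]
) -> PeakCounts:
    ip = ip_tracks[peak.transcript_id]
    inp = in_tracks[peak.transcript_id]
    return PeakCounts(
        ip=int(ip.values[peak.start_t : peak.end_t].sum()),
        input=int(inp.values[peak.start_t : peak.end_t].sum()),
        n_ip=ip.library_size,
        n_in=inp.library_size,
    )


def differential_m6a(
    peaks: Sequence,
    ip_a: Mapping[str, CoverageTrack],
    in_a: Mapping[str, CoverageTrack],
    ip_b: Mapping[str, CoverageTrack],
    in_b: Mapping[str, CoverageTrack],
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential m6A per peak between conditions A and B.

    Enrichment per condition is the pseudocounted, library-normalized
    IP/input ratio over the peak interval; FC = enrichment_B/enrichment_A;
    p is the two-sided Fisher's exact test on the counts table
    [[IP_A, in_A], [IP_B, in_B]]. Significant iff p < ``alpha`` and
    max(FC, 1/FC) >= ``fc_min``. Direction "up" means more methylated in
    condition B.
    """
    rows = []
    for i, peak in enumerate(peaks):
        ca = _peak_counts(peak, ip_a, in_a)
        cb = _peak_counts(peak, ip_b, in_b)
        enr_a = ((ca.ip + PSEUDOCOUNT) / ca.n_ip) / ((ca.input + PSEUDOCOUNT) / ca.n_in)
        enr_b = ((cb.ip + PSEUDOCOUNT) / cb.n_ip) / ((cb.input + PSEUDOCOUNT) / cb.n_in)
        fc = enr_b / enr_a
        _, p = stats.fisher_exact([[ca.ip, ca.input], [cb.ip, cb.input]])
        magnitude = max(fc, 1.0 / fc)
        rows.append(
            {
                "peak_id": f"{peak.transcript_id}:{peak.start_t}-{peak.end_t}",
                "transcript_id": peak.transcript_id,
                "start_t": peak.start_t,
                "end_t": peak.end_t,
                "enrichment_a": enr_a,
                "enrichment_b": enr_b,
                "fold_change": fc,
                "log2_fold_change": float(np.log2(fc)),
                "p_value": float(p),
                "significant": bool(p < alpha and magnitude >= fc_min),
                "direction": "up" if fc >= 1.0 else "down",
            }
        )
    columns = [
        "peak_id", "transcript_id", "start_t", "end_t", "enrichment_a",
        "enrichment_b", "fold_change", "log2_fold_change", "p_value",
        "significant", "direction",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class QuadrantTable:
    """Counts of transcripts in {m6A up, down} x {expr up, down, unchanged}."""

    counts: pd.DataFrame  # index: m6a_up/m6a_down; columns: up/down/unchanged

    @property
    def n_transcripts(self) -> int:
        return int(self.counts.to_numpy().sum())

    def negative_association_pvalue(self) -> float:
        """One-sided sign test for the negative m6A-expression coupling.

        Concordant-negative pairs (m6A up & expression down, or m6A down &
        expression up) are tested against discordant pairs with a one-sided
        binomial; transcripts with unchanged expression are uninformative.
        """
        c = self.counts
        concordant = int(c.loc["m6a_up", "down"] + c.loc["m6a_down", "up"])
        discordant = int(c.loc["m6a_up", "up"] + c.loc["m6a_down", "down"])
        n = concordant + discordant
        if n == 0:
            return 1.0
        return float(stats.binomtest(concordant, n, 0.5, alternative="greater").pvalue)


def quadrants(diff_m6a: pd.DataFrame, diff_expr: pd.DataFrame) -> QuadrantTable:
    """Cross-tabulate differential m6A against expression at transcript level.

    Only significant m6A peaks enter; a transcript with several keeps its
    most significant peak (smallest p, tie: largest \\|log2 FC\\|). The
    expression stratum is up/down for significant expression calls and
    "unchanged" otherwise (including transcripts absent from the
    expression table).
    """
    table = pd.DataFrame(
        0,
        index=["m6a_up", "m6a_down"],
        columns=["up", "down", "unchanged"],
        dtype=int,
    )
    sig = diff_m6a[diff_m6a["significant"]]
    if len(sig):
        sig = sig.assign(_abs_lfc=sig["log2_fold_change"].abs())
        sig = sig.sort_values(
            ["p_value", "_abs_lfc"], ascending=[True, False], kind="stable"
        )
        best = sig.drop_duplicates("transcript_id", keep="first")
        for _, row in best.iterrows():
            tid = row["transcript_id"]
            if tid in diff_expr.index and bool(diff_expr.loc[tid, "significant"]):
                stratum = str(diff_expr.loc[tid, "direction"])
            else:
                stratum = "unchanged"
            table.loc[f"m6a_{row['direction']}", stratum] += 1
    return QuadrantTable(counts=table)
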