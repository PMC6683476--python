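"""End-to-end pipeline: simulate -> peaks -> consensus -> topology ->
motif -> differential -> quadrants, with a machine-readable report.

The report is a plain JSON-serializable dict of per-stage counts and
metrics; its SHA-256 hash over the canonical JSON encoding doubles as a
determinism check (two runs with the same config/seed hash identically).
Truth-recovery metrics against the simulator's planted sites are included
so calibration and power can be read off a single run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from m6akit import differential, motif, peak_calling, synthetic_data, topology
from m6akit.synthetic_data import SimulationConfig, TruthTable
from m6akit.transcript_model import BedRecord, write_bed


@dataclass(frozen=True)
class Region:
    """A bare transcript interval (used for merged peak regions)."""

    transcript_id: str
    start_t: int
    end_t: int


def merge_regions(peak_lists: Sequence[Sequence]) -> list[Region]:
    """Union of peak intervals across lists, merged per transcript."""
    by_tid: dict[str, list[tuple[int, int]]] = {}
    for peaks in peak_lists:
        for p in peaks:
            by_tid.setdefault(p.transcript_id, []).append((p.start_t, p.end_t))
    regions = []
    for tid in sorted(by_tid):
        merged: list[list[int]] = []
        for s, e in sorted(by_tid[tid]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        regions.extend(Region(tid, s, e) for s, e in merged)
    return regions


def evaluate_recovery(
    consensus_peaks: Sequence,
    truth: TruthTable,
    stoich_column: str = "stoich_a",
    window: int = 50,
) -> dict:
    """Sensitivity/precision of consensus peaks against planted sites.

    A site counts as recovered when a consensus peak overlaps its
    ``[pos - window, pos + window)`` footprint; a peak counts as true when
    it overlaps any site footprint. Summit accuracy is the fraction of
    matched peaks whose summit lies within ``window`` nt of the site.
    """
    sites = truth.sites
    sites_by_tid: dict[str, list[int]] = {}
    for _, row in sites.iterrows():
        sites_by_tid.setdefault(row["transcript_id"], []).append(int(row["position"]))

    n_sites = len(sites)
    recovered = 0
    for _, row in sites.iterrows():
        pos = int(row["position"])
        hit = any(
            p.start_t < pos + window and p.end_t > pos - window
            for p in consensus_peaks
            if p.transcript_id == row["transcript_id"]
        )
        recovered += bool(hit)

    true_peaks = 0
    summit_ok = 0
    for p in consensus_peaks:
        positions = sites_by_tid.get(p.transcript_id, [])
        matches = [x for x in positions if p.start_t < x + window and p.end_t > x - window]
        if matches:
            true_peaks += 1
            nearest = min(matches, key=lambda x: abs(x - p.summit_t))
            summit_ok += abs(nearest - p.summit_t) <= window
    n_peaks = len(consensus_peaks)
    return {
        "n_sites": n_sites,
        "n_peaks": n_peaks,
        "sensitivity": recovered / n_sites if n_sites else float("nan"),
        "precision": true_peaks / n_peaks if n_peaks else float("nan"),
        "summit_within_window": summit_ok / true_peaks if true_peaks else float("nan"),
    }


def evaluate_differential(dm: pd.DataFrame, truth: TruthTable, window: int = 50) -> dict:
    """Recovery of planted differential-methylation sites.

    A planted site is detected when a significant differential peak
    overlaps its footprint; among detections, the direction must match
    the planted direction.
    """
    sig = dm[dm["significant"]]
    planted = truth.sites[truth.sites["direction"].isin(["up", "down"])]
    detected = 0
    correct = 0
    for _, row in planted.iterrows():
        pos = int(row["position"])
        hits = sig[
            (sig["transcript_id"] == row["transcript_id"])
            & (sig["start_t"] < pos + window)
            & (sig["end_t"] > pos - window)
        ]
        if len(hits):
            detected += 1
            best = hits.sort_values("p_value", kind="stable").iloc[0]
            correct += best["direction"] == row["direction"]
    return {
        "n_planted": int(len(planted)),
        "n_detected": detected,
        "sensitivity": detected / len(planted) if len(planted) else float("nan"),
        "direction_accuracy": correct / detected if detected else float("nan"),
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def report_hash(report: Mapping) -> str:
    payload = json.dumps(report, sort_keys=True, default=_json_default)
    return hashlib.sha256(payload.encode()).hexdigest()


def peaks_to_frame(peaks: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": p.transcript_id,
                "start_t": p.start_t,
                "end_t": p.end_t,
                "summit_t": p.summit_t,
                "enrichment": getattr(p, "enrichment", float("nan")),
                "p_value": getattr(p, "p_value", float("nan")),
                "q_value": getattr(p, "q_value", float("nan")),
            }
            for p in peaks
        ],
        columns=["transcript_id", "start_t", "end_t", "summit_t", "enrichment",
                 "p_value", "q_value"],
    )


def frame_to_peaks(df: pd.DataFrame) -> list[peak_calling.Peak]:
    return [
        peak_calling.Peak(
            transcript_id=str(r["transcript_id"]),
            start_t=int(r["start_t"]),
            end_t=int(r["end_t"]),
            summit_t=int(r["summit_t"]),
            enrichment=float(r.get("enrichment", float("nan"))),
            p_value=float(r.get("p_value", float("nan"))),
            q_value=float(r.get("q_value", float("nan"))),
        )
        for _, r in df.iterrows()
    ]


def peaks_to_bed(peaks: Sequence, path) -> None:
    """Write peaks as BED6: name = transcript:rank, score = -10*log10(q)."""
    ranks: dict[str, int] = {}
    records = []
    for p in sorted(peaks, key=lambda p: (p.transcript_id, p.start_t)):
        ranks[p.transcript_id] = ranks.get(p.transcript_id, 0) + 1
        q = getattr(p, "q_value", float("nan"))
        score = -10.0 * np.log10(max(q, 1e-30)) if np.isfinite(q) else 0.0
        records.append(
            BedRecord(
                chrom=p.transcript_id, start=p.start_t, end=p.end_t,
                name=f"{p.transcript_id}:{ranks[p.transcript_id]}",
                score=round(float(score), 3), strand="+",
            )
        )
    write_bed(records, path)


def run(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    alpha_fdr: float = 0.05,
    fc_min: float = 1.5,
    alpha_diff: float = 0.05,
    motif_k: int = 6,
) -> dict:
    """Run the full synthetic-data pipeline and return the report dict.

    Stages: simulate both conditions and all replicates; call peaks per
    replicate and form per-condition consensus sets; topology and motif
    analysis on the condition-A consensus; FPKM and differential
    expression from the input libraries; differential m6A over the merged
    consensus regions; quadrant integration; truth-recovery metrics.
    When ``outdir`` is given, per-stage TSV/BED outputs and
    ``report.json`` are written there.
    """
    t0 = time.time()
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.time()

    stage("simulate")
    models, sequences, truth, data = synthetic_data.simulate_dataset(config)
    timings["simulate"] = time.time() - timings["simulate"]

    stage("peaks")
    peak_sets: dict[str, list] = {}
    consensus_sets: dict[str, list] = {}
    for cond in ("A", "B"):
        reps = []
        for rep in range(1, config.n_replicates + 1):
            ip, inp = data[(cond, rep)]
            reps.append(peak_calling.call_peaks(ip, inp, alpha_fdr=alpha_fdr))
        peak_sets[cond] = reps
        consensus_sets[cond] = peak_calling.consensus(reps)
    timings["peaks"] = time.time() - timings["peaks"]
    report["stages"]["peaks"] = {
        "replicate_peaks": {c: [len(r) for r in peak_sets[c]] for c in peak_sets},
        "consensus_peaks": {c: len(consensus_sets[c]) for c in consensus_sets},
    }

    stage("topology")
    partitions = {
        tid: topology.partition(m) for tid, m in models.items() if m.is_coding
    }
    summits = [(p.transcript_id, p.summit_t) for p in consensus_sets["A"]]
    counts, fractions = topology.assign_summits(summits, partitions)
    nt_fractions = topology.segment_nt_fractions(partitions)
    enrichment = topology.relative_enrichment(fractions, nt_fractions)
    profile = topology.metagene(summits, models)
    dist, mean_peaks = topology.peaks_per_transcript(consensus_sets["A"])
    timings["topology"] = time.time() - timings["topology"]
    report["stages"]["topology"] = {
        "summit_fractions": fractions,
        "segment_nt_fractions": nt_fractions,
        "relative_enrichment": enrichment,
        "peaks_per_transcript": dist,
        "mean_peaks_per_m6a_transcript": mean_peaks,
        "metagene_n_summits": profile.n_summits,
    }

    stage("motif")
    targets, background = motif.build_sequence_sets(consensus_sets["A"], sequences)
    kmers = motif.kmer_enrichment(targets, background, k=motif_k)
    top = kmers.iloc[0] if len(kmers) else None
    timings["motif"] = time.time() - timings["motif"]
    report["stages"]["motif"] = {
        "n_targets": len(targets),
        "n_background": len(background),
        "top_kmer": None if top is None else str(top["kmer"]),
        "top_kmer_q": None if top is None else float(top["q_value"]),
        "top_matches_uguayy": bool(top is not None and
                                   motif.match_pattern(str(top["kmer"]), "UGUAYY")),
    }

    stage("expression")
    lengths = {tid: m.length_t for tid, m in models.items()}
    fpkm_tables = {}
    for cond in ("A", "B"):
        cols = {}
        for rep in range(1, config.n_replicates + 1):
            _, inp = data[(cond, rep)]
            n = inp[next(iter(inp))].library_size
            cols[f"{cond}{rep}"] = {
                tid: differential.fpkm(float(inp[tid].values.sum()), lengths[tid], n)
                for tid in models
            }
        fpkm_tables[cond] = pd.DataFrame(cols).loc[sorted(models)]
    de = differential.differential_expression(
        fpkm_tables["A"], fpkm_tables["B"], fc_min=fc_min, alpha=alpha_diff
    )
    timings["expression"] = time.time() - timings["expression"]
    report["stages"]["expression"] = {
        "n_genes": int(len(de)),
        "n_significant": int(de["significant"].sum()),
        "n_up": int((de["significant"] & (de["direction"] == "up")).sum()),
        "n_down": int((de["significant"] & (de["direction"] == "down")).sum()),
    }

    stage("differential_m6a")
    regions = merge_regions([consensus_sets["A"], consensus_sets["B"]])

    def summed(cond, which):
        out = {}
        for tid in models:
            total = sum(
                data[(cond, rep)][which][tid].values
                for rep in range(1, config.n_replicates + 1)
            )
            n = sum(
                data[(cond, rep)][which][next(iter(models))].library_size
                for rep in range(1, config.n_replicates + 1)
            )
            out[tid] = synthetic_data.CoverageTrack(tid, total, n)
        return out

    dm = differential.differential_m6a(
        regions,
        summed("A", 0), summed("A", 1), summed("B", 0), summed("B", 1),
        fc_min=fc_min, alpha=alpha_diff,
    )
    quad = differential.quadrants(dm, de)
    timings["differential_m6a"] = time.time() - timings["differential_m6a"]
    report["stages"]["differential_m6a"] = {
        "n_regions": len(regions),
        "n_significant": int(dm["significant"].sum()),
        "n_up": int((dm["significant"] & (dm["direction"] == "up")).sum()),
        "n_down": int((dm["significant"] & (dm["direction"] == "down")).sum()),
        "quadrants": {
            row: {col: int(quad.counts.loc[row, col]) for col in quad.counts.columns}
            for row in quad.counts.index
        },
        "negative_association_p": quad.negative_association_pvalue(),
    }

    report["recovery"] = {
        "consensus_A": evaluate_recovery(consensus_sets["A"], truth),
        "differential": evaluate_differential(dm, truth),
    }
    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    report["total_s"] = round(time.time() - t0, 3)
    report["report_hash"] = report_hash(
        {k: v for k, v in report.items() if k not in ("timings_s", "total_s")}
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond in ("A", "B"):
            peaks_to_bed(consensus_sets[cond], outdir / f"consensus_{cond}.bed")
            peaks_to_frame(consensus_sets[cond]).to_csv(
                outdir / f"consensus_{cond}.tsv", sep="\t", index=False
            )
        kmers.head(50).to_csv(outdir / "motif_top50.tsv", sep="\t", index=False)
        de.to_csv(outdir / "differential_expression.tsv", sep="\t")
        dm.to_csv(outdir / "differential_m6a.tsv", sep="\t", index=False)
        quad.counts.to_csv(outdir / "quadrants.tsv", sep="\t")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
    return report
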