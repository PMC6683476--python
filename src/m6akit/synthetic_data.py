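"""Ground-truth simulator for m6A-seq style IP/input count data.

The generator builds a multi-transcript transcriptome (each mRNA with a
5'UTR, CDS, and 3'UTR, one to three exons, random strand), plants m6A
sites with a positional bias concentrated in the stop-codon window and
3'UTR, embeds the plant consensus motif UGUAYY at a configurable fraction
of sites, and simulates negative-binomial fragment counts for IP and
input libraries over three replicates and two conditions. Condition B can
carry differential methylation (a fold change on the IP enrichment boost)
coupled to differential expression with a configurable sign — by default
hypermethylation goes with lower abundance, the regime in which the
negative m6A-expression association is recoverable downstream.

Counts model: input coverage at each nucleotide is negative binomial with
mean ``mean_coverage * abundance``; the IP mean is the input mean times
``1 + (enrichment_factor - 1) * stoichiometry`` inside a fragment-length
window (default 100 nt) around each planted site, renormalized so the IP
library depth matches the input depth. Replicates share expectations and
differ only through noise; every (condition, replicate) stream is an
independent, reproducible child of the single global seed.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from m6akit import topology
from m6akit.transcript_model import (
    CoverageTrack,
    TranscriptModel,
    parse_annotation,
    read_bedgraph,
    read_fasta,
    write_annotation,
    write_bedgraph,
    write_fasta,
)

_DNA = np.array(list("ACGT"))
_CONDITIONS = ("A", "B")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic m6A-seq experiment."""

    n_transcripts: int = 500
    utr5_range: tuple = (50, 300)
    cds_range: tuple = (300, 1800)  # rounded to codons
    utr3_range: tuple = (100, 500)
    fraction_methylated: float = 0.10
    segment_weights: dict = field(
        default_factory=lambda: {
            "tss": 0.02, "utr5": 0.03, "cds": 0.10,
            "stop_codon": 0.55, "utr3": 0.30,
        }
    )
    enrichment_factor: float = 8.0
    stoichiometry: float = 0.8
    mean_coverage: float = 30.0
    dispersion: float = 0.02
    n_replicates: int = 3
    fraction_differential: float = 0.5  # of methylated transcripts
    fraction_hyper: float = 0.8  # of differential sites: higher m6A in B
    m6a_fold_change: float = 3.0  # fold change on the IP enrichment boost
    expression_fold_change: float = 2.0
    coupling_sign: int = -1  # -1: m6A up in B -> expression down in B
    fragment_length: int = 100
    motif_fraction: float = 0.6
    abundance_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_methylated", "fraction_differential", "fraction_hyper",
            "motif_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.stoichiometry <= 1.0):
            raise ValueError("stoichiometry must be in (0, 1]")
        if self.enrichment_factor <= 1.0:
            raise ValueError("enrichment_factor must exceed 1")
        if self.utr5_range[0] < 1 or self.cds_range[0] < 6 or self.utr3_range[0] < 1:
            raise ValueError("minimal lengths: 5'UTR >= 1, CDS >= 6, 3'UTR >= 1")
        if self.m6a_fold_change < 1.0:
            raise ValueError("m6a_fold_change must be >= 1")
        if self.fraction_differential > 0 and self.m6a_fold_change > 1.0:
            boost = 1.0 + (self.enrichment_factor - 1.0) * self.stoichiometry
            if boost / self.m6a_fold_change <= 1.0:
                raise ValueError(
                    "m6a_fold_change too large: depleted-condition boost would "
                    "fall to or below 1"
                )
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.coupling_sign not in (-1, 1):
            raise ValueError("coupling_sign must be -1 or +1")
        weights = self.segment_weights
        if set(weights) != set(topology.SEGMENTS):
            raise ValueError(f"segment_weights must cover {topology.SEGMENTS}")
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("segment_weights must be non-negative, not all zero")


@dataclass
class TruthTable:
    """Planted ground truth: per-site and per-transcript frames.

    ``sites`` columns: transcript_id, position, segment, stoich_a,
    stoich_b, motif, direction (up/down/none).
    ``transcripts`` columns: transcript_id, abundance_a, abundance_b,
    methylated, differential, direction.
    """

    sites: pd.DataFrame
    transcripts: pd.DataFrame


def _boost(config: SimulationConfig, stoich: float) -> float:
    return 1.0 + (config.enrichment_factor - 1.0) * stoich


def _stoich_for_boost(config: SimulationConfig, boost: float) -> float:
    return (boost - 1.0) / (config.enrichment_factor - 1.0)


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[dict[str, TranscriptModel], dict[str, str], TruthTable]:
    """Generate transcript models, sequences, and the planted truth table.

    Deterministic given ``config.seed``. Each planted site carries a
    UGUAYY instance centered on the methylated adenosine when motif
    embedding fires (probability ``motif_fraction`` per site).
    """
    rng = np.random.default_rng(config.seed)
    models: dict[str, TranscriptModel] = {}
    sequences: dict[str, str] = {}
    partitions: dict[str, topology.SegmentPartition] = {}

    for i in range(config.n_transcripts):
        tid, gid = f"tx{i:05d}", f"gene{i:05d}"
        utr5 = int(rng.integers(*config.utr5_range, endpoint=True))
        cds = int(rng.integers(*config.cds_range, endpoint=True)) // 3 * 3
        cds = max(cds, 6)
        utr3 = int(rng.integers(*config.utr3_range, endpoint=True))
        length = utr5 + cds + utr3

        n_exons = int(rng.integers(1, 4))
        if n_exons == 1 or length < 2 * n_exons:
            exon_lens = [length]
        else:
            cuts = np.sort(rng.choice(np.arange(1, length), n_exons - 1, replace=False))
            exon_lens = np.diff(np.concatenate(([0], cuts, [length]))).tolist()
        strand = "+" if rng.random() < 0.5 else "-"
        # Lay exons out genomically with random introns; the first exon in
        # genomic order is the transcript 5' end on + and 3' end on -.
        genomic_lens = exon_lens if strand == "+" else exon_lens[::-1]
        pos = 1000
        exons = []
        for n in genomic_lens:
            exons.append((pos, pos + n))
            pos += n + int(rng.integers(50, 501))
        model = TranscriptModel(
            transcript_id=tid, gene_id=gid, contig=f"chr{i + 1:05d}",
            strand=strand, exons=tuple(exons),
            cds_start_t=utr5, cds_end_t=utr5 + cds,
        )
        seq = rng.choice(_DNA, size=length)
        seq[utr5 : utr5 + 3] = list("ATG")
        seq[utr5 + cds - 3 : utr5 + cds] = list("TAA")
        models[tid] = model
        sequences[tid] = "".join(seq)
        partitions[tid] = topology.partition(model)

    tids = list(models)
    n_meth = int(round(config.fraction_methylated * config.n_transcripts))
    methylated = sorted(rng.choice(tids, size=n_meth, replace=False).tolist())
    n_diff = int(round(config.fraction_differential * n_meth))
    differential = set(methylated[:0])
    if n_diff:
        differential = set(rng.choice(methylated, size=n_diff, replace=False).tolist())

    weights = np.array([config.segment_weights[s] for s in topology.SEGMENTS], float)
    weights = weights / weights.sum()

    site_rows = []
    direction_by_tid: dict[str, str] = {}
    for tid in methylated:
        part = partitions[tid]
        seg_lens = part.segment_lengths()
        avail = np.array([weights[j] if seg_lens[s] > 0 else 0.0
                          for j, s in enumerate(topology.SEGMENTS)])
        avail = avail / avail.sum()
        segment = topology.SEGMENTS[int(rng.choice(len(avail), p=avail))]
        ivals = part.intervals[segment]
        lens = np.array([e - s for s, e in ivals], float)
        s0, e0 = ivals[int(rng.choice(len(ivals), p=lens / lens.sum()))]
        pos = int(rng.integers(s0, e0))
        length = models[tid].length_t
        pos = min(max(pos, 3), length - 4)  # leave room for a centered 6-mer

        full = config.stoichiometry
        if tid in differential:
            hyper = rng.random() < config.fraction_hyper
            depleted = _stoich_for_boost(config, _boost(config, full) / config.m6a_fold_change)
            if hyper:
                stoich_a, stoich_b, direction = depleted, full, "up"
            else:
                stoich_a, stoich_b, direction = full, depleted, "down"
            direction_by_tid[tid] = direction
        else:
            stoich_a = stoich_b = full
            direction = "none"

        embed = bool(rng.random() < config.motif_fraction)
        if embed:
            seq = list(sequences[tid])
            y_choices = "CT"
            motif = "TGTA" + y_choices[int(rng.integers(2))] + y_choices[int(rng.integers(2))]
            seq[pos - 3 : pos + 3] = list(motif)
            sequences[tid] = "".join(seq)

        site_rows.append(
            {
                "transcript_id": tid, "position": pos,
                "segment": part.label_of(pos),
                "stoich_a": stoich_a, "stoich_b": stoich_b,
                "motif": embed, "direction": direction,
            }
        )

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(tids))
    tx_rows = []
    for tid, ab in zip(tids, abundance):
        direction = direction_by_tid.get(tid, "none")
        factor = 1.0
        if direction == "up":
            factor = (
                1.0 / config.expression_fold_change
                if config.coupling_sign < 0
                else config.expression_fold_change
            )
        elif direction == "down":
            factor = (
                config.expression_fold_change
                if config.coupling_sign < 0
                else 1.0 / config.expression_fold_change
            )
        tx_rows.append(
            {
                "transcript_id": tid,
                "abundance_a": float(ab),
                "abundance_b": float(ab * factor),
                "methylated": tid in methylated,
                "differential": tid in differential,
                "direction": direction,
            }
        )

    truth = TruthTable(
        sites=pd.DataFrame(
            site_rows,
            columns=["transcript_id", "position", "segment", "stoich_a",
                     "stoich_b", "motif", "direction"],
        ),
        transcripts=pd.DataFrame(tx_rows),
    )
    return models, sequences, truth


def expected_means(
    models: Mapping[str, TranscriptModel],
    truth: TruthTable,
    config: SimulationConfig,
    condition: str,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Closed-form per-nucleotide IP and input means for one condition.

    The IP means are renormalized so total IP depth equals total input
    depth; tests compare Monte-Carlo averages against these vectors.
    """
    cond = condition.upper()
    if cond not in _CONDITIONS:
        raise ValueError("condition must be 'A' or 'B'")
    ab_col = f"abundance_{cond.lower()}"
    st_col = f"stoich_{cond.lower()}"
    abundance = dict(zip(truth.transcripts["transcript_id"], truth.transcripts[ab_col]))

    input_means, ip_raw = {}, {}
    half = config.fragment_length // 2
    sites_by_tid: dict[str, list[tuple[int, float]]] = {}
    for _, row in truth.sites.iterrows():
        sites_by_tid.setdefault(row["transcript_id"], []).append(
            (int(row["position"]), float(row[st_col]))
        )
    for tid, model in models.items():
        mu = np.full(model.length_t, config.mean_coverage * abundance[tid])
        boost = np.ones(model.length_t)
        for pos, stoich in sites_by_tid.get(tid, []):
            s = max(0, pos - half)
            e = min(model.length_t, pos + (config.fragment_length - half))
            np.maximum(boost[s:e], _boost(config, stoich), out=boost[s:e])
        input_means[tid] = mu
        ip_raw[tid] = mu * boost

    total_in = sum(float(v.sum()) for v in input_means.values())
    total_ip = sum(float(v.sum()) for v in ip_raw.values())
    scale = total_in / total_ip if total_ip > 0 else 1.0
    ip_means = {tid: v * scale for tid, v in ip_raw.items()}
    return ip_means, input_means


def _sample(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def simulate_counts(
    models: Mapping[str, TranscriptModel],
    truth: TruthTable,
    config: SimulationConfig,
    condition: str = "A",
    replicate: int = 1,
) -> tuple[dict[str, CoverageTrack], dict[str, CoverageTrack]]:
    """Simulate (IP, input) coverage tracks for one condition/replicate.

    The random stream is seeded as ``(seed, condition, replicate)`` so any
    subset of the design is independently reproducible.
    """
    cond = condition.upper()
    rng = np.random.default_rng(
        [config.seed, _CONDITIONS.index(cond) + 1, 1000 + replicate]
    )
    ip_means, input_means = expected_means(models, truth, config, cond)

    in_values = {tid: _sample(rng, input_means[tid], config.dispersion) for tid in models}
    ip_values = {tid: _sample(rng, ip_means[tid], config.dispersion) for tid in models}
    n_in = int(sum(v.sum() for v in in_values.values()))
    n_ip = int(sum(v.sum() for v in ip_values.values()))
    ip_tracks = {
        tid: CoverageTrack(tid, ip_values[tid], max(n_ip, 1)) for tid in models
    }
    in_tracks = {
        tid: CoverageTrack(tid, in_values[tid], max(n_in, 1)) for tid in models
    }
    return ip_tracks, in_tracks


def simulate_dataset(
    config: SimulationConfig, conditions: tuple = _CONDITIONS
) -> tuple[dict, dict, TruthTable, dict]:
    """Full design: transcriptome plus tracks for every condition/replicate.

    Returns ``(models, sequences, truth, data)`` where
    ``data[(condition, replicate)] = (ip_tracks, input_tracks)``.
    """
    models, sequences, truth = simulate_transcriptome(config)
    data = {}
    for cond in conditions:
        for rep in range(1, config.n_replicates + 1):
            data[(cond, rep)] = simulate_counts(models, truth, config, cond, rep)
    return models, sequences, truth, data


# ---------------------------------------------------------------------------
# Dataset persistence
# ---------------------------------------------------------------------------


def emit_dataset(outdir: str | os.PathLike, config: SimulationConfig,
                 conditions: tuple = _CONDITIONS) -> Path:
    """Simulate and write a complete dataset re-loadable by the readers.

    Layout: ``transcripts.gff3``, ``transcripts.fa``, ``truth_sites.tsv``,
    ``truth_transcripts.tsv``, ``config.yaml``, and per condition/replicate
    ``{cond}_rep{r}_ip.bedgraph`` / ``{cond}_rep{r}_input.bedgraph``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    models, sequences, truth, data = simulate_dataset(config, conditions)
    write_annotation(models, outdir / "transcripts.gff3")
    write_fasta(sequences, outdir / "transcripts.fa")
    truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    truth.transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t", index=False)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    for (cond, rep), (ip_tracks, in_tracks) in data.items():
        write_bedgraph(ip_tracks, outdir / f"{cond}_rep{rep}_ip.bedgraph")
        write_bedgraph(in_tracks, outdir / f"{cond}_rep{rep}_input.bedgraph")
    return outdir


def load_dataset(outdir: str | os.PathLike):
    """Load a dataset written by :func:`emit_dataset`."""
    outdir = Path(outdir)
    with open(outdir / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    for key in ("utr5_range", "cds_range", "utr3_range"):
        raw[key] = tuple(raw[key])
    config = SimulationConfig(**raw)
    models = parse_annotation(outdir / "transcripts.gff3")
    sequences = read_fasta(outdir / "transcripts.fa")
    truth = TruthTable(
        sites=pd.read_csv(outdir / "truth_sites.tsv", sep="\t"),
        transcripts=pd.read_csv(outdir / "truth_transcripts.tsv", sep="\t"),
    )
    lengths = {tid: m.length_t for tid, m in models.items()}
    data = {}
    for path in sorted(outdir.glob("*_ip.bedgraph")):
        cond, rep_s, _ = path.stem.split("_")
        rep = int(rep_s.replace("rep", ""))
        ip_vals = read_bedgraph(path, lengths)
        in_vals = read_bedgraph(outdir / f"{cond}_{rep_s}_input.bedgraph", lengths)
        n_ip = int(sum(v.sum() for v in ip_vals.values()))
        n_in = int(sum(v.sum() for v in in_vals.values()))
        data[(cond, rep)] = (
            {tid: CoverageTrack(tid, ip_vals[tid], max(n_ip, 1)) for tid in models},
            {tid: CoverageTrack(tid, in_vals[tid], max(n_in, 1)) for tid in models},
        )
    return models, sequences, truth, data, config
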