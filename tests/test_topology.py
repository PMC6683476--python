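"""Five-segment partition, summit assignment, metagene, peak-count stats."""

from __future__ import annotations

import numpy as np
import pytest

from m6akit import topology
from m6akit.peak_calling import Peak
from m6akit.synthetic_data import SimulationConfig, simulate_transcriptome
from m6akit.transcript_model import TranscriptModel


def brute_force_labels(model, stop_window=100, tss_window=100):
    """Per-base oracle: label every position by direct rule application.

    Stop window first (precedence), then TSS / 5'UTR / CDS / 3'UTR by
    coordinate comparison.
    """
    c = model.cds_end_t - 3
    labels = []
    for pos in range(model.length_t):
        if c - stop_window // 2 <= pos < c + stop_window - stop_window // 2:
            labels.append("stop_codon")
        elif pos < min(tss_window, model.cds_start_t):
            labels.append("tss")
        elif pos < model.cds_start_t:
            labels.append("utr5")
        elif pos < model.cds_end_t:
            labels.append("cds")
        else:
            labels.append("utr3")
    return labels


def make_model(utr5, cds, utr3, tid="t"):
    return TranscriptModel(tid, "g", "c", "+", ((0, utr5 + cds + utr3),),
                           cds_start_t=utr5, cds_end_t=utr5 + cds)


class TestPartition:
    def test_worked_example(self):
        """5'UTR 200 / CDS 900 / 3'UTR 300: stop triplet [1097,1100) puts the
        stop segment at [1047,1147), squeezing CDS and 3'UTR around it."""
        part = topology.partition(make_model(200, 900, 300))
        assert part.intervals["stop_codon"] == ((1047, 1147),)
        assert part.intervals["tss"] == ((0, 100),)
        assert part.intervals["utr5"] == ((100, 200),)
        assert part.intervals["cds"] == ((200, 1047),)
        assert part.intervals["utr3"] == ((1147, 1400),)

    def test_short_utr5_truncates_tss(self):
        part = topology.partition(make_model(40, 900, 300))
        assert part.intervals["tss"] == ((0, 40),)
        assert part.intervals["utr5"] == tuple()

    def test_noncoding_rejected(self):
        m = TranscriptModel("t", "g", "c", "+", ((0, 500),))
        with pytest.raises(ValueError):
            topology.partition(m)

    def test_partition_matches_per_base_oracle_on_random_transcripts(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            utr5 = int(rng.integers(1, 300))
            cds = int(rng.integers(2, 400)) * 3
            utr3 = int(rng.integers(1, 400))
            m = make_model(utr5, cds, utr3)
            part = topology.partition(m)
            oracle = brute_force_labels(m)
            for pos in range(m.length_t):
                assert part.label_of(pos) == oracle[pos]
            # disjoint cover: segment lengths sum to the transcript length
            assert sum(part.segment_lengths().values()) == m.length_t


class TestAssign:
    def test_summit_at_origin_is_tss(self):
        parts = {"t": topology.partition(make_model(200, 900, 300))}
        counts, _ = topology.assign_summits([("t", 0)], parts)
        assert counts["tss"] == 1

    def test_stop_window_precedence_inside_cds_coordinates(self):
        parts = {"t": topology.partition(make_model(200, 900, 300))}
        counts, _ = topology.assign_summits([("t", 1050)], parts)  # in CDS span
        assert counts["stop_codon"] == 1

    def test_totals_conserved_and_fractions_sum_to_one(self):
        parts = {"t": topology.partition(make_model(200, 900, 300))}
        summits = [("t", p) for p in (0, 150, 500, 1050, 1200)]
        counts, fractions = topology.assign_summits(summits, parts)
        assert sum(counts.values()) == len(summits)
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_synthetic_stop_codon_regime_assigns_stop(self):
        weights = {s: 0.0 for s in topology.SEGMENTS}
        weights["stop_codon"] = 1.0
        cfg = SimulationConfig(n_transcripts=80, fraction_methylated=0.5,
                               segment_weights=weights, seed=3)
        models, _, truth = simulate_transcriptome(cfg)
        parts = {tid: topology.partition(m) for tid, m in models.items()}
        summits = [(r.transcript_id, int(r.position)) for _, r in truth.sites.iterrows()]
        _, fractions = topology.assign_summits(summits, parts)
        assert fractions["stop_codon"] >= 0.95


class TestRelativeEnrichment:
    def test_all_summits_in_small_segment(self):
        """All summits in a segment holding 5% of nucleotides -> ratio 20."""
        ratios = topology.relative_enrichment(
            {"tss": 0, "utr5": 0, "cds": 0, "stop_codon": 1.0, "utr3": 0},
            {"tss": 0.1, "utr5": 0.1, "cds": 0.55, "stop_codon": 0.05, "utr3": 0.2},
        )
        assert ratios["stop_codon"] == pytest.approx(20.0)

    def test_hand_computed_three_transcript_set(self):
        models = {f"t{i}": make_model(*dims, tid=f"t{i}")
                  for i, dims in enumerate([(100, 300, 100), (50, 600, 200),
                                            (200, 900, 300)])}
        parts = {tid: topology.partition(m) for tid, m in models.items()}
        nt = topology.segment_nt_fractions(parts)
        # hand oracle: total nt per segment over total transcriptome nt
        lengths = {seg: 0 for seg in topology.SEGMENTS}
        for part in parts.values():
            for seg, n in part.segment_lengths().items():
                lengths[seg] += n
        total = sum(m.length_t for m in models.values())
        for seg in topology.SEGMENTS:
            assert nt[seg] == pytest.approx(lengths[seg] / total)
        # stop windows: t1 [597,697), t2 [1047,1147); t0 summit 0 is TSS
        summits = [("t0", 0), ("t1", 650), ("t2", 1100)]
        _, fr = topology.assign_summits(summits, parts)
        ratios = topology.relative_enrichment(fr, nt)
        assert ratios["stop_codon"] == pytest.approx((2 / 3) / nt["stop_codon"])

    def test_invariant_under_transcript_duplication(self):
        models = {"t": make_model(100, 600, 200)}
        parts = {"t": topology.partition(models["t"])}
        doubled = {
            "t": parts["t"],
            "t2": topology.partition(make_model(100, 600, 200, tid="t2")),
        }
        summits = [("t", 650)]
        summits2 = summits + [("t2", 650)]
        r1 = topology.relative_enrichment(
            topology.assign_summits(summits, parts)[1],
            topology.segment_nt_fractions(parts),
        )
        r2 = topology.relative_enrichment(
            topology.assign_summits(summits2, doubled)[1],
            topology.segment_nt_fractions(doubled),
        )
        for seg in topology.SEGMENTS:
            if not np.isnan(r1[seg]):
                assert r1[seg] == pytest.approx(r2[seg])


class TestMetagene:
    def test_cds_midpoint_concentrates_in_central_bin(self):
        models = {"t": make_model(200, 902, 300)}
        c = 200 + 902 - 3
        mid = (200 + c) // 2
        profile = topology.metagene([("t", mid)] * 10, models)
        assert profile.densities.sum() == pytest.approx(1.0)
        cds_slice = profile.segment_slices()["cds"]
        cds_part = profile.densities[cds_slice]
        expected_bin = int((mid - 200) / (c - 200) * 100)
        assert cds_part[expected_bin] == pytest.approx(1.0)
        assert np.count_nonzero(profile.densities) == 1

    def test_density_sums_to_one(self):
        models = {"t": make_model(100, 600, 200)}
        summits = [("t", p) for p in range(0, 900, 7)]
        profile = topology.metagene(summits, models)
        assert profile.densities.sum() == pytest.approx(1.0)
        assert profile.n_summits == len(summits)

    def test_uniform_summits_give_flat_profile(self):
        """Evenly spaced summits over one transcript produce bin densities
        within a factor 2 of each other in every segment."""
        models = {"t": make_model(300, 3000, 300)}
        summits = [("t", p) for p in range(0, 3600, 1)]
        profile = topology.metagene(summits, models)
        for seg, sl in profile.segment_slices().items():
            d = profile.densities[sl]
            assert d.max() / d.min() < 2


class TestPeakCounts:
    def _peak(self, tid, s=0, e=10):
        return Peak(tid, s, e, s, 1.0, 0.01, 0.01)

    def test_all_single_peaks(self):
        peaks = [self._peak(f"t{i}") for i in range(10)]
        dist, mean = topology.peaks_per_transcript(peaks)
        assert dist == {"1": 1.0, "2": 0.0, "3": 0.0, ">3": 0.0}
        assert mean == 1.0

    def test_mixed_toy_set_counting_oracle(self):
        layout = {"a": 1, "b": 2, "c": 1, "d": 3, "e": 5}
        peaks = [
            self._peak(tid, s=20 * i, e=20 * i + 10)
            for tid, n in layout.items()
            for i in range(n)
        ]
        dist, mean = topology.peaks_per_transcript(peaks)
        assert dist["1"] == pytest.approx(2 / 5)
        assert dist["2"] == pytest.approx(1 / 5)
        assert dist["3"] == pytest.approx(1 / 5)
        assert dist[">3"] == pytest.approx(1 / 5)
        assert mean == pytest.approx(12 / 5)
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_peaks_per_expressed(self):
        peaks = [self._peak(f"t{i}") for i in range(50)]
        fpkm = {f"t{i}": 2.0 for i in range(100)}
        assert topology.peaks_per_expressed(peaks, fpkm) == pytest.approx(0.5)

    def test_no_expressed_transcripts_guard(self):
        with pytest.raises(ValueError):
            topology.peaks_per_expressed([], {"t": 0.1}, fpkm_min=1.0)

    def test_synthetic_regime_reproduces_planted_ratio(self):
        """With every transcript expressed and one planted site per
        methylated transcript, peaks per expressed = fraction methylated."""
        cfg = SimulationConfig(n_transcripts=100, fraction_methylated=0.2, seed=4)
        _, _, truth = simulate_transcriptome(cfg)
        peaks = [self._peak(tid) for tid in truth.sites.transcript_id]
        fpkm = {tid: 5.0 for tid in truth.transcripts.transcript_id}
        ratio = topology.peaks_per_expressed(peaks, fpkm)
        assert ratio == pytest.approx(len(truth.sites) / 100)
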