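"""Generator determinism, planted-truth structure, and count calibration."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from m6akit import topology
from m6akit.peak_calling import window_counts, _window_pvalues
from m6akit.synthetic_data import (
    SimulationConfig,
    emit_dataset,
    expected_means,
    load_dataset,
    simulate_counts,
    simulate_transcriptome,
)


def small_config(**kw) -> SimulationConfig:
    defaults = dict(n_transcripts=60, seed=5)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestTranscriptome:
    def test_seeded_runs_are_identical(self):
        cfg = small_config()
        m1, s1, t1 = simulate_transcriptome(cfg)
        m2, s2, t2 = simulate_transcriptome(cfg)
        assert s1 == s2
        assert {k: v.exons for k, v in m1.items()} == {k: v.exons for k, v in m2.items()}
        pd.testing.assert_frame_equal(t1.sites, t2.sites)
        pd.testing.assert_frame_equal(t1.transcripts, t2.transcripts)

    def test_counts_reproducible_per_condition_replicate(self):
        cfg = small_config()
        models, _, truth = simulate_transcriptome(cfg)
        a1 = simulate_counts(models, truth, cfg, "B", 2)
        a2 = simulate_counts(models, truth, cfg, "B", 2)
        tid = next(iter(models))
        np.testing.assert_array_equal(a1[0][tid].values, a2[0][tid].values)
        b = simulate_counts(models, truth, cfg, "B", 3)
        assert not np.array_equal(a1[0][tid].values, b[0][tid].values)

    def test_zero_methylation_gives_empty_truth(self):
        _, _, truth = simulate_transcriptome(small_config(fraction_methylated=0.0))
        assert len(truth.sites) == 0

    def test_all_mass_on_stop_codon_places_sites_there(self):
        """With the positional weight entirely on the stop-codon segment the
        topology partition labels every planted site stop_codon."""
        weights = {s: 0.0 for s in topology.SEGMENTS}
        weights["stop_codon"] = 1.0
        cfg = small_config(segment_weights=weights, fraction_methylated=0.5)
        models, _, truth = simulate_transcriptome(cfg)
        for _, row in truth.sites.iterrows():
            part = topology.partition(models[row.transcript_id])
            assert part.label_of(int(row.position)) == "stop_codon"

    def test_motif_embedded_at_sites(self):
        cfg = small_config(fraction_methylated=0.5, motif_fraction=1.0)
        models, seqs, truth = simulate_transcriptome(cfg)
        assert len(truth.sites) > 0
        for _, row in truth.sites.iterrows():
            pos = int(row.position)
            hexamer = seqs[row.transcript_id][pos - 3 : pos + 3]
            assert hexamer[:4] == "TGTA" and all(b in "CT" for b in hexamer[4:])

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(enrichment_factor=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(stoichiometry=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(m6a_fold_change=50.0)  # depleted boost would be <= 1
        with pytest.raises(ValueError):
            SimulationConfig(cds_range=(3, 9))


class TestCounts:
    def test_library_size_equals_total_counts(self):
        cfg = small_config()
        models, _, truth = simulate_transcriptome(cfg)
        ip, inp = simulate_counts(models, truth, cfg, "A", 1)
        for tracks in (ip, inp):
            total = sum(int(t.values.sum()) for t in tracks.values())
            assert tracks[next(iter(models))].library_size == total

    def test_total_depth_matches_expectation_within_3_se(self):
        cfg = small_config(dispersion=0.02)
        models, _, truth = simulate_transcriptome(cfg)
        _, input_means = expected_means(models, truth, cfg, "A")
        expected = sum(float(v.sum()) for v in input_means.values())
        var = sum(
            float((v + cfg.dispersion * v**2).sum()) for v in input_means.values()
        )
        _, inp = simulate_counts(models, truth, cfg, "A", 1)
        observed = sum(int(t.values.sum()) for t in inp.values())
        assert abs(observed - expected) < 3 * np.sqrt(var)

    def test_site_window_ip_mean_matches_closed_form(self):
        """Monte-Carlo IP mean at fully methylated site windows agrees with
        the renormalized closed form (stoichiometry 1, enrichment 8x)."""
        cfg = small_config(
            n_transcripts=200, fraction_methylated=0.5, stoichiometry=1.0,
            fraction_differential=0.0, dispersion=0.02, seed=9,
        )
        models, _, truth = simulate_transcriptome(cfg)
        ip_means, _ = expected_means(models, truth, cfg, "A")
        ip, _ = simulate_counts(models, truth, cfg, "A", 1)
        obs, exp, var = 0.0, 0.0, 0.0
        for _, row in truth.sites.iterrows():
            tid, pos = row.transcript_id, int(row.position)
            L = models[tid].length_t
            s, e = max(0, pos - 50), min(L, pos + 50)
            obs += float(ip[tid].values[s:e].sum())
            mu = ip_means[tid][s:e]
            exp += float(mu.sum())
            var += float((mu + cfg.dispersion * mu**2).sum())
        assert abs(obs - exp) < 3 * np.sqrt(var)
        # The normalized IP/input enrichment at a saturated site approaches
        # the configured factor (diluted only by the IP renormalization).
        tid = truth.sites.iloc[0].transcript_id
        pos = int(truth.sites.iloc[0].position)
        mu_ratio = ip_means[tid][pos] / (cfg.mean_coverage *
            truth.transcripts.set_index("transcript_id").loc[tid, "abundance_a"])
        assert 0.7 * cfg.enrichment_factor < mu_ratio <= cfg.enrichment_factor

    def test_enrichment_limit_of_one_means_no_ip_excess(self):
        """As enrichment_factor -> 1 the IP and input means coincide."""
        cfg = small_config(
            n_transcripts=100, fraction_methylated=0.5,
            enrichment_factor=1.0 + 1e-9, fraction_differential=0.0,
        )
        models, _, truth = simulate_transcriptome(cfg)
        ip_means, input_means = expected_means(models, truth, cfg, "A")
        for tid in models:
            np.testing.assert_allclose(ip_means[tid], input_means[tid], rtol=1e-6)

    def test_null_window_pvalues_are_uniform(self):
        """Unmethylated data in the Poisson limit yields a ~Uniform(0,1)
        window p-value distribution (KS at alpha = 0.01)."""
        cfg = small_config(n_transcripts=40, fraction_methylated=0.0,
                           dispersion=0.0, seed=13)
        models, _, truth = simulate_transcriptome(cfg)
        ip, inp = simulate_counts(models, truth, cfg, "A", 1)
        pvals = []
        n_ip = ip[next(iter(models))].library_size
        n_in = inp[next(iter(models))].library_size
        for tid in models:
            _, a, b = window_counts(ip[tid], inp[tid])
            pvals.append(_window_pvalues(a.astype(np.int64), b.astype(np.int64),
                                         n_ip, n_in))
        pvals = np.concatenate(pvals)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_differential_truth_directions(self):
        cfg = small_config(n_transcripts=200, fraction_methylated=0.3,
                           fraction_differential=1.0, fraction_hyper=0.8)
        _, _, truth = simulate_transcriptome(cfg)
        sites = truth.sites
        assert set(sites.direction) <= {"up", "down"}
        # hyper sites: higher stoichiometry in B; hypo: the reverse
        up = sites[sites.direction == "up"]
        down = sites[sites.direction == "down"]
        assert (up.stoich_b > up.stoich_a).all()
        assert (down.stoich_a > down.stoich_b).all()
        # negative coupling: m6A-up transcripts lose abundance in B
        tx = truth.transcripts.set_index("transcript_id")
        for tid in up.transcript_id:
            assert tx.loc[tid, "abundance_b"] < tx.loc[tid, "abundance_a"]


class TestPersistence:
    def test_emit_and_load_round_trip(self, tmp_path):
        cfg = small_config(n_transcripts=20)
        outdir = emit_dataset(tmp_path / "ds", cfg)
        models, sequences, truth, data, loaded_cfg = load_dataset(outdir)
        ref_models, ref_seqs, ref_truth = simulate_transcriptome(cfg)
        assert loaded_cfg == cfg
        assert sequences == ref_seqs
        assert {k: v.exons for k, v in models.items()} == {
            k: v.exons for k, v in ref_models.items()
        }
        pd.testing.assert_frame_equal(
            truth.sites, ref_truth.sites, check_dtype=False
        )
        ref_ip, ref_in = simulate_counts(ref_models, ref_truth, cfg, "A", 1)
        ip, inp = data[("A", 1)]
        for tid in models:
            np.testing.assert_array_equal(ip[tid].values, ref_ip[tid].values)
            np.testing.assert_array_equal(inp[tid].values, ref_in[tid].values)

    def test_truth_tsv_row_count_equals_planted_sites(self, tmp_path):
        cfg = small_config(n_transcripts=30, fraction_methylated=0.4)
        outdir = emit_dataset(tmp_path / "ds", cfg)
        _, _, truth = simulate_transcriptome(cfg)
        lines = (outdir / "truth_sites.tsv").read_text().strip().splitlines()
        assert len(lines) - 1 == len(truth.sites)
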