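"""Shared fixtures: small simulated datasets and derived analysis objects.

Session-scoped fixtures cache the expensive simulations so the recovery,
differential, and acceptance tests share one default-regime run.
"""

from __future__ import annotations

import pytest

from m6akit import differential, peak_calling, pipeline
from m6akit.synthetic_data import SimulationConfig, simulate_dataset
from m6akit.transcript_model import CoverageTrack, TranscriptModel


@pytest.fixture(scope="session")
def default_dataset():
    """Default planted regime: 500 transcripts, 10% methylated,
    stoichiometry 0.8, enrichment 8x, 30x input coverage, 3 replicates."""
    config = SimulationConfig(seed=11)
    models, sequences, truth, data = simulate_dataset(config)
    return config, models, sequences, truth, data


@pytest.fixture(scope="session")
def default_consensus(default_dataset):
    """Per-condition consensus peaks for the default regime."""
    config, models, _, _, data = default_dataset
    out = {}
    for cond in ("A", "B"):
        sets = [
            peak_calling.call_peaks(*data[(cond, rep)])
            for rep in range(1, config.n_replicates + 1)
        ]
        out[cond] = (sets, peak_calling.consensus(sets))
    return out


def summed_tracks(models, data, cond, which, n_replicates=3):
    """Replicate-summed coverage tracks for one condition and library type."""
    any_tid = next(iter(models))
    n = sum(data[(cond, rep)][which][any_tid].library_size
            for rep in range(1, n_replicates + 1))
    return {
        tid: CoverageTrack(
            tid,
            sum(data[(cond, rep)][which][tid].values
                for rep in range(1, n_replicates + 1)),
            max(n, 1),
        )
        for tid in models
    }


@pytest.fixture(scope="session")
def default_differential(default_dataset, default_consensus):
    """Differential m6A over merged consensus regions, default regime."""
    config, models, _, truth, data = default_dataset
    regions = pipeline.merge_regions(
        [default_consensus["A"][1], default_consensus["B"][1]]
    )
    dm = differential.differential_m6a(
        regions,
        summed_tracks(models, data, "A", 0),
        summed_tracks(models, data, "A", 1),
        summed_tracks(models, data, "B", 0),
        summed_tracks(models, data, "B", 1),
    )
    return regions, dm


@pytest.fixture
def toy_model():
    """Single-exon plus-strand mRNA: 200 nt 5'UTR, 900 nt CDS, 300 nt 3'UTR."""
    return TranscriptModel(
        transcript_id="toy1",
        gene_id="g1",
        contig="chr1",
        strand="+",
        exons=((1000, 2400),),
        cds_start_t=200,
        cds_end_t=1100,
    )
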