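import numpy as np
import pytest

from mosaicstats import (
    SimulationConfig,
    annotate_context,
    generate_reference,
    generate_tracks,
    simulate_callset,
)


@pytest.fixture(scope="session")
def enriched_cohort():
    """Small cohort with planted T>G / CpG>GpG enrichment and hotspots."""
    cfg = SimulationConfig(
        genome_length=2_000_000, n_case=12, n_control=8,
        enrich_tg=25.0, enrich_cpg_transversion=10.0, enrich_halfwidth=100,
        n_hotspots=2, hotspot_hit_prob=0.5, seed=7,
    )
    ref = generate_reference(cfg)
    tracks = generate_tracks(ref, cfg)
    callset, truth = simulate_callset(ref, tracks, cfg)
    annotate_context(callset, ref)
    return {"config": cfg, "reference": ref, "tracks": tracks,
            "callset": callset, "truth": truth}


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted case/control difference."""
    cfg = SimulationConfig(
        genome_length=1_000_000, n_case=25, n_control=25,
        nb_mean=40.0, seed=11,
    )
    ref = generate_reference(cfg)
    tracks = generate_tracks(ref, cfg)
    callset, truth = simulate_callset(ref, tracks, cfg)
    annotate_context(callset, ref)
    return {"config": cfg, "reference": ref, "tracks": tracks,
            "callset": callset, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
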