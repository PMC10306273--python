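"""Shared fixtures: one default fusion study simulated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lepisex import (
    AlignerParams,
    GenomeIndex,
    ScenarioConfig,
    align_unique,
    apply_scenario,
    simulate_ancestral_genome,
)
from lepisex.chromstats import mask_repeats_simple
from lepisex.genome import make_cohort
from lepisex.reads import preprocess_records, simulate_individual_reads


@pytest.fixture(scope="session")
def default_cfg() -> ScenarioConfig:
    return ScenarioConfig(seed=1)


@pytest.fixture(scope="session")
def fusion_sim(default_cfg):
    """(config, ancestral, male, female, truth) under the fusion scenario."""
    ancestral = simulate_ancestral_genome(default_cfg)
    male, female, truth = apply_scenario(ancestral, default_cfg)
    return default_cfg, ancestral, male, female, truth


@pytest.fixture(scope="session")
def b_origin_sim():
    cfg = ScenarioConfig(scenario="b_origin", seed=1)
    ancestral = simulate_ancestral_genome(cfg)
    male, female, truth = apply_scenario(ancestral, cfg)
    return cfg, ancestral, male, female, truth


@pytest.fixture(scope="session")
def masked_female(fusion_sim):
    """Female fusion genome with the simple k-mer repeat mask applied."""
    return mask_repeats_simple(fusion_sim[3])


@pytest.fixture(scope="session")
def cohort(default_cfg):
    return make_cohort(default_cfg.n_per_sex)


@pytest.fixture(scope="session")
def cohort_reads(fusion_sim, cohort):
    """Preprocessed (residual-filtered, 91 bp) reads per individual."""
    cfg, _, male, female, _ = fusion_sim
    genomes = {"male": male, "female": female}
    out = {}
    for idx, ind in enumerate(cohort):
        rng = np.random.default_rng([cfg.seed, 3, idx])
        raw = simulate_individual_reads(
            genomes[ind.sex], ind, cfg.mean_depth, cfg.error_rate,
            cfg.read_len, rng, cfg.depth_dispersion)
        out[ind.id] = preprocess_records(raw, seed=cfg.seed)
    return out


def _align_cohort_to(genome, cohort_reads, score_threshold=400):
    index = GenomeIndex(genome)
    params = AlignerParams(score_threshold)
    rows = []
    for ind_id, recs in cohort_reads.items():
        for r in recs:
            hit = align_unique(r.seq, index, params, query_id=r.name)
            if hit is not None:
                rows.append((ind_id, hit.chrom, hit.start, hit.strand,
                             hit.n_mismatch))
    return pd.DataFrame(
        rows, columns=["individual", "chrom", "start", "strand", "n_mismatch"])


@pytest.fixture(scope="session")
def rad_alignment(fusion_sim, cohort_reads):
    """Whole-cohort unique read placements on the male (W-less) genome."""
    return _align_cohort_to(fusion_sim[2], cohort_reads)


@pytest.fixture(scope="session")
def female_genome_alignment(fusion_sim, cohort_reads):
    """Whole-cohort unique read placements on the female (W-bearing) genome."""
    return _align_cohort_to(fusion_sim[3], cohort_reads)
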