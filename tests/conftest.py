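import numpy as np
import pytest

from piecemeal import (
    KNNGenotypeImputer,
    SimConfig,
    build_panel_hierarchy,
    mask_to_panel,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_instance():
    """A small simulated instance: 40 markers, tier 12 typed, modest LD."""
    cfg = SimConfig(
        n_founder_haplotypes=4,
        n_reference=24,
        n_study=8,
        n_markers=40,
        chrom_length=100_000,
        recomb_prob_per_interval=0.02,
        error_rate=0.01,
        tier_sizes=(12, 40),
        seed=11,
    )
    reference, study_truth, panel = simulate_truth(cfg)
    hier = build_panel_hierarchy(panel, cfg.tier_sizes)
    study = mask_to_panel(study_truth, hier.bottom)
    return {
        "cfg": cfg,
        "reference": reference,
        "truth": study_truth,
        "study": study,
        "panel": panel,
        "typed": hier.bottom,
    }


@pytest.fixture
def knn_engine():
    return KNNGenotypeImputer(window_typed_markers=7, k_neighbors=3)


@pytest.fixture(scope="session")
def perfect_instance():
    """Noise-free, recombination-free population from 2 founder haplotypes.

    Every individual's genotype is fully determined by its founder pair, so a
    1-nearest-neighbor imputer with any distance-zero reference neighbor
    recovers every untyped call exactly.
    """
    cfg = SimConfig(
        n_founder_haplotypes=2,
        n_reference=30,
        n_study=8,
        n_markers=60,
        chrom_length=60_000,
        recomb_prob_per_interval=0.0,
        error_rate=0.0,
        maf_min=0.5,
        tier_sizes=(10, 30, 60),
        seed=5,
    )
    reference, study_truth, panel = simulate_truth(cfg)
    hier = build_panel_hierarchy(panel, cfg.tier_sizes)
    return {
        "cfg": cfg,
        "reference": reference,
        "truth": study_truth,
        "panel": panel,
        "hierarchy": hier,
    }
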