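"""Shared fixtures: small synthetic cohorts generated at test time."""

import pytest

from psopd import SimulationConfig, normalize_counts
from psopd.simulate import generate_serum_cohort, generate_skin_cohort


@pytest.fixture(scope="session")
def skin_small():
    """Small paired skin cohort: 6 subjects/arm, 600 genes, 60 disease genes."""
    cfg = SimulationConfig(seed=11, n_per_arm=6, n_genes=600, n_disease_genes=60)
    counts, meta, truth = generate_skin_cohort(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def skin_small_expr(skin_small):
    counts, meta, truth = skin_small
    return normalize_counts(counts), meta, truth


@pytest.fixture(scope="session")
def serum_small():
    """Serum cohort with the default decline kinetics, 12 subjects/arm."""
    cfg = SimulationConfig(seed=12, n_per_arm=12)
    return generate_serum_cohort(cfg)
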