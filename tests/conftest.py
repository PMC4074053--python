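"""Shared fixtures: small synthetic screens generated at test time."""

import numpy as np
import pytest

from endoscreen.synthetic import (
    Effect,
    ScreenConfig,
    generate_primary_screen,
)
from endoscreen import shape_stats


@pytest.fixture(scope="session")
def null_screen():
    """A small fully-null screen (no planted effects)."""
    cfg = ScreenConfig(n_genes=40, n_rows=4, n_cols=15, n_negative=12,
                       n_positive=4, cells_per_well_mean=120, seed=101)
    wells, truth = generate_primary_screen(cfg)
    return cfg, wells, truth


@pytest.fixture(scope="session")
def planted_screen():
    """A small screen with strong skew effects on known feature subsets."""
    effects = {}
    targets = {
        "g0000": ("Fint1", "Fint2", "Fint3"),
        "g0001": ("Fint1", "Fint2", "Fint3"),
        "g0002": ("Tint1", "Tint2"),
        "g0003": ("Tint1", "Tint2"),
        "g0004": ("NucSize",),
    }
    for gene, feats in targets.items():
        effects[gene] = {f: Effect("skew", 4.0) for f in feats}
    cfg = ScreenConfig(n_genes=40, n_rows=4, n_cols=15, n_negative=12,
                       n_positive=4, cells_per_well_mean=120,
                       effect_table=effects, seed=202)
    wells, truth = generate_primary_screen(cfg)
    return cfg, wells, truth


@pytest.fixture(scope="session")
def planted_zscores(planted_screen):
    _, wells, truth = planted_screen
    result = shape_stats.compute_zscore_matrix(wells, seed=7)
    return result, truth


@pytest.fixture(scope="session")
def null_zscores(null_screen):
    _, wells, _ = null_screen
    return shape_stats.compute_zscore_matrix(wells, seed=7)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.PCG64(12345))
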