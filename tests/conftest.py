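import numpy as np
import pandas as pd
import pytest

from mapkscreen import (
    EPISTASIS_ASSAYS,
    PlateNormalizer,
    SimConfig,
    aggregate_replicates,
    generate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """A small simulated screen shared across read-only tests."""
    cfg = SimConfig(n_genes=60, seed=11)
    wells, truth = generate_screen(cfg)
    return cfg, wells, truth


@pytest.fixture(scope="session")
def small_screen_matrix(small_screen):
    """Aggregated gene x assay value matrix for the small screen."""
    _, wells, truth = small_screen
    normalizer = PlateNormalizer().fit(wells)
    normalized = normalizer.transform(wells)
    agg = aggregate_replicates(normalized[normalized["role"] == "sample"])
    matrix = agg.pivot(index="reagent_id", columns="assay", values="value")
    return matrix, truth.set_index("gene_id")


def run_screen_to_calls(cfg: SimConfig):
    """Full screen -> normalized matrix + truth, used by recovery tests."""
    wells, truth = generate_screen(cfg)
    normalizer = PlateNormalizer().fit(wells)
    normalized = normalizer.transform(wells)
    agg = aggregate_replicates(normalized[normalized["role"] == "sample"])
    matrix = agg.pivot(index="reagent_id", columns="assay", values="value")
    return matrix, truth.set_index("gene_id")


def loop_uncentered_pearson(x, y, w):
    """Independent loop-based reference for the weighted uncentered correlation."""
    num = sxx = syy = 0.0
    for xi, yi, wi in zip(x, y, w):
        num += wi * xi * yi
        sxx += wi * xi * xi
        syy += wi * yi * yi
    return num / np.sqrt(sxx * syy)
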