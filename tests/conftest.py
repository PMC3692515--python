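"""Shared fixtures.

The heavy replicated-experiment fixtures are session-scoped so the whole
suite pays their simulation cost once.
"""

import numpy as np
import pandas as pd
import pytest

from markerh2.config import ExperimentGrid, SimulationConfig
from markerh2 import experiments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small population for fast end-to-end runs."""
    return SimulationConfig(
        N=60, S=0.5, n_generations=3, L_M=40, L_QTL=30, n_qtl_alleles=3,
        target_h2=0.4, seed=7, n_replicates=2,
    )


@pytest.fixture(scope="session")
def bias_table() -> pd.DataFrame:
    """Full-scale replicated experiment: N = 500, 10 generations, both
    mating regimes, all three heritabilities, all four SNP panel sizes,
    20 replicates, all three estimation methods."""
    grid = ExperimentGrid(
        selfing_rates=(0.0, 0.9),
        heritabilities=(0.15, 0.3, 0.6),
        panel_sizes=(384, 1500, 3000, 5000),
        population_sizes=(500,),
        n_replicates=20,
    )
    return experiments.run_grid(grid, experiment_seed=20201)


@pytest.fixture(scope="session")
def relatedness_table() -> pd.DataFrame:
    """Per-replicate relatedness structure (marker, pedigree and QTL
    kinship) for 20 replicates of each mating regime at 1500 SNPs."""
    frames = []
    for S in (0.0, 0.9):
        cfg = SimulationConfig(N=500, S=S, L_M=1500, target_h2=0.3, seed=50801)
        frames.append(experiments.relatedness_replicates(cfg, n_replicates=20, with_qtl=True))
    return pd.concat(frames, ignore_index=True)
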