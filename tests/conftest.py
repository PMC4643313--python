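import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lineagetx as lx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sim_small():
    """Small stage-structured simulation shared by read-only tests."""
    cfg = lx.SimConfig(n_genes=400, seed=11)
    em, truth = lx.simulate_counts(cfg)
    return cfg, em, truth


@pytest.fixture(scope="session")
def sim_recovery():
    """The planted-recovery study conditions: 2,000 genes, 200 dynamic in
    ten modules with 4-fold stage effects, dispersion 0.1, 4 replicates per
    stage."""
    cfg = lx.SimConfig(seed=7)
    em, truth = lx.simulate_counts(cfg)
    sf = lx.size_factors(em.counts)
    em.fpkm = lx.fpkm(em)
    em.vst = lx.vst(em.counts, sf)
    stages = em.stage_of()
    de = lx.de_all_pairs(em.counts, stages, factors=sf)
    return cfg, em, truth, sf, de


@pytest.fixture()
def tiny_counts():
    """3 genes x 4 samples (2 stages x 2 replicates), hand-sized."""
    counts = pd.DataFrame(
        {
            "a1": [10, 20, 30],
            "a2": [12, 18, 33],
            "b1": [40, 5, 30],
            "b2": [38, 6, 27],
        },
        index=["g1", "g2", "g3"],
    )
    stages = pd.Series(["A", "A", "B", "B"], index=counts.columns, name="stage")
    return counts, stages


@pytest.fixture()
def if_cells_null():
    cells, truth = lx.simulate_if_cells(
        n_embryos_per_treatment=4,
        cells_per_embryo=50,
        treatments=["DMSO", "X"],
        effects=None,
        seed=3,
    )
    return cells, truth
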