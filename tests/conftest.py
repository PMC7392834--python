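import numpy as np
import pandas as pd
import pytest

from aileqtl.datatypes import CovariateTable, GeneticMap, GenotypeMatrix
from aileqtl.linkage import genotype_probs
from aileqtl.simulate import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """A 59-bird, 4-chromosome cross with 6 cis eQTL and a 10-target hotspot."""
    cfg = SimConfig(seed=11, n_individuals=59, n_probesets=60, n_chromosomes=4,
                    n_cis=6, hotspot_targets=10)
    return simulate_cross(cfg)


@pytest.fixture(scope="session")
def small_grid(small_cross):
    cross, _ = small_cross
    return genotype_probs(cross.genotypes, cross.gmap, step_cm=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def single_marker_setup(rng):
    """One fully informative marker, n=40, no covariate structure."""
    n = 40
    ids = [f"i{k}" for k in range(n)]
    g = rng.choice(["RR", "RW", "WW"], p=[0.25, 0.5, 0.25], size=n)
    gmap = GeneticMap(pd.DataFrame({"marker": ["m1"], "chrom": ["1"], "pos_cm": [0.0]}))
    gm = GenotypeMatrix(pd.DataFrame(g[:, None], index=ids, columns=["m1"]))
    cov = CovariateTable(pd.DataFrame({"sex": ["F"] * n, "batch": ["b1"] * n}, index=ids))
    grid = genotype_probs(gm, gmap, step_cm=0, error_prob=0.0)
    return g, gmap, gm, cov, grid
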