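import numpy as np
import pytest

import snpherit as sh
from snpherit.reml import RemlModel, fit_reml


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate simulated cohort shared by read-only tests."""
    cfg = sh.SimConfig(
        n_individuals=300, n_snps=1200, n_chromosomes=4, h2_target=0.5, seed=7
    )
    G = sh.simulate_genotypes(cfg)
    table, truth = sh.simulate_phenotype(G, cfg)
    return cfg, G, table, truth


@pytest.fixture(scope="session")
def small_grm(small_cohort):
    _, G, _, _ = small_cohort
    return sh.compute_grm(G)


@pytest.fixture(scope="session")
def small_fit(small_cohort, small_grm):
    _, _, table, _ = small_cohort
    y = table.data["trait1"].to_numpy()
    return fit_reml(RemlModel(y=y, components={"genome": small_grm.values}))


def toy_grm(values, ids=None):
    """Build a GRM object from a plain matrix (counts filled with 100)."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if ids is None:
        ids = [f"s{i + 1}" for i in range(n)]
    return sh.GRM(
        values=values,
        pair_snp_counts=np.full((n, n), 100, dtype=np.int64),
        samples=np.asarray(ids, dtype=object),
    )
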