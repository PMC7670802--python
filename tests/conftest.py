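import numpy as np
import pandas as pd
import pytest

from gutherit.simulate import (SimTruth, StudyDesign,
                               simulate_otu_phenotypes,
                               simulate_pedigree_genotypes)


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_families=10, tanks_per_family=2, fish_per_tank=5,
                       n_snps=400, n_chromosomes=4)


@pytest.fixture(scope="session")
def small_genotypes(small_design):
    return simulate_pedigree_genotypes(small_design, seed=11)


@pytest.fixture(scope="session")
def small_truth():
    return SimTruth(h2=np.array([0.3, 0.1, 0.0]),
                    c2=np.array([0.1, 0.05, 0.0]),
                    seed=11)


@pytest.fixture(scope="session")
def small_sim(small_genotypes, small_truth):
    geno, fam = small_genotypes
    live, pheno, ln = simulate_otu_phenotypes(geno, fam, small_truth,
                                              depth=20000)
    return {"geno": geno, "family_map": fam, "live": live,
            "phenotypes": pheno, "ln": ln}


def make_tank_data(n_tanks=8, fish_per_tank=6, sigma_t=0.4, sigma_e=1.0,
                   seed=0):
    """Balanced tank-only dataset with a known one-way variance structure."""
    rng = np.random.default_rng(seed)
    n = n_tanks * fish_per_tank
    tank = np.repeat(np.arange(n_tanks), fish_per_tank)
    y = (rng.normal(0, np.sqrt(sigma_e), n)
         + rng.normal(0, np.sqrt(sigma_t), n_tanks)[tank])
    return y, tank


def anova_reml_oneway(y, tank):
    """Closed-form REML (= ANOVA) estimators for a balanced one-way design."""
    tank = np.asarray(tank)
    levels = np.unique(tank)
    k = len(levels)
    m = len(y) // k
    gm = y.mean()
    means = np.array([y[tank == t].mean() for t in levels])
    msb = m * np.sum((means - gm) ** 2) / (k - 1)
    msw = np.sum((y - means[np.searchsorted(levels, tank)]) ** 2) / (len(y) - k)
    return max((msb - msw) / m, 0.0), msw
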