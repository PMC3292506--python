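import numpy as np
import pytest

from gpcombine import (
    GenotypeMatrix,
    PopulationConfig,
    SimConfig,
    TraitSpec,
    simulate_study,
)


def uniform_rg(c, off):
    rg = np.full((c, c), float(off))
    np.fill_diagonal(rg, 1.0)
    return rg


@pytest.fixture(scope="session")
def small_study():
    """Two-population study small enough for fast model fits."""
    pops = [
        PopulationConfig("A", 120, 30, (1990, 2003), edc_mean=100.0),
        PopulationConfig("B", 120, 30, (1990, 2003), edc_mean=100.0),
    ]
    traits = [
        TraitSpec("yield", 0.35, 1.0, uniform_rg(2, 0.9), ["A", "B"]),
        TraitSpec("fert", 0.05, 1.0, uniform_rg(2, 0.7), ["A", "B"]),
    ]
    cfg = SimConfig(
        populations=pops, traits=traits, m_markers=300, n_qtl=60,
        n_chromosomes=5, seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture
def tiny_geno():
    """Three bulls × four markers with computable allele frequencies."""
    dosages = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 0, 1],
            [2, 0, 1, 1],
        ]
    )
    return GenotypeMatrix(bull_ids=["b1", "b2", "b3"], dosages=dosages)


def random_instance(rng, n, m):
    """Random polymorphic genotype matrix + weighted phenotypes."""
    p = rng.uniform(0.1, 0.9, size=m)
    dos = rng.binomial(2, p, size=(n, m))
    poly = (dos.mean(axis=0) > 0) & (dos.mean(axis=0) < 2)
    geno = GenotypeMatrix(
        bull_ids=[f"b{i}" for i in range(n)], dosages=dos[:, poly]
    )
    y = rng.standard_normal(n)
    w = rng.uniform(0.2, 5.0, size=n)
    return geno, y, w
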