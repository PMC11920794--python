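import numpy as np
import pytest

from meioscope import (
    SimConfig,
    arabidopsis_chromosomes,
    call_crossovers,
    segment_genotypes,
    simulate_f2_population,
)
from meioscope.models import ChromosomeModel


@pytest.fixture(scope="session")
def ara_chroms():
    return arabidopsis_chromosomes()


@pytest.fixture(scope="session")
def mini_chroms():
    """Two small chromosomes for fast pipeline-level tests."""
    return [
        ChromosomeModel("ChrA", 12_000_000, 5_000_000, ((4_000_000, 6_000_000),)),
        ChromosomeModel("ChrB", 9_000_000, 3_500_000, ((2_800_000, 4_200_000),)),
    ]


@pytest.fixture(scope="session")
def wt_population(ara_chroms):
    """One wild-type-like simulated population shared across tests:
    interfering crossovers (nu=5), 2% genotype error, 50 kb markers."""
    cfg = SimConfig(
        chromosomes=ara_chroms,
        class1_mean=1.8,
        nu=5.0,
        class2_mean=0.2,
        geno_error_p=0.02,
        marker_spacing=50_000,
        seed=424_242,
    )
    matrix, record = simulate_f2_population(cfg, 300)
    segments = segment_genotypes(matrix)
    events = call_crossovers(segments)
    return cfg, matrix, record, segments, events


@pytest.fixture()
def rng():
    return np.random.default_rng(8675309)
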