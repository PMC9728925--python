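import numpy as np
import pytest

from tcrot import GermlineCdrTable, Repertoire, SimConfig, TcrBeta, generate_background


@pytest.fixture(scope="session")
def germline() -> GermlineCdrTable:
    return GermlineCdrTable.default()


@pytest.fixture(scope="session")
def allele_pool(germline) -> list[str]:
    return germline.alleles


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_tcr(rng: np.random.Generator, alleles: list[str]) -> TcrBeta:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    length = int(rng.integers(8, 17))
    cdr3 = "C" + "".join(rng.choice(list(aa), size=length - 2)) + "F"
    return TcrBeta(alleles[int(rng.integers(len(alleles)))], cdr3)


@pytest.fixture(scope="session")
def small_pair(germline):
    """A deterministic 6-vs-8 repertoire pair for transport tests."""
    rng = np.random.default_rng(7)
    r1 = Repertoire.from_tcrs([random_tcr(rng, germline.alleles) for _ in range(6)])
    r2 = Repertoire.from_tcrs([random_tcr(rng, germline.alleles) for _ in range(8)])
    return r1, r2


@pytest.fixture(scope="session")
def background_pair(germline):
    """Two independent 60-clonotype background repertoires."""
    r1 = generate_background(SimConfig(seed=11, n_background=60), germline)
    r2 = generate_background(SimConfig(seed=12, n_background=60), germline)
    return r1, r2
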