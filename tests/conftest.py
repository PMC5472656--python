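import numpy as np
import pytest
from hypothesis import settings

from slatyper.library import (AlleleLibrary, AlleleRecord, SHORT_PRIMERS,
                              revcomp)
from slatyper.simulate import SimConfig, make_fixture_library, simulate_reads

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

# concrete realizations of the degenerate primer binding sites used to build
# toy templates by hand
FWD_SITE = "CGTGGACGACACGCAGTTC"
REV_SITE = revcomp("TCCAGTAGCGCAGGTCCTC")


def make_allele(name: str, insert: str, rng=None, flank: int = 20) -> AlleleRecord:
    """Toy allele: random flanks around primer-framed insert."""
    rng = rng or np.random.default_rng(abs(hash(name)) % 2**31)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    f5 = rng.choice(bases, flank).tobytes().decode()
    f3 = rng.choice(bases, flank).tobytes().decode()
    return AlleleRecord(name, f5 + FWD_SITE + insert + REV_SITE + f3)


def random_insert(rng, length: int = 282) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return rng.choice(bases, length).tobytes().decode()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_library(rng):
    """3 alleles: two share an identical insert (group pair), one unique."""
    shared = random_insert(rng)
    other = random_insert(rng)
    a1 = make_allele("SLA-1*01:01", shared, rng)
    return AlleleLibrary([
        a1,
        AlleleRecord("SLA-1*01:02", a1.sequence),  # same sequence, new name
        make_allele("SLA-2*05:01", other, rng),
    ])


@pytest.fixture(scope="session")
def fixture_pool():
    return make_fixture_library(4, divergence=6, seed=11, n_samples=6)


@pytest.fixture(scope="session")
def small_run(fixture_pool):
    """A small but complete simulated run shared across pipeline tests."""
    cfg = SimConfig(
        genotypes={"S01": ("HpSim-1", "HpSim-1"),
                   "S02": ("HpSim-1", "HpSim-2"),
                   "S03": ("HpSim-2", "HpSim-3")},
        depth_per_allele=400, seed=101)
    reads, truth = simulate_reads(fixture_pool, cfg)
    return fixture_pool, cfg, reads, truth
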