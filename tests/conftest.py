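import pytest

from mirap import bundled_adapter_library
from mirap.simulate import SimulationConfig, build_reference_pool, simulate_library

TRUSEQ = "TGGAATTCTCGGGTGCCAAGG"

MIRNA_ONLY = {"miRNA": 1.0, "rRNA": 0.0, "tRNA": 0.0, "snoRNA": 0.0, "other": 0.0}


@pytest.fixture(scope="session")
def adapter_library():
    return bundled_adapter_library()


@pytest.fixture(scope="session")
def small_pool():
    """A small synthetic reference: 10 hairpins plus companion pools."""
    return build_reference_pool(n_mirna=10, n_other_per_class=8, seed=11)


@pytest.fixture(scope="session")
def ligated_library(small_pool):
    """5k error-free miRNA reads ligated with the TruSeq small RNA adapter."""
    annotation, pools = small_pool
    cfg = SimulationConfig(
        n_reads=5000, class_fractions=dict(MIRNA_ONLY), adapter=TRUSEQ,
        mismatch_read_fraction=0.0, seed=5,
    )
    reads, truth = simulate_library(cfg, pools, annotation)
    return reads, truth, annotation


@pytest.fixture(scope="session")
def adapter_free_library(small_pool):
    """20k adapter-free mixed-class reads (artificial-dataset recipe, small n)."""
    annotation, pools = small_pool
    cfg = SimulationConfig(n_reads=20000, seed=6)
    reads, truth = simulate_library(cfg, pools, annotation)
    return reads, truth, annotation
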