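import numpy as np
import pytest

from popexpand import coalsim, seqio


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150)


@pytest.fixture
def toy_alignment():
    """Four 10-bp sequences with two segregating sites, hand-checkable."""
    return seqio.Alignment(
        ids=["a", "b", "c", "d"],
        seqs=[
            "AAAAAAAAAA",
            "AAAAAAAAAT",
            "AAAAAAAAAT",
            "AAAAACAAAT",
        ],
    )


@pytest.fixture(scope="session")
def constant_genealogy_n40():
    return coalsim.simulate_genealogy(
        40, coalsim.TwoEpochModel.constant(0.005), np.random.default_rng(11)
    )


@pytest.fixture(scope="session")
def constant_genealogy_n84():
    return coalsim.simulate_genealogy(
        84, coalsim.TwoEpochModel.constant(0.005), np.random.default_rng(12)
    )


@pytest.fixture(scope="session")
def simulated_study_dataset():
    """One study-scale dataset (n=84, L=352, 10 localities)."""
    return coalsim.generate_dataset(coalsim.study_config(seed=77))


def small_layout(n_loc=5, n=20):
    counts = [n // n_loc] * n_loc
    counts[0] += n - sum(counts)
    return coalsim.LocalityLayout(
        names=[f"L{i}" for i in range(n_loc)],
        lats=[44.0, 44.3, 44.6, 44.2, 44.8][:n_loc],
        lons=[14.2, 14.8, 14.5, 15.3, 15.0][:n_loc],
        counts=counts,
    )
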