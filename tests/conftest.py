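import numpy as np
import pytest

from asmatch.synth import MutationModel, make_families


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def random_dna_factory():
    return random_dna


@pytest.fixture(scope="session")
def small_families():
    """Small labelled family fixture shared across tests (seeded)."""
    within = MutationModel(sub_rate=0.03, ins_rate=0.005, del_rate=0.005)
    between = MutationModel(sub_rate=0.15, ins_rate=0.02, del_rate=0.02)
    records, _ = make_families(
        4, 6, 80, within, between, seed=11, with_distances=False
    )
    return records
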