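from __future__ import annotations

import numpy as np
import pytest

from spacerscan.core import CrisprArrayModel, ReferenceSet
from spacerscan.simulate import ErrorModel, SimulationConfig, simulate_run

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def model() -> CrisprArrayModel:
    return CrisprArrayModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_refs() -> ReferenceSet:
    r = np.random.default_rng(777)
    return ReferenceSet(
        chromosome=random_dna(r, 20_000),
        plasmid=random_dna(r, 3_000),
    )


@pytest.fixture(scope="session")
def clean_simulation():
    """Error-free simulation with no parental reads: the exact-recovery oracle."""
    cfg = SimulationConfig(
        seed=4242,
        n_events=120,
        plasmid_source_prob=0.5,
        parental_read_fraction=0.0,
        error_model=ErrorModel(0.0, 0.0, 0.0),
    )
    refs, model, events, reads = simulate_run(cfg)
    return cfg, refs, model, events, reads


@pytest.fixture(scope="session")
def noisy_simulation():
    """Default 2% total error rate with parental reads mixed in."""
    cfg = SimulationConfig(
        seed=99,
        n_events=150,
        plasmid_source_prob=0.5,
        parental_read_fraction=0.3,
    )
    refs, model, events, reads = simulate_run(cfg)
    return cfg, refs, model, events, reads
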