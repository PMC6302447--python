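import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from srnakit import DnaSequence, SyntheticSpec, gen_planted_dataset


def random_dna(rng: np.random.Generator, length: int, name: str = "s") -> DnaSequence:
    return DnaSequence(name, "".join(rng.choice(list("ACGT"), size=length)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequences(rng):
    """100 random sequences, lengths 45-120."""
    return [
        random_dna(rng, int(rng.integers(45, 121)), f"r{i}") for i in range(100)
    ]


@pytest.fixture(scope="session")
def planted_small():
    """Small planted 3-mer-bias dataset for classifier-level tests."""
    return gen_planted_dataset(
        SyntheticSpec(n_pos=40, length_bounds=(45, 120), effect_size=0.4, seed=7)
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Linearly separable toy: A-rich positives vs C-rich negatives."""
    rng = np.random.default_rng(99)
    pos, neg = [], []
    for i in range(20):
        L = int(rng.integers(45, 80))
        pos.append(
            DnaSequence(
                f"p{i}",
                "".join(rng.choice(list("ACGT"), size=L, p=[0.7, 0.1, 0.1, 0.1])),
            )
        )
        neg.append(
            DnaSequence(
                f"n{i}",
                "".join(rng.choice(list("ACGT"), size=L, p=[0.1, 0.7, 0.1, 0.1])),
            )
        )
    from srnakit import LabeledDataset

    return LabeledDataset(pos + neg, [1] * 20 + [0] * 20)
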