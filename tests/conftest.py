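import numpy as np
import pytest

from nrpred.encoding import ProteinSequence
from nrpred.properties import AMINO_ACIDS, load_reference_table


@pytest.fixture(scope="session")
def table():
    return load_reference_table()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sequence(rng, length: int, seq_id: str = "rnd") -> ProteinSequence:
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinSequence(seq_id, residues)


@pytest.fixture(scope="session")
def small_labeled_dataset():
    """A small, quickly separable dataset covering non-NR plus two subfamilies."""
    from nrpred.synthetic import GeneratorSpec, sample_dataset

    spec = GeneratorSpec(
        class_labels=("nonNR", "NR1", "NR2"),
        class_sizes=(10, 5, 5),
        length_range=(30, 90),
        separation=4.0,
        seed=42,
    )
    return sample_dataset(spec)
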