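import numpy as np
import pytest

from lncrnapred.features import feature_frame
from lncrnapred.synthetic import GeneratorSpec, generate_coding, generate_noncoding


@pytest.fixture(scope="session")
def small_dataset():
    """200 transcripts per class at generator defaults (fixed seed)."""
    spec = GeneratorSpec(n_per_class=200, seed=11)
    return generate_coding(spec) + generate_noncoding(spec)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Feature matrix + labels for the small synthetic dataset."""
    return feature_frame(small_dataset)


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
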