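import numpy as np
import pytest

from plasmasec.io_formats import LabeledDataset
from plasmasec.synthetic import (
    PlantedDatasetSpec,
    SecretoryLikeSpec,
    gen_end_to_end_corpus,
    gen_planted_dataset,
)


@pytest.fixture(scope="session")
def tiny_planted() -> LabeledDataset:
    """N=5 features, one strongly informative: cheap oracle playground."""
    return gen_planted_dataset(
        PlantedDatasetSpec(n_pos=30, n_neg=30, n_features=5,
                           informative=(0,), effect_size=3.0, seed=42)
    )


@pytest.fixture(scope="session")
def planted_n10() -> LabeledDataset:
    """The N=10 dataset used for oracle-equivalence checks."""
    return gen_planted_dataset(
        PlantedDatasetSpec(n_pos=30, n_neg=30, n_features=10,
                           informative=(0, 1), effect_size=2.0, seed=7)
    )


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory) -> dict:
    """A small on-disk secretory-like corpus shared across tests."""
    outdir = tmp_path_factory.mktemp("corpus") / "c"
    spec = SecretoryLikeSpec(n_per_class=12, length_range=(80, 160), seed=5)
    paths = gen_end_to_end_corpus(spec, outdir)
    paths["spec"] = spec
    return paths
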