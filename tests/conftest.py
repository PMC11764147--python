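import numpy as np
import pytest

from dgil6.pipeline import build_dataset_graphs, fit_embedding_projection
from dgil6.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small planted-signal dataset with graphs ready for training."""
    config = SyntheticConfig(seed=11, n_peptides=56, embedding_dim=24, length_range=(5, 12))
    manifest, contacts, embeddings = generate_dataset(config)
    projection = fit_embedding_projection(manifest.records, embeddings, k=10)
    graphs = build_dataset_graphs(manifest.records, contacts, embeddings, projection)
    return manifest, graphs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
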