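"""End-to-end wiring: inputs -> graphs -> trained model -> metrics.

These helpers glue the stage modules together the way the tool is meant to
be run: fit the embedding PCA on the training split only, featurize and
threshold every peptide into a graph, train the dual-channel classifier,
and score held-out peptides.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .estimator import DualChannelGraphClassifier
from .evaluation import MetricsReport, TrainConfig, apply_toggles, compute_metrics
from .features import (
    EMBEDDING_REDUCED_DIM,
    PcaProjection,
    featurize_peptide,
    fit_pca,
)
from .graphs import (
    DEFAULT_CONTACT_THRESHOLD,
    SHORT_RANGE_BINS,
    ContactBinTensor,
    PeptideGraph,
    build_adjacency,
    build_graph,
    contact_probability,
)
from .io_formats import DatasetManifest, PeptideRecord
from .synthetic import SyntheticConfig, generate_dataset

__all__ = [
    "fit_embedding_projection",
    "build_dataset_graphs",
    "split_manifest",
    "SyntheticRunResult",
    "run_synthetic_experiment",
]


def fit_embedding_projection(
    records: Sequence[PeptideRecord],
    embeddings: Mapping[str, np.ndarray],
    k: int = EMBEDDING_REDUCED_DIM,
) -> PcaProjection:
    """Fit the PCA on the pooled per-residue embeddings of training peptides."""
    rows = np.vstack([embeddings[r.id] for r in records])
    return fit_pca(rows, k=k)


def build_dataset_graphs(
    records: Sequence[PeptideRecord],
    contacts: Mapping[str, ContactBinTensor],
    embeddings: Mapping[str, np.ndarray] | None = None,
    projection: PcaProjection | None = None,
    threshold: float = DEFAULT_CONTACT_THRESHOLD,
    bin_range: tuple[int, int] = SHORT_RANGE_BINS,
    use_onehot: bool = True,
    use_position: bool = True,
) -> list[PeptideGraph]:
    """Featurize and threshold every peptide into a graph, in record order."""
    graphs = []
    for record in records:
        tensor = contacts[record.id]
        if tensor.length != len(record.sequence):
            raise ValueError(
                f"contact tensor of {record.id!r} has L={tensor.length}, "
                f"sequence has {len(record.sequence)}"
            )
        adjacency = build_adjacency(contact_probability(tensor, bin_range), threshold)
        features = featurize_peptide(
            record.sequence,
            embedding=None if embeddings is None else embeddings[record.id],
            projection=projection,
            use_onehot=use_onehot,
            use_position=use_position,
        )
        graphs.append(build_graph(record, features, adjacency))
    return graphs


def split_manifest(
    manifest: DatasetManifest, test_fraction: float = 0.2, seed: int = 0
) -> tuple[DatasetManifest, DatasetManifest]:
    """Stratified train/test split of a labelled manifest."""
    labels = manifest.labels
    idx_train, idx_test = train_test_split(
        np.arange(len(manifest)),
        test_size=test_fraction,
        random_state=seed,
        stratify=labels,
    )
    return (
        DatasetManifest([manifest.records[i] for i in sorted(idx_train)], "train"),
        DatasetManifest([manifest.records[i] for i in sorted(idx_test)], "test"),
    )


@dataclasses.dataclass
class SyntheticRunResult:
    report: MetricsReport
    estimator: DualChannelGraphClassifier
    scores: np.ndarray
    test_labels: np.ndarray
    train_graphs: list[PeptideGraph]
    test_graphs: list[PeptideGraph]


def run_synthetic_experiment(
    config: SyntheticConfig,
    train_config: TrainConfig | None = None,
    test_fraction: float = 0.2,
    pca_dim: int = EMBEDDING_REDUCED_DIM,
    toggles: Sequence[str] = (),
) -> SyntheticRunResult:
    """Generate, split 80/20, train and evaluate in one deterministic sweep.

    The PCA is fitted on training-split residues only; ablation toggles are
    applied identically to the train and test graphs.
    """
    train_config = train_config or TrainConfig(seed=config.seed)
    manifest, contacts, embeddings = generate_dataset(config)
    train_manifest, test_manifest = split_manifest(
        manifest, test_fraction=test_fraction, seed=config.seed
    )
    use_embedding = "no_embedding" not in toggles
    projection = (
        fit_embedding_projection(train_manifest.records, embeddings, k=pca_dim)
        if use_embedding
        else None
    )
    kwargs = dict(
        contacts=contacts,
        embeddings=embeddings if use_embedding else None,
        projection=projection,
    )
    train_graphs = build_dataset_graphs(train_manifest.records, **kwargs)
    test_graphs = build_dataset_graphs(test_manifest.records, **kwargs)
    remaining = [t for t in toggles if t != "no_embedding"]
    train_graphs, overrides = apply_toggles(train_graphs, set(remaining))
    test_graphs, _ = apply_toggles(test_graphs, set(remaining))
    est = train_config.make_estimator(**overrides)
    est.fit(train_graphs, train_manifest.labels)
    scores = est.predict_proba(test_graphs)[:, 1]
    report = compute_metrics(scores, test_manifest.labels, train_config.threshold)
    return SyntheticRunResult(
        report=report,
        estimator=est,
        scores=scores,
        test_labels=test_manifest.labels,
        train_graphs=train_graphs,
        test_graphs=test_graphs,
    )
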