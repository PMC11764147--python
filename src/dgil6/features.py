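"""Node featurization: one-hot, sinusoidal position encoding, reduced embeddings.

Each residue (graph node) is described by the concatenation, in fixed order,
of three blocks:

* ``onehot`` (20) — indicator of the residue type, columns in alphabetical
  one-letter-code order ('A' first);
* ``position`` (20) — sinusoidal encoding of the residue index,
  ``sin(pos / b^(2i/d))`` in even columns and ``cos`` in odd columns with
  ``b = 1000, d = 20``;
* ``embedding`` (30) — a protein-language-model per-residue embedding
  (1280-d for ESM-1b-style providers) reduced by PCA fitted on the pooled
  residue embeddings of the *training* peptides only.

Any block can be dropped for ablation; the full width is 70.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np
from sklearn.decomposition import PCA

from .io_formats import AMINO_ACIDS, validate_sequence

POSITION_BASE = 1000.0
POSITION_DIM = 20
EMBEDDING_REDUCED_DIM = 30
FULL_FEATURE_DIM = 70

#: ``provider(sequence) -> (L, E) ndarray``; shipped implementations are the
#: synthetic generator and a file-backed reader — a real language model is an
#: optional adapter, not a dependency.
EmbeddingProvider = Callable[[str], np.ndarray]

__all__ = [
    "NodeFeatureMatrix",
    "PcaProjection",
    "one_hot_encode",
    "position_encode",
    "fit_pca",
    "reduce_embedding",
    "fuse_features",
    "featurize_peptide",
]


@dataclasses.dataclass(frozen=True)
class NodeFeatureMatrix:
    """LxD node features with named column spans for the present blocks."""

    values: np.ndarray
    blocks: Mapping[str, tuple[int, int]]  # name -> (start, stop) column span

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        widths = sum(stop - start for start, stop in self.blocks.values())
        if widths != values.shape[1]:
            raise ValueError(
                f"block spans cover {widths} columns but the matrix has "
                f"{values.shape[1]}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "blocks", dict(self.blocks))

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def drop_blocks(self, names: set[str]) -> "NodeFeatureMatrix":
        """Return a copy without the named blocks (ablation support)."""
        keep = [n for n in self.blocks if n not in names]
        if not keep:
            raise ValueError("at least one feature block must remain")
        cols, spans, offset = [], {}, 0
        for name in keep:
            start, stop = self.blocks[name]
            cols.append(self.values[:, start:stop])
            spans[name] = (offset, offset + stop - start)
            offset += stop - start
        return NodeFeatureMatrix(values=np.hstack(cols), blocks=spans)


@dataclasses.dataclass(frozen=True)
class PcaProjection:
    """A fitted mean + orthonormal component matrix projecting E -> k."""

    mean: np.ndarray
    components: np.ndarray  # (E, k), orthonormal columns

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=np.float64)
        comp = np.asarray(self.components, dtype=np.float64)
        if comp.ndim != 2 or mean.ndim != 1 or comp.shape[0] != mean.shape[0]:
            raise ValueError("components must be (E, k) with an E-vector mean")
        if comp.shape[1] > comp.shape[0]:
            raise ValueError("cannot project to more dimensions than the input has")
        if not np.allclose(comp.T @ comp, np.eye(comp.shape[1]), atol=1e-6):
            raise ValueError("projection columns must be orthonormal")
        mean.setflags(write=False)
        comp.setflags(write=False)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "components", comp)

    @property
    def k(self) -> int:
        return self.components.shape[1]


def one_hot_encode(sequence: str) -> np.ndarray:
    """Lx20 indicator block; column order is the alphabetical residue code."""
    validate_sequence(sequence)
    idx = np.array([AMINO_ACIDS.index(ch) for ch in sequence])
    block = np.zeros((len(sequence), len(AMINO_ACIDS)))
    block[np.arange(len(sequence)), idx] = 1.0
    return block

def position_encode(
    length: int, base: float = POSITION_BASE, dim: int = POSITION_DIM
) -> np.ndarray:
    """Sinusoidal position block: sin at even columns, cos at odd columns."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if dim % 2:
        raise ValueError("position-encoding dimension must be even")
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / base ** (2 * i / dim)
    block = np.empty((length, dim))
    block[:, 0::2] = np.sin(angle)
    block[:, 1::2] = np.cos(angle)
    return block


def fit_pca(train_embeddings: np.ndarray, k: int = EMBEDDING_REDUCED_DIM) -> PcaProjection:
    """Fit a k-component PCA on stacked per-residue training embeddings.

    Only training-split residues may be passed in: the projection is applied
    unchanged to held-out peptides, so fitting here is the leakage boundary.
    The component sign is fixed deterministically (largest-magnitude loading
    positive) so that checkpoints are reproducible.
    """
    X = np.asarray(train_embeddings, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("training embeddings must be stacked into a 2-D array")
    n, E = X.shape
    if n <= k:
        raise ValueError(f"need more than k={k} residue rows to fit PCA, got {n}")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    informative = np.sum(pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1e-300))
    if informative < k:
        raise ValueError(
            f"training embeddings support only {informative} informative "
            f"directions, fewer than the requested k={k}"
        )
    components = pca.components_.T.copy()  # (E, k)
    for col in range(k):
        j = np.argmax(np.abs(components[:, col]))
        if components[j, col] < 0:
            components[:, col] *= -1.0
    return PcaProjection(mean=pca.mean_, components=components)


def reduce_embedding(embedding: np.ndarray, projection: PcaProjection) -> np.ndarray:
    """Project an LxE embedding matrix to Lxk: ``(emb - mean) @ components``."""
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.ndim != 2 or emb.shape[1] != projection.mean.shape[0]:
        raise ValueError(
            f"embedding width {emb.shape[-1] if emb.ndim == 2 else '?'} does not "
            f"match the projection input width {projection.mean.shape[0]}"
        )
    return (emb - projection.mean) @ projection.components


def fuse_features(
    onehot: np.ndarray | None = None,
    position: np.ndarray | None = None,
    embedding: np.ndarray | None = None,
) -> NodeFeatureMatrix:
    """Concatenate the present blocks in the fixed order onehot|position|embedding."""
    blocks = [
        (name, np.asarray(b, dtype=np.float64))
        for name, b in (("onehot", onehot), ("position", position), ("embedding", embedding))
        if b is not None
    ]
    if not blocks:
        raise ValueError("at least one feature block must be provided")
    rows = {b.shape[0] for _, b in blocks}
    if len(rows) != 1:
        raise ValueError(f"feature blocks disagree on the number of residues: {rows}")
    spans, offset = {}, 0
    for name, b in blocks:
        spans[name] = (offset, offset + b.shape[1])
        offset += b.shape[1]
    return NodeFeatureMatrix(values=np.hstack([b for _, b in blocks]), blocks=spans)


def featurize_peptide(
    sequence: str,
    embedding: np.ndarray | None = None,
    projection: PcaProjection | None = None,
    use_onehot: bool = True,
    use_position: bool = True,
) -> NodeFeatureMatrix:
    """Build the fused node-feature matrix for one peptide."""
    reduced = None
    if embedding is not None:
        if projection is None:
            raise ValueError("an embedding block requires a fitted PCA projection")
        reduced = reduce_embedding(embedding, projection)
    return fuse_features(
        onehot=one_hot_encode(sequence) if use_onehot else None,
        position=position_encode(len(sequence)) if use_position else None,
        embedding=reduced,
    )
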