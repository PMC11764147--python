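"""Peptide graph construction from predicted residue-contact distributions.

A structure predictor emits, for every residue pair, a probability
distribution over 37 distance bins (index 0 = no contact, indices 1..36 =
0.5 Angstrom segments from 2 Angstrom). The contact probability of a pair
is the summed mass of the short-range bins; thresholding it yields a binary
adjacency matrix with forced self-loops, which together with the node
feature matrix forms the graph both network channels consume.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import N_BINS, PeptideRecord

SHORT_RANGE_BINS = (1, 13)
"""Inclusive bin-index range summed into the contact probability.

Bin 1 starts at 2 Angstrom; 13 bins of 0.5 Angstrom reach 8.5 Angstrom.
The range is a knob because the 2-8 Angstrom description and the printed
summation limits (1..13) differ by one bin; the printed limits are the
default.
"""

DEFAULT_CONTACT_THRESHOLD = 0.8

__all__ = [
    "SHORT_RANGE_BINS",
    "DEFAULT_CONTACT_THRESHOLD",
    "ContactBinTensor",
    "ContactProbabilityMap",
    "AdjacencyMatrix",
    "PeptideGraph",
    "contact_probability",
    "build_adjacency",
    "build_graph",
    "write_edge_list",
]


@dataclasses.dataclass(frozen=True)
class ContactBinTensor:
    """LxLx37 per-pair probability distributions over distance bins."""

    bins: np.ndarray

    def __post_init__(self):
        bins = np.asarray(self.bins, dtype=np.float64)
        if bins.ndim != 3 or bins.shape[0] != bins.shape[1] or bins.shape[2] != N_BINS:
            raise ValueError(f"expected an LxLx{N_BINS} tensor, got shape {bins.shape}")
        if np.any(bins < -1e-12):
            raise ValueError("bin probabilities must be non-negative")
        if not np.allclose(bins, bins.transpose(1, 0, 2), atol=1e-6):
            raise ValueError("bin tensor must be symmetric in the residue indices")
        sums = bins.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError("per-pair bin distributions must sum to 1 +/- 1e-3")
        bins.setflags(write=False)
        object.__setattr__(self, "bins", bins)

    @property
    def length(self) -> int:
        return self.bins.shape[0]


@dataclasses.dataclass(frozen=True)
class ContactProbabilityMap:
    """Symmetric LxL matrix of per-pair contact probabilities."""

    prob: np.ndarray

    def __post_init__(self):
        prob = np.asarray(self.prob, dtype=np.float64)
        if prob.ndim != 2 or prob.shape[0] != prob.shape[1]:
            raise ValueError("contact map must be square")
        prob.setflags(write=False)
        object.__setattr__(self, "prob", prob)

    @property
    def length(self) -> int:
        return self.prob.shape[0]


@dataclasses.dataclass(frozen=True)
class AdjacencyMatrix:
    """Binary symmetric LxL adjacency with unit diagonal (self-loops)."""

    adj: np.ndarray

    def __post_init__(self):
        adj = np.asarray(self.adj)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isin(adj, (0, 1))):
            raise ValueError("adjacency must be binary")
        if not np.all(np.diag(adj) == 1):
            raise ValueError("adjacency must have self-loops on every node")
        adj = adj.astype(np.float64)
        adj.setflags(write=False)
        object.__setattr__(self, "adj", adj)

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]


@dataclasses.dataclass(frozen=True)
class PeptideGraph:
    """Immutable bundle of a peptide, its node features and adjacency."""

    record: PeptideRecord
    features: "NodeFeatureMatrix"  # noqa: F821 - defined in dgil6.features
    adjacency: AdjacencyMatrix

    def __post_init__(self):
        L = len(self.record.sequence)
        if self.features.values.shape[0] != L:
            raise ValueError(
                f"feature matrix has {self.features.values.shape[0]} rows for a "
                f"length-{L} peptide"
            )
        if self.adjacency.n_nodes != L:
            raise ValueError(
                f"adjacency is {self.adjacency.n_nodes}x{self.adjacency.n_nodes} "
                f"for a length-{L} peptide"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.record.sequence)

    @property
    def label(self) -> int | None:
        return self.record.label


def contact_probability(
    tensor: ContactBinTensor, bin_range: tuple[int, int] = SHORT_RANGE_BINS
) -> ContactProbabilityMap:
    """Sum each pair's short-range bin mass into a contact probability.

    ``bin_range`` is the inclusive (lo, hi) index range of bins counted as
    "in contact"; the default covers bins 1..13.
    """
    lo, hi = bin_range
    if not (1 <= lo <= hi < N_BINS):
        raise ValueError(f"bin range must lie within 1..{N_BINS - 1}")
    prob = tensor.bins[:, :, lo : hi + 1].sum(axis=2)
    return ContactProbabilityMap(prob=prob)


def build_adjacency(
    cmap: ContactProbabilityMap, threshold: float = DEFAULT_CONTACT_THRESHOLD
) -> AdjacencyMatrix:
    """Threshold the contact map into a binary adjacency with self-loops.

    An edge is present iff the contact probability is >= ``threshold``
    (boundary inclusive) or the pair is a diagonal entry.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"contact threshold must be in (0, 1), got {threshold}")
    adj = (cmap.prob >= threshold).astype(np.int64)
    np.fill_diagonal(adj, 1)
    return AdjacencyMatrix(adj=adj)


def build_graph(record: PeptideRecord, features, adj: AdjacencyMatrix) -> PeptideGraph:
    """Bundle features and adjacency into the graph both channels consume."""
    return PeptideGraph(record=record, features=features, adjacency=adj)


def write_edge_list(adj: AdjacencyMatrix, path) -> None:
    """Export the off-diagonal edges as a two-column TSV for inspection."""
    ii, jj = np.nonzero(np.triu(adj.adj, k=1))
    with open(path, "w") as fh:
        fh.write("i\tj\n")
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\n")
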