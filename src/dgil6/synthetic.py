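"""Synthetic peptides, contact-bin tensors and embeddings with a planted signal.

The generator emulates the inputs the real pipeline consumes — peptide
sequences, trRosetta-style LxLx37 distance-bin distributions, and
per-residue language-model embeddings — with a controllable class signal so
that every stage, and the end-to-end model, can be exercised without any
external database or pre-trained weights.

Positives carry a short sequence motif; the class signal is planted in two
independently toggleable places:

* **contacts** — residue pairs flanking the motif receive ``contact_signal``
  probability mass in the short-range bins, creating class-correlated extra
  edges after thresholding;
* **embeddings** — positive residues get a mean shift of magnitude
  ``embedding_effect`` along a fixed (seed-determined) direction on top of
  isotropic Gaussian noise.

When both signal knobs are zero the motif is not planted either, so the two
classes are drawn from exactly the same distribution and any classifier can
only reach chance performance. Both classes share class-neutral structure:
backbone neighbours are always in contact, and a small fraction of random
long-range pairs are too.

Residues are drawn uniformly over the 20-letter alphabet (simplicity over
natural amino-acid frequencies).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .features import fuse_features, one_hot_encode, position_encode
from .graphs import (
    ContactBinTensor,
    PeptideGraph,
    build_adjacency,
    build_graph,
    contact_probability,
)
from .io_formats import AMINO_ACIDS, N_BINS, DatasetManifest, PeptideRecord

__all__ = ["SyntheticConfig", "generate_dataset", "write_dataset", "worked_micrograph"]

_N_SHORT = 13  # bins 1..13
_N_LONG = N_BINS - _N_SHORT - 1  # bins 14..36 (bin 0 handled separately)


@dataclasses.dataclass(kw_only=True)
class SyntheticConfig:
    """Study conditions of the synthetic benchmark. The seed is mandatory."""

    seed: int
    n_peptides: int = 500
    length_range: tuple[int, int] = (5, 25)
    motif: str = "WKH"
    contact_signal: float = 0.9
    embedding_dim: int = 128
    embedding_effect: float = 2.0
    embedding_noise: float = 1.0
    positive_fraction: float = 0.5
    background_contact_rate: float = 0.1

    def __post_init__(self):
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError("length range must satisfy 1 <= min <= max")
        if len(self.motif) > lo:
            raise ValueError(
                f"motif {self.motif!r} is longer than the minimum peptide length {lo}"
            )
        for ch in self.motif:
            if ch not in AMINO_ACIDS:
                raise ValueError(f"motif residue {ch!r} is not a standard amino acid")
        for name in ("contact_signal", "positive_fraction", "background_contact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_peptides < 2 or self.embedding_dim < 1:
            raise ValueError("need at least 2 peptides and a positive embedding dim")

    @property
    def has_signal(self) -> bool:
        return self.contact_signal > 0 or self.embedding_effect > 0

    @classmethod
    def imbalanced_preset(cls, seed: int, **overrides) -> "SyntheticConfig":
        """The 292:2393 positive:negative imbalance of the benchmark training split."""
        kwargs = dict(n_peptides=2685, positive_fraction=292 / 2685)
        kwargs.update(overrides)
        return cls(seed=seed, **kwargs)


def _short_mass_distributions(rng: np.random.Generator, mass: np.ndarray) -> np.ndarray:
    """One 37-bin distribution per pair with the given short-range (1..13) mass."""
    mass = np.asarray(mass, dtype=np.float64)[:, None]
    w_short = rng.gamma(2.0, size=(mass.shape[0], _N_SHORT))
    w_short /= w_short.sum(axis=1, keepdims=True)
    w_long = rng.gamma(1.0, size=(mass.shape[0], _N_LONG + 1))  # bin 0 + long bins
    w_long /= w_long.sum(axis=1, keepdims=True)
    dist = np.empty((mass.shape[0], N_BINS))
    dist[:, 1 : _N_SHORT + 1] = mass * w_short
    long_part = (1.0 - mass) * w_long
    dist[:, 0] = long_part[:, 0]
    dist[:, _N_SHORT + 1 :] = long_part[:, 1:]
    return dist


def _make_contact_tensor(
    rng: np.random.Generator,
    length: int,
    signal_pairs: set[tuple[int, int]],
    contact_signal: float,
    background_rate: float,
) -> ContactBinTensor:
    pairs = [(i, j) for i in range(length) for j in range(i + 1, length)]
    mass = rng.beta(1.0, 15.0, size=len(pairs))  # diffuse long-range background
    for idx, (i, j) in enumerate(pairs):
        if j - i == 1:
            mass[idx] = rng.uniform(0.85, 0.98)  # backbone neighbours touch
        elif rng.random() < background_rate:
            mass[idx] = rng.uniform(0.5, 0.95)  # occasional genuine contact
        if (i, j) in signal_pairs:
            mass[idx] = contact_signal
    dists = _short_mass_distributions(rng, mass)
    bins = np.zeros((length, length, N_BINS))
    for idx, (i, j) in enumerate(pairs):
        bins[i, j] = bins[j, i] = dists[idx]
    bins[np.arange(length), np.arange(length), 1] = 1.0  # diagonal: trivially close
    return ContactBinTensor(bins=bins)


def _motif_signal_pairs(start: int, motif_len: int, length: int) -> set[tuple[int, int]]:
    """Residue pairs bracketing the motif that receive the contact signal."""
    left = [p for p in (start - 1, start) if 0 <= p < length]
    right = [p for p in (start + motif_len - 1, start + motif_len) if 0 <= p < length]
    return {(a, b) for a in left for b in right if b - a >= 2}


def generate_dataset(config: SyntheticConfig):
    """Draw a full dataset: ``(manifest, contact tensors, embeddings)`` by id.

    Fully reproducible: the same config (and seed) yields byte-identical
    sequences, tensors and embeddings. Class counts match
    ``positive_fraction`` within one sample.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_peptides
    n_pos = int(round(n * config.positive_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    direction = rng.normal(size=config.embedding_dim)
    direction /= np.linalg.norm(direction)

    lo, hi = config.length_range
    records, contacts, embeddings = [], {}, {}
    width = len(str(n))
    for i in range(n):
        pid = f"pep{i:0{width}d}"
        label = int(labels[i])
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=length))
        signal_pairs: set[tuple[int, int]] = set()
        if label == 1 and config.has_signal:
            start = int(rng.integers(0, length - len(config.motif) + 1))
            seq[start : start + len(config.motif)] = list(config.motif)
            if config.contact_signal > 0:
                signal_pairs = _motif_signal_pairs(start, len(config.motif), length)
        records.append(PeptideRecord(id=pid, sequence="".join(seq), label=label))
        contacts[pid] = _make_contact_tensor(
            rng, length, signal_pairs, config.contact_signal,
            config.background_contact_rate,
        )
        emb = rng.normal(0.0, config.embedding_noise, size=(length, config.embedding_dim))
        if label == 1:
            emb += config.embedding_effect * direction
        embeddings[pid] = emb
    return DatasetManifest(records=records), contacts, embeddings


def write_dataset(config: SyntheticConfig, out_dir) -> None:
    """Emit a generated dataset in the formats the real pipeline reads."""
    from pathlib import Path

    from .io_formats import write_contact_archive, write_embedding, write_fasta, write_manifest

    out = Path(out_dir)
    (out / "contacts").mkdir(parents=True, exist_ok=True)
    (out / "embeddings").mkdir(parents=True, exist_ok=True)
    manifest, contacts, embeddings = generate_dataset(config)
    write_manifest(manifest, out / "manifest.tsv")
    write_fasta(manifest.records, out / "peptides.fasta")
    for pid, tensor in contacts.items():
        write_contact_archive(tensor, out / "contacts" / f"{pid}.npz")
    for pid, emb in embeddings.items():
        write_embedding(emb, out / "embeddings" / f"{pid}.npy")


# ---------------------------------------------------------------------------
# the worked micrograph


def _micrograph_distribution(short_mass: float) -> np.ndarray:
    """Short-range mass spread evenly over bins 1..13, remainder in bin 0."""
    d = np.zeros(N_BINS)
    d[1 : _N_SHORT + 1] = short_mass / _N_SHORT
    d[0] = 1.0 - short_mass
    return d


def micrograph_tensor() -> ContactBinTensor:
    """The hand-written bin tensor behind :func:`worked_micrograph`.

    Pair short-range masses: backbone neighbours 0.9, pair (1,3) 0.85
    (an edge at threshold 0.8), pair (0,4) 0.5 (no edge), remaining
    long-range pairs 0.2.
    """
    masses = {(0, 1): 0.9, (1, 2): 0.9, (2, 3): 0.9, (3, 4): 0.9,
              (1, 3): 0.85, (0, 4): 0.5,
              (0, 2): 0.2, (0, 3): 0.2, (1, 4): 0.2, (2, 4): 0.2}
    bins = np.zeros((5, 5, N_BINS))
    for (i, j), m in masses.items():
        bins[i, j] = bins[j, i] = _micrograph_distribution(m)
    bins[np.arange(5), np.arange(5), 1] = 1.0
    return ContactBinTensor(bins=bins)


def worked_micrograph() -> PeptideGraph:
    """A fixed five-residue graph whose every stage is precomputable by hand.

    Sequence "ACDEF"; the embedding block is a small deterministic pattern
    (no provider involved) so the full 70-wide feature matrix is fixed.
    """
    sequence = "ACDEF"
    tensor = micrograph_tensor()
    adjacency = build_adjacency(contact_probability(tensor), threshold=0.8)
    emb = np.fromfunction(
        lambda i, j: ((i + 1) * (j + 1) % 7 - 3) * 0.1, (5, 30), dtype=float
    )
    features = fuse_features(
        onehot=one_hot_encode(sequence),
        position=position_encode(len(sequence)),
        embedding=emb,
    )
    record = PeptideRecord(id="micro", sequence=sequence, label=1)
    return build_graph(record, features, adjacency)
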