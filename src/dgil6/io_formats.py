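"""Readers and writers for every external representation the pipeline touches.

Sequences travel as FASTA or as a TSV manifest (``id``, ``sequence``,
``label``); residue-pair distance-bin distributions come from a
trRosetta-style ``.npz`` archive (or a plain-text dump for portability);
per-residue embeddings are 2-D array files; trained models round-trip
through an ``.npz`` checkpoint with the run configuration embedded.

Conventions fixed across the package:

* labels: ``1`` = IL-6-inducing (positive), ``0`` = non-inducing;
* distance-bin order: index 0 is the "no contact" bin, indices 1..36 are
  0.5 Angstrom bins starting at 2 Angstrom;
* non-standard residues (``X``, ``B``, ``Z``, ``U``, ...) are rejected —
  the featurization has no column for them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard residues, alphabetical one-letter codes."""

N_DISTANCE_BINS = 36
"""Number of 0.5-Angstrom distance segments covering 2-20 Angstrom."""

N_BINS = N_DISTANCE_BINS + 1  # + the no-contact bin
BIN_SUM_TOL = 1e-3

__all__ = [
    "AMINO_ACIDS",
    "N_DISTANCE_BINS",
    "N_BINS",
    "PeptideRecord",
    "DatasetManifest",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_manifest",
    "read_contact_archive",
    "write_contact_archive",
    "read_embedding",
    "write_embedding",
    "save_checkpoint",
    "load_checkpoint",
    "load_config",
    "save_config",
]


def n_distance_bins(d_min: float = 2.0, d_max: float = 20.0, width: float = 0.5) -> int:
    """Number of equal-width distance segments covering ``[d_min, d_max]``."""
    n = (d_max - d_min) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError("bin width does not evenly divide the distance range")
    return int(round(n))


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """A peptide: identifier, residue string, optional binary label."""

    id: str
    sequence: str
    label: int | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        validate_sequence(self.sequence, self.id)
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label of {self.id!r} must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


def validate_sequence(sequence: str, record_id: str = "?") -> None:
    if len(sequence) < 1:
        raise ValueError(f"sequence of {record_id!r} is empty")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} of record {record_id!r}: "
                f"only the 20 standard one-letter codes are accepted"
            )


@dataclasses.dataclass
class DatasetManifest:
    """An ordered peptide collection with a train/test/unsplit tag."""

    records: list[PeptideRecord]
    split_tag: str = "unsplit"

    def __post_init__(self):
        if self.split_tag not in ("train", "test", "unsplit"):
            raise ValueError(f"unknown split tag {self.split_tag!r}")
        _check_unique_ids(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        if any(r.label is None for r in self.records):
            raise ValueError("manifest contains unlabelled records")
        return np.array([r.label for r in self.records], dtype=int)


def _check_unique_ids(records: Iterable[PeptideRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate peptide id {r.id!r}")
        seen.add(r.id)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path) -> list[PeptideRecord]:
    """Read peptides from FASTA; sequences are uppercased, labels absent."""
    records = [
        PeptideRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[PeptideRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_manifest(path, split_tag: str = "unsplit") -> DatasetManifest:
    """Read a TSV manifest with columns ``id``, ``sequence``, ``label``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    for col in ("id", "sequence", "label"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        label = row.label
        if not (isinstance(label, (int, np.integer)) and label in (0, 1)):
            raise ValueError(
                f"label of record {row.id!r} must be 0 or 1, got {label!r}"
            )
        records.append(
            PeptideRecord(id=row.id, sequence=row.sequence.upper(), label=int(label))
        )
    return DatasetManifest(records=records, split_tag=split_tag)


def write_manifest(manifest: DatasetManifest, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "id": [r.id for r in manifest.records],
            "sequence": [r.sequence for r in manifest.records],
            "label": [r.label for r in manifest.records],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contact archives


def _validate_bins(bins: np.ndarray, expected_length: int | None, path) -> np.ndarray:
    bins = np.asarray(bins, dtype=np.float64)
    if bins.ndim != 3 or bins.shape[0] != bins.shape[1] or bins.shape[2] != N_BINS:
        raise ValueError(
            f"malformed contact archive {path}: expected an LxLx{N_BINS} array, "
            f"got shape {bins.shape}"
        )
    length = bins.shape[0]
    if expected_length is not None and length != expected_length:
        raise ValueError(
            f"contact archive {path} has L={length} but the peptide has "
            f"length {expected_length}"
        )
    sums = bins.sum(axis=2)
    if np.any(np.abs(sums - 1.0) > BIN_SUM_TOL):
        i, j = np.unravel_index(np.argmax(np.abs(sums - 1.0)), sums.shape)
        raise ValueError(
            f"malformed contact archive {path}: bin distribution of pair "
            f"({i},{j}) sums to {sums[i, j]:.6f}, outside 1 +/- {BIN_SUM_TOL}"
        )
    return bins


def read_contact_archive(path, expected_length: int | None = None):
    """Read an LxLx37 distance-bin probability tensor.

    ``.npz`` archives are read from their ``dist`` field (trRosetta layout);
    any other extension is parsed as a whitespace-delimited text dump whose
    first line is ``L n_bins`` followed by the flattened tensor.
    """
    from .graphs import ContactBinTensor

    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as archive:
            if "dist" not in archive:
                raise ValueError(
                    f"malformed contact archive {path}: no 'dist' field "
                    f"(fields: {sorted(archive.files)})"
                )
            bins = archive["dist"]
    else:
        with open(path) as fh:
            header = fh.readline().split()
            if len(header) != 2:
                raise ValueError(f"malformed contact archive {path}: bad header")
            length, nbins = int(header[0]), int(header[1])
            flat = np.loadtxt(fh, dtype=np.float64).ravel()
        if flat.size != length * length * nbins:
            raise ValueError(
                f"malformed contact archive {path}: header promises "
                f"{length * length * nbins} values, found {flat.size}"
            )
        bins = flat.reshape(length, length, nbins)
    bins = _validate_bins(bins, expected_length, path)
    return ContactBinTensor(bins=bins)


def write_contact_archive(tensor, path) -> None:
    """Write a tensor as ``.npz`` (``dist`` field) or as a text dump."""
    path = Path(path)
    bins = np.asarray(tensor.bins, dtype=np.float64)
    if path.suffix == ".npz":
        np.savez_compressed(path, dist=bins)
    else:
        with open(path, "w") as fh:
            fh.write(f"{bins.shape[0]} {bins.shape[2]}\n")
            np.savetxt(fh, bins.reshape(bins.shape[0], -1), fmt="%.8g")


# ---------------------------------------------------------------------------
# embeddings


def read_embedding(path) -> np.ndarray:
    """Read an LxE per-residue embedding matrix (``.npy`` or text)."""
    path = Path(path)
    emb = np.load(path) if path.suffix == ".npy" else np.loadtxt(path, ndmin=2)
    emb = np.asarray(emb, dtype=np.float64)
    if emb.ndim != 2:
        raise ValueError(f"embedding file {path} is not a 2-D array")
    return emb


def write_embedding(embedding: np.ndarray, path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(embedding, dtype=np.float64))
    else:
        np.savetxt(path, np.asarray(embedding, dtype=np.float64), fmt="%.8g")


# ---------------------------------------------------------------------------
# checkpoints and configs


def save_checkpoint(params, config: Mapping[str, Any], path) -> None:
    """Serialise model weights plus configuration to a single ``.npz``.

    The round trip is bit-exact: ``load_checkpoint(save_checkpoint(...))``
    reproduces every weight array.
    """
    state = params.state_dict()
    meta = {
        "config": dict(config),
        "shapes": {k: list(v.shape) for k, v in state.items()},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Load ``(ModelParams, config)``; shape metadata is cross-checked."""
    from .nn import ModelParams

    with np.load(path) as archive:
        if "__meta__" not in archive:
            raise ValueError(f"{path} is not a dgil6 checkpoint")
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    for key, shape in meta["shapes"].items():
        if key not in state or list(state[key].shape) != shape:
            raise ValueError(
                f"checkpoint {path} is inconsistent: array {key!r} does not "
                f"match its recorded shape {shape}"
            )
    params = ModelParams.from_state_dict(state, meta["config"])
    return params, meta["config"]


def save_graphs(graphs, path) -> None:
    """Bundle built peptide graphs (features + adjacency + records) as one npz."""
    meta, arrays = [], {}
    for i, g in enumerate(graphs):
        meta.append(
            {
                "id": g.record.id,
                "sequence": g.record.sequence,
                "label": g.record.label,
                "blocks": {k: list(v) for k, v in g.features.blocks.items()},
            }
        )
        arrays[f"g{i}.feat"] = g.features.values
        arrays[f"g{i}.adj"] = g.adjacency.adj
    header = json.dumps({"records": meta}).encode()
    np.savez(path, __meta__=np.frombuffer(header, dtype=np.uint8), **arrays)


def load_graphs(path):
    """Load a graph bundle written by :func:`save_graphs`, order preserved."""
    from .features import NodeFeatureMatrix
    from .graphs import AdjacencyMatrix, PeptideGraph

    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        graphs = []
        for i, rec in enumerate(meta["records"]):
            record = PeptideRecord(
                id=rec["id"],
                sequence=rec["sequence"],
                label=None if rec["label"] is None else int(rec["label"]),
            )
            features = NodeFeatureMatrix(
                values=archive[f"g{i}.feat"],
                blocks={k: tuple(v) for k, v in rec["blocks"].items()},
            )
            graphs.append(
                PeptideGraph(
                    record=record,
                    features=features,
                    adjacency=AdjacencyMatrix(adj=archive[f"g{i}.adj"]),
                )
            )
    return graphs


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh) or {}
        return json.load(fh)


def save_config(config: Mapping[str, Any], path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(dict(config), fh)
        else:
            json.dump(dict(config), fh, indent=2)
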