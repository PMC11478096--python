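"""Per-residue protein embeddings: container, on-disk store, and embedders.

A protein of length ``l`` is represented by a matrix ``e`` of shape
``(l, D)`` whose rows are per-residue vectors produced by a protein
language model (pLM).  The pipeline is dimension-agnostic: production
models use large ``D`` (ESM2-15b emits D=5120), while tests and the
synthetic generator use small dimensions.

Two embedder backends are provided:

* ``PrecomputedEmbedder`` — looks matrices up in an :class:`EmbeddingStore`
  (the normal route: embeddings are computed once, off-line, and stored).
* ``SyntheticEmbedder`` — deterministic pseudo-embeddings derived from the
  sequence content; used for testing and simulation.

An optional adapter for running an ESM2 model in-process exists
(:class:`ESM2Embedder`) but requires the ``esm`` package and a GPU-scale
budget; nothing in this package depends on it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "EmbeddingStore",
    "store_embeddings",
    "load_embeddings",
    "PrecomputedEmbedder",
    "SyntheticEmbedder",
    "ESM2Embedder",
    "get_embedder",
]


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Per-residue embedding of one protein.

    Attributes
    ----------
    protein_id : str
        Identifier of the embedded protein.
    matrix : numpy.ndarray
        Array of shape ``(l, D)``; row ``i`` is the vector for residue ``i``.
    model_tag : str
        Name of the model that produced the vectors (e.g. ``"esm2_t48_15B"``
        or ``"synthetic"``).
    """

    protein_id: str
    matrix: np.ndarray
    model_tag: str = "unknown"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
            raise ValueError(
                f"embedding for {self.protein_id!r} must be a non-empty 2-D "
                f"matrix, got shape {m.shape}"
            )
        if not np.all(np.isfinite(m)):
            raise ValueError(f"embedding for {self.protein_id!r} contains non-finite values")
        object.__setattr__(self, "matrix", m)

    @property
    def length(self) -> int:
        """Number of residues ``l``."""
        return int(self.matrix.shape[0])

    @property
    def dim(self) -> int:
        """Vector dimension ``D``."""
        return int(self.matrix.shape[1])


class EmbeddingStore(Mapping[str, EmbeddingMatrix]):
    """In-memory mapping of protein id -> :class:`EmbeddingMatrix`.

    All matrices in one store share the vector dimension ``D``; adding a
    matrix with a different ``D`` is rejected.
    """

    def __init__(self, matrices: Iterable[EmbeddingMatrix] = (), model_tag: str | None = None):
        self._data: dict[str, EmbeddingMatrix] = {}
        self._dim: int | None = None
        self.model_tag = model_tag
        for m in matrices:
            self.add(m)

    def add(self, m: EmbeddingMatrix) -> None:
        if m.protein_id in self._data:
            raise ValueError(f"duplicate embedding id {m.protein_id!r}")
        if self._dim is None:
            self._dim = m.dim
        elif m.dim != self._dim:
            raise ValueError(
                f"mixed embedding dimensions in store: have D={self._dim}, "
                f"got D={m.dim} for {m.protein_id!r}"
            )
        if self.model_tag is None:
            self.model_tag = m.model_tag
        self._data[m.protein_id] = m

    @property
    def dim(self) -> int | None:
        return self._dim

    def __getitem__(self, protein_id: str) -> EmbeddingMatrix:
        try:
            return self._data[protein_id]
        except KeyError:
            raise KeyError(f"no embedding stored for id {protein_id!r}") from None

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def save(self, path) -> None:
        store_embeddings(self._data.values(), path)

    @classmethod
    def open(cls, path, ids: Sequence[str] | None = None) -> "EmbeddingStore":
        return load_embeddings(path, ids)


def store_embeddings(matrices: Iterable[EmbeddingMatrix], path) -> None:
    """Write embeddings to an HDF5 file, one float32 dataset per protein id.

    Layout: datasets live in a flat root group keyed by protein id; the
    file carries ``model_tag`` and ``dim`` as attributes.  Round-trips are
    bit-exact for float32 payloads.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("refusing to write an empty embedding store")
    dims = {m.dim for m in matrices}
    if len(dims) != 1:
        raise ValueError(f"matrices have mixed dimensions {sorted(dims)}")
    tags = {m.model_tag for m in matrices}
    ids = [m.protein_id for m in matrices]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids")
    with h5py.File(path, "w") as fh:
        fh.attrs["dim"] = dims.pop()
        fh.attrs["model_tag"] = tags.pop() if len(tags) == 1 else "mixed"
        for m in matrices:
            # track_times=False keeps files byte-identical across runs
            fh.create_dataset(m.protein_id, data=m.matrix.astype(np.float32), track_times=False)


def load_embeddings(path, ids: Sequence[str] | None = None) -> EmbeddingStore:
    """Read embeddings back from an HDF5 store.

    Parameters
    ----------
    ids : sequence of str, optional
        Load only these proteins.  Missing ids raise a ``KeyError`` that
        lists every absent id.
    """
    store = EmbeddingStore()
    with h5py.File(path, "r") as fh:
        tag = str(fh.attrs.get("model_tag", "unknown"))
        store.model_tag = tag
        wanted = list(ids) if ids is not None else list(fh.keys())
        missing = [i for i in wanted if i not in fh]
        if missing:
            raise KeyError(f"ids absent from embedding store {path}: {missing}")
        for pid in wanted:
            store.add(EmbeddingMatrix(pid, fh[pid][()], model_tag=tag))
    return store


@dataclass
class PrecomputedEmbedder:
    """Embedder backend that returns matrices already present in a store."""

    store: Mapping[str, EmbeddingMatrix]

    def embed(self, protein_id: str, sequence: str) -> EmbeddingMatrix:
        if protein_id not in self.store:
            raise KeyError(f"no precomputed embedding for id {protein_id!r}")
        m = self.store[protein_id]
        if m.length != len(sequence):
            raise ValueError(
                f"embedding/sequence length mismatch for {protein_id!r}: "
                f"embedding has {m.length} rows, sequence has {len(sequence)} residues"
            )
        return m


@dataclass
class SyntheticEmbedder:
    """Deterministic pseudo-embeddings for testing.

    Each residue vector is drawn from a normal distribution seeded by the
    (seed, sequence) pair, so identical sequences always embed identically
    and the row count equals the sequence length.
    """

    dim: int = 16
    seed: int = 0
    model_tag: str = field(default="synthetic", init=False)

    def embed(self, protein_id: str, sequence: str) -> EmbeddingMatrix:
        if len(sequence) == 0:
            raise ValueError(f"cannot embed empty sequence for {protein_id!r}")
        digest = hashlib.sha256(f"{self.seed}:{sequence}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        matrix = rng.standard_normal((len(sequence), self.dim)).astype(np.float32)
        return EmbeddingMatrix(protein_id, matrix, model_tag=self.model_tag)


class ESM2Embedder:
    """Adapter that runs an ESM2 checkpoint in-process (optional).

    Requires the ``esm`` package (fair-esm) and substantial compute: the
    15-billion-parameter checkpoint emits D=5120 vectors and is impractical
    without a GPU.  Representations are taken from the final transformer
    layer by default; the layer used is recorded in ``model_tag``.
    """

    def __init__(self, model_name: str = "esm2_t48_15B_UR50D", repr_layer: int | None = None):
        try:
            import esm  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the ESM2 adapter requires the 'esm' package (pip install fair-esm)"
            ) from exc
        self._esm = esm
        self.model, self.alphabet = esm.pretrained.load_model_and_alphabet(model_name)
        self.model.eval()
        self.repr_layer = repr_layer if repr_layer is not None else self.model.num_layers
        self.model_tag = f"{model_name}:layer{self.repr_layer}"

    def embed(self, protein_id: str, sequence: str) -> EmbeddingMatrix:  # pragma: no cover
        import torch  # type: ignore

        if len(sequence) == 0:
            raise ValueError(f"cannot embed empty sequence for {protein_id!r}")
        batch_converter = self.alphabet.get_batch_converter()
        _, _, tokens = batch_converter([(protein_id, sequence)])
        with torch.no_grad():
            out = self.model(tokens, repr_layers=[self.repr_layer])
        # strip BOS/EOS tokens
        reps = out["representations"][self.repr_layer][0, 1 : len(sequence) + 1].numpy()
        return EmbeddingMatrix(protein_id, reps, model_tag=self.model_tag)


def get_embedder(backend: str, **kwargs):
    """Instantiate an embedder backend by name.

    ``backend`` is one of ``"precomputed"``, ``"synthetic"`` or ``"esm2"``.
    """
    backends = {
        "precomputed": PrecomputedEmbedder,
        "synthetic": SyntheticEmbedder,
        "esm2": ESM2Embedder,
    }
    try:
        cls = backends[backend]
    except KeyError:
        raise ValueError(
            f"unknown embedder backend {backend!r}; choose from {sorted(backends)}"
        ) from None
    return cls(**kwargs)
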