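"""Reference-set ("bait") data model and per-class length ranges.

Annotation transfer needs a curated, labeled reference set: every
reference protein carries a class label and a per-residue embedding and
acts as a *bait* that can capture query proteins ("preys") through
embedding-based alignment.  Because class membership in a superfamily like
the GSTs is ultimately a statement about fold conservation, each class
also gets a reference length range (RLR) — the closed interval spanned by
its bait lengths — used later to triage predictions by how plausible
structural conservation is at the query's length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .embeddings import EmbeddingMatrix

__all__ = [
    "ProteinRecord",
    "Bait",
    "ClassLengthRange",
    "ReferenceSet",
    "load_reference_set",
    "compute_rlr",
    "class_identity_range",
]

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: id, sequence, and optional taxon / expected class."""

    id: str
    sequence: str
    taxon: str | None = None
    expected_class: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {self.id!r} has non-amino-acid characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Bait:
    """A reference protein with its class label and embedding."""

    record: ProteinRecord
    class_label: str
    embedding: EmbeddingMatrix

    def __post_init__(self) -> None:
        if not self.class_label:
            raise ValueError(f"bait {self.record.id!r} has an empty class label")
        if self.embedding.length != self.record.length:
            raise ValueError(
                f"bait {self.record.id!r}: embedding has {self.embedding.length} rows "
                f"but sequence has {self.record.length} residues"
            )

    @property
    def id(self) -> str:
        return self.record.id


@dataclass(frozen=True)
class ClassLengthRange:
    """Closed interval [min_len, max_len] of bait lengths for one class."""

    class_label: str
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError(
                f"invalid length range for {self.class_label!r}: "
                f"[{self.min_len}, {self.max_len}]"
            )

    def __contains__(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


class ReferenceSet:
    """Collection of baits indexed by id and by class."""

    def __init__(self, baits: Iterable[Bait]):
        self.baits: list[Bait] = list(baits)
        if not self.baits:
            raise ValueError("reference set is empty")
        self.by_id: dict[str, Bait] = {}
        self.by_class: dict[str, list[Bait]] = {}
        dims = set()
        for b in self.baits:
            if b.id in self.by_id:
                raise ValueError(f"duplicate bait id {b.id!r}")
            self.by_id[b.id] = b
            self.by_class.setdefault(b.class_label, []).append(b)
            dims.add(b.embedding.dim)
        if len(dims) != 1:
            raise ValueError(f"baits have mixed embedding dimensions {sorted(dims)}")
        self.dim: int = dims.pop()

    def __len__(self) -> int:
        return len(self.baits)

    @property
    def classes(self) -> list[str]:
        return sorted(self.by_class)

    def rlr(self) -> dict[str, ClassLengthRange]:
        return compute_rlr(self)


def load_reference_set(fasta_path, labels_path, embedding_store: Mapping[str, EmbeddingMatrix]) -> ReferenceSet:
    """Assemble a :class:`ReferenceSet` from FASTA + labels TSV + embeddings.

    The labels file is tab-separated with a header row and columns
    ``id``, ``class`` and optionally ``taxon``.  Every FASTA record must
    have a label and an embedding whose row count equals its length.
    """
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if "id" not in labels.columns or "class" not in labels.columns:
        raise ValueError(f"labels file {labels_path} must have 'id' and 'class' columns")
    labels = labels.set_index("id")

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no records in FASTA file {fasta_path}")

    baits = []
    for rec in records:
        pid = rec.id
        if pid not in labels.index:
            raise ValueError(f"protein {pid!r} has no entry in the labels file")
        row = labels.loc[pid]
        taxon = row.get("taxon")
        taxon = None if pd.isna(taxon) else str(taxon)
        protein = ProteinRecord(pid, str(rec.seq), taxon=taxon)
        if pid not in embedding_store:
            raise ValueError(f"protein {pid!r} has no embedding in the store")
        baits.append(Bait(protein, str(row["class"]), embedding_store[pid]))
    return ReferenceSet(baits)


def compute_rlr(refset: ReferenceSet) -> dict[str, ClassLengthRange]:
    """Per-class reference length range: min/max over bait lengths.

    The interval is closed on both ends; a query of exactly the shortest
    or longest bait length counts as within range.
    """
    out = {}
    for label, baits in refset.by_class.items():
        if not baits:
            raise ValueError(f"class {label!r} has no baits")
        lengths = [b.record.length for b in baits]
        out[label] = ClassLengthRange(label, min(lengths), max(lengths))
    return out


def class_identity_range(
    refset: ReferenceSet,
    class_label: str,
    identity_fn: Callable[[str, str], float] | None = None,
) -> tuple[float, float]:
    """Min/max pairwise sequence identity (%) among one class's baits.

    Requires at least two baits; with exactly two, min equals max.
    """
    if identity_fn is None:
        from .curation import sequence_identity

        identity_fn = sequence_identity
    try:
        baits = refset.by_class[class_label]
    except KeyError:
        raise KeyError(f"unknown class {class_label!r}") from None
    if len(baits) < 2:
        raise ValueError(
            f"class {class_label!r} has {len(baits)} bait(s); "
            "pairwise identity needs at least two"
        )
    idents = [
        identity_fn(a.record.sequence, b.record.sequence)
        for i, a in enumerate(baits)
        for b in baits[i + 1 :]
    ]
    return (min(idents), max(idents))
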