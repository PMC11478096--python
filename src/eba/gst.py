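"""Packaged glutathione S-transferase (GST) superfamily summaries.

The GST superfamily (EC 2.5.1.18) comprises ~20 classes across cytosolic,
mitochondrial (Kappa) and microsomal (MAPEG) compartments.  This module
ships three published summary tables as plain TSV data:

* ``refset_summary`` — the curated 284-protein reference set: per class,
  counts by taxonomic group and the shortest/longest member length
  (the class's reference length range, RLR).
* ``testing_counts`` — benchmark of embedding-based classification
  against the rule-based UniProt annotation of 15,061 GST proteins:
  per class, expected vs. agreeing predictions split by length region.
* ``trial_counts`` — classification of 64,207 previously unclassified
  GST proteins: per-taxon class counts plus region totals.

It also builds a synthetic stand-in for the reference set itself
(:func:`synthetic_gst_refset`): real class labels, taxon assignments and
length ranges from the summary table, with synthetic sequences and
embeddings, so the full pipeline is exercisable without downloading the
curated sequences.  Users with the real reference FASTA/embeddings load
them through :func:`eba.refset.load_reference_set` instead.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .embeddings import EmbeddingMatrix, store_embeddings
from .refset import Bait, ProteinRecord, ReferenceSet
from .synthetic import _AA20

__all__ = [
    "TAXA",
    "load_refset_summary",
    "load_testing_counts",
    "load_trial_counts",
    "synthetic_gst_refset",
    "write_gst_fixture",
]

TAXA = [
    "bacteria", "amoebozoa", "fungi", "viridiplantae", "platyhelminthes",
    "nematoda", "arthropoda", "mollusca", "actinopterygii", "amphibia",
    "aves", "mammalia",
]


def _read(name: str, index_col: str) -> pd.DataFrame:
    with resources.files("eba.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", index_col=index_col)


def load_refset_summary() -> pd.DataFrame:
    """Reference-set composition: per class, taxon counts and length range."""
    return _read("refset_summary.tsv", "class")


def load_testing_counts() -> pd.DataFrame:
    """Labeled-benchmark counts: per class, Exp/Pred by length region."""
    return _read("testing_counts.tsv", "class")


def load_trial_counts() -> pd.DataFrame:
    """Unlabeled-survey counts: per-taxon class counts and region totals."""
    return _read("trial_counts.tsv", "row")


def synthetic_gst_refset(dim: int = 32, seed: int = 0) -> ReferenceSet:
    """Synthetic stand-in for the curated GST reference set.

    Class labels, per-taxon membership counts and per-class length ranges
    follow the packaged summary table (284 baits, 20 classes); sequences
    and embeddings are synthetic.  Bait lengths are spread evenly across
    each class's length range including both endpoints, so the derived
    reference length ranges reproduce the published ones exactly.
    """
    summary = load_refset_summary()
    rng = np.random.default_rng(seed)
    n_classes = len(summary)
    if n_classes > dim:
        raise ValueError(f"dim={dim} too small for {n_classes} separable classes")
    # one centroid per class, mutually equidistant
    q, _ = np.linalg.qr(rng.standard_normal((dim, n_classes)))
    cents = q.T * 6.0 / np.sqrt(2.0)

    baits: list[Bait] = []
    for k, (label, row) in enumerate(summary.iterrows()):
        total = int(row["total"])
        lengths = np.unique(
            np.linspace(int(row["min_len"]), int(row["max_len"]), num=max(total, 2))
            .round().astype(int)
        )
        taxa = [t for t in TAXA for _ in range(int(row[t]))]
        assert len(taxa) == total
        for i, taxon in enumerate(taxa):
            length = int(lengths[i % len(lengths)])
            if i == 0:
                length = int(row["min_len"])
            elif i == 1 and total >= 2:
                length = int(row["max_len"])
            pid = f"{label}_{taxon[:4]}_{i:03d}"
            seq = "".join(rng.choice(_AA20, size=length))
            matrix = (cents[k] + rng.normal(0.0, 0.75, size=(length, dim))).astype(np.float32)
            baits.append(
                Bait(ProteinRecord(pid, seq, taxon=taxon), str(label),
                     EmbeddingMatrix(pid, matrix, model_tag="synthetic"))
            )
    return ReferenceSet(baits)


def write_gst_fixture(out_dir, dim: int = 32, seed: int = 0) -> dict:
    """Materialise the synthetic reference set as FASTA + labels TSV + HDF5.

    Returns the three paths, suitable for
    :func:`eba.refset.load_reference_set`.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refset = synthetic_gst_refset(dim=dim, seed=seed)
    fasta = out / "gst_refset.fasta"
    labels = out / "gst_refset_labels.tsv"
    h5 = out / "gst_refset_embeddings.h5"
    with open(fasta, "w") as fh:
        for b in refset.baits:
            fh.write(f">{b.id}\n{b.record.sequence}\n")
    with open(labels, "w") as fh:
        fh.write("id\tclass\ttaxon\n")
        for b in refset.baits:
            fh.write(f"{b.id}\t{b.class_label}\t{b.record.taxon or ''}\n")
    store_embeddings((b.embedding for b in refset.baits), h5)
    return {"fasta": fasta, "labels": labels, "embeddings": h5}
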