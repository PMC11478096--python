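"""Class-structured synthetic proteins and embeddings.

The generator emulates the geometry that makes embedding-based
classification work: each class has a centroid vector in embedding
space, every residue vector of a protein is its class centroid plus a
smooth positional drift (so residues are not i.i.d., mimicking
context-aware embeddings) plus isotropic noise.  Sequences are drawn
from class-specific residue-frequency profiles, and query lengths can be
placed inside, below or above each class's configured length range so
the length-triage machinery is exercised end to end.

Class centroids are placed with an exact minimum pairwise separation
``Δ`` (delta); the noise level ``σ`` (sigma) is expressed in the same
units.  The default calibration — 5 classes, D=32, ``σ = Δ/8`` — is the
configuration under which the recovery benchmarks of the test suite are
defined, and is fixed here rather than per-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import ClassificationRecord
from .embeddings import EmbeddingMatrix, EmbeddingStore
from .refset import Bait, ProteinRecord, ReferenceSet

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "make_table_counts"]

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic benchmark.

    ``class_length_ranges`` maps class label -> (min, max) residue
    counts; when ``None``, ``n_classes`` overlapping GST-like ranges are
    used.  ``region_mix`` gives the proportions of query lengths falling
    within / below / above their class range.
    """

    n_classes: int = 5
    dim: int = 32
    class_length_ranges: Mapping[str, tuple[int, int]] | None = None
    centroid_separation: float = 6.0
    residue_noise_sd: float = 0.75  # default calibration: Δ/8
    drift_amplitude: float | None = None  # defaults to residue_noise_sd
    n_baits_per_class: int = 20
    n_queries_per_class: int = 20
    region_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_classes > self.dim:
            raise ValueError("centroid construction requires n_classes <= dim")
        if self.centroid_separation <= 0:
            raise ValueError("centroid separation must be positive")
        if self.residue_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if abs(sum(self.region_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.region_mix):
            raise ValueError(f"region_mix must be non-negative and sum to 1, got {self.region_mix}")

    def ranges(self) -> dict[str, tuple[int, int]]:
        if self.class_length_ranges is not None:
            out = {str(k): (int(a), int(b)) for k, (a, b) in self.class_length_ranges.items()}
        else:
            # overlapping ranges, loosely like cytosolic GST classes
            out = {
                f"class{k}": (170 + 6 * k, 230 + 6 * k) for k in range(self.n_classes)
            }
        if len(out) != self.n_classes:
            raise ValueError("class_length_ranges must have one entry per class")
        for label, (lo, hi) in out.items():
            if not (1 <= lo <= hi):
                raise ValueError(f"bad length range for {label!r}: ({lo}, {hi})")
        return out


@dataclass
class SyntheticDataset:
    """Output of :func:`generate`."""

    refset: ReferenceSet
    queries: list[tuple[ProteinRecord, EmbeddingMatrix]]
    store: EmbeddingStore
    config: SyntheticConfig

    @property
    def true_labels(self) -> dict[str, str]:
        return {q.id: q.expected_class for q, _ in self.queries}


def _centroids(rng: np.random.Generator, k: int, dim: int, sep: float) -> np.ndarray:
    """K centroid vectors with pairwise Euclidean distance exactly ``sep``.

    A random orthonormal frame scaled by ``sep / sqrt(2)``: orthogonal
    equal-norm vectors are mutually equidistant.
    """
    q, _ = np.linalg.qr(rng.standard_normal((dim, k)))
    return (q * (sep / np.sqrt(2.0))).T  # shape (k, dim)


def _protein_embedding(
    rng: np.random.Generator,
    protein_id: str,
    centroid: np.ndarray,
    length: int,
    noise_sd: float,
    drift_amp: float,
) -> EmbeddingMatrix:
    dim = centroid.shape[0]
    rows = np.tile(centroid, (length, 1))
    if drift_amp > 0:
        u = rng.standard_normal(dim)
        u /= np.linalg.norm(u)
        freq = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        positions = np.arange(length) / max(length - 1, 1)
        rows = rows + drift_amp * np.sin(2 * np.pi * freq * positions + phase)[:, None] * u
    if noise_sd > 0:
        rows = rows + rng.normal(0.0, noise_sd, size=(length, dim))
    return EmbeddingMatrix(protein_id, rows.astype(np.float32), model_tag="synthetic")


def _sequence(rng: np.random.Generator, profile: np.ndarray, length: int) -> str:
    return "".join(rng.choice(_AA20, size=length, p=profile))


def _region_counts(n: int, mix: tuple[float, float, float]) -> tuple[int, int, int]:
    below = int(round(n * mix[1]))
    above = int(round(n * mix[2]))
    within = n - below - above
    if within < 0:
        raise ValueError("region_mix rounds to more queries than requested")
    return within, below, above


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a reference set plus labeled queries, reproducibly from the seed.

    Bait lengths are uniform in the class range, with the first two baits
    pinned to the range endpoints so the realised reference length range
    equals the configured one.  Query lengths follow ``region_mix``:
    below-range queries are 1-40 residues shorter than the class minimum
    (an error if the minimum is 1) and above-range queries 1-40 residues
    longer than the maximum.
    """
    rng = np.random.default_rng(config.seed)
    ranges = config.ranges()
    labels = list(ranges)
    cents = _centroids(rng, config.n_classes, config.dim, config.centroid_separation)
    profiles = rng.dirichlet(np.ones(len(_AA20)), size=config.n_classes)
    drift = config.drift_amplitude if config.drift_amplitude is not None else config.residue_noise_sd

    # infeasibility check before drawing anything
    for label in labels:
        lo, _ = ranges[label]
        if config.region_mix[1] > 0 and config.n_queries_per_class > 0 and lo <= 1:
            raise ValueError(
                f"below-range queries requested but class {label!r} has min length {lo}"
            )

    store = EmbeddingStore(model_tag="synthetic")
    baits: list[Bait] = []
    queries: list[tuple[ProteinRecord, EmbeddingMatrix]] = []

    for k, label in enumerate(labels):
        lo, hi = ranges[label]
        n = config.n_baits_per_class
        lengths = rng.integers(lo, hi + 1, size=n)
        if n >= 1:
            lengths[0] = lo
        if n >= 2:
            lengths[1] = hi
        for b, length in enumerate(lengths):
            pid = f"{label}_bait{b:03d}"
            rec = ProteinRecord(pid, _sequence(rng, profiles[k], int(length)), taxon=None)
            emb = _protein_embedding(rng, pid, cents[k], int(length),
                                     config.residue_noise_sd, drift)
            store.add(emb)
            baits.append(Bait(rec, label, emb))

    for k, label in enumerate(labels):
        lo, hi = ranges[label]
        n_within, n_below, n_above = _region_counts(config.n_queries_per_class, config.region_mix)
        qlengths = []
        qlengths += list(rng.integers(lo, hi + 1, size=n_within))
        if n_below:
            qlengths += list(rng.integers(max(1, lo - 40), lo, size=n_below))
        if n_above:
            qlengths += list(rng.integers(hi + 1, hi + 41, size=n_above))
        for q, length in enumerate(qlengths):
            pid = f"{label}_query{q:03d}"
            rec = ProteinRecord(
                pid, _sequence(rng, profiles[k], int(length)),
                taxon=None, expected_class=label,
            )
            emb = _protein_embedding(rng, pid, cents[k], int(length),
                                     config.residue_noise_sd, drift)
            store.add(emb)
            queries.append((rec, emb))

    return SyntheticDataset(ReferenceSet(baits), queries, store, config)


def make_table_counts(
    scenario: str,
    records: Sequence[ClassificationRecord] | None = None,
):
    """Count tables for the reporting module.

    ``scenario`` selects either a packaged fixture — ``"table2_fixture"``
    (the labeled GST benchmark counts: per class, expected vs predicted
    by length region) or ``"table3_fixture"`` (the unlabeled GST survey:
    per-taxon class counts plus region totals) — or ``"synthetic"``,
    which builds a table2-shaped count table from classification records
    carrying expected labels.
    """
    from . import gst

    if scenario == "table2_fixture":
        return gst.load_testing_counts()
    if scenario == "table3_fixture":
        return gst.load_trial_counts()
    if scenario == "synthetic":
        if records is None:
            raise ValueError("synthetic scenario requires classification records")
        return counts_from_records(records)
    raise ValueError(f"unknown scenario {scenario!r}")


def counts_from_records(records: Sequence[ClassificationRecord]):
    """Table2-shaped per-class counts from labeled classification records.

    Rows are expected classes; per region, ``exp_*`` counts every record
    and ``pred_*`` the records whose prediction agrees with the label.
    """
    import pandas as pd

    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        if rec.expected_class is None:
            raise ValueError(f"record {rec.query_id!r} has no expected class")
        region = rec.region
        row = rows.setdefault(
            rec.expected_class,
            {c: 0 for c in ("total", "exp_within", "pred_within",
                            "exp_below", "pred_below", "exp_above", "pred_above")},
        )
        row["total"] += 1
        row[f"exp_{region}"] += 1
        if rec.agree:
            row[f"pred_{region}"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "class"
    return df
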