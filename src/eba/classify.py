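"""Nearest-bait annotation transfer and length-range triage.

A query protein is aligned (via its embedding) to every bait in the
reference set and assumes the class of the best-scoring bait under
EBAmin.  Because class transfer is only structurally safe when the fold
is conserved — and fold conservation constrains length — each call is
also triaged against the predicted class's reference length range (RLR):
``within`` (min <= l <= max), ``below`` (l < min) or ``above`` (l > max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import align_pair, path_identity
from .embeddings import EmbeddingMatrix
from .refset import Bait, ClassLengthRange, ProteinRecord, ReferenceSet

__all__ = [
    "ClassificationRecord",
    "classify_query",
    "triage_length",
    "classify_set",
    "write_calls_tsv",
    "CALLS_COLUMNS",
]

CALLS_COLUMNS = [
    "query_id",
    "predicted_class",
    "best_bait_id",
    "eba_min",
    "margin",
    "region",
    "identity_pct",
    "expected_class",
    "agree",
]


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-query classification outcome."""

    query_id: str
    predicted_class: str
    best_bait_id: str
    eba_min: float
    runner_up_class: str | None
    margin: float
    region: str
    identity_to_best: float
    expected_class: str | None = None
    agree: bool | None = None

    def tsv_row(self) -> str:
        vals = [
            self.query_id,
            self.predicted_class,
            self.best_bait_id,
            f"{self.eba_min:.6f}",
            "inf" if math.isinf(self.margin) else f"{self.margin:.6f}",
            self.region,
            f"{self.identity_to_best:.1f}",
            self.expected_class or "",
            "" if self.agree is None else str(self.agree).lower(),
        ]
        return "\t".join(vals)


def triage_length(
    query_length: int,
    predicted_class: str,
    rlr_map: Mapping[str, ClassLengthRange],
) -> str:
    """Call the query's length region relative to a class's RLR."""
    try:
        rlr = rlr_map[predicted_class]
    except KeyError:
        raise KeyError(f"class {predicted_class!r} has no reference length range") from None
    if query_length < rlr.min_len:
        return "below"
    if query_length > rlr.max_len:
        return "above"
    return "within"


def classify_query(
    query: ProteinRecord,
    embedding: EmbeddingMatrix,
    refset: ReferenceSet,
    gap_open: float = -1.0,
    gap_extend: float = -0.1,
    rlr_map: Mapping[str, ClassLengthRange] | None = None,
) -> ClassificationRecord:
    """Assign a query the class of its best-scoring bait.

    Every bait is aligned to the query and scored with EBAmin; the best
    bait wins.  A bait whose id equals the query id is excluded
    (leave-one-out on the reference set itself); sequence-identical baits
    under different ids are legitimate neighbours.  Ties are broken by
    higher identity to the query along the alignment path, then by
    lexicographically smaller bait id.
    """
    if embedding.dim != refset.dim:
        raise ValueError(
            f"query {query.id!r} embedding dimension D={embedding.dim} "
            f"does not match reference set D={refset.dim}"
        )
    candidates = [b for b in refset.baits if b.id != query.id]
    if not candidates:
        raise ValueError(f"no baits available to classify {query.id!r}")

    results: list[tuple[Bait, float, object]] = []
    for bait in candidates:
        res = align_pair(embedding, bait.embedding, gap_open=gap_open, gap_extend=gap_extend)
        results.append((bait, res.eba_min, res))

    best_score = max(r[1] for r in results)
    tied = [r for r in results if r[1] == best_score]
    if len(tied) > 1:
        # resolve exact score ties: higher path identity, then smaller id
        def tie_key(item):
            bait, _, res = item
            ident = path_identity(res.path, query.sequence, bait.record.sequence)
            return (-ident, bait.id)

        tied.sort(key=tie_key)
    best_bait, best_eba, best_res = tied[0]

    other = [(b, s) for b, s, _ in results if b.class_label != best_bait.class_label]
    if other:
        runner_bait, runner_score = min(other, key=lambda t: (-t[1], t[0].id))
        runner_class: str | None = runner_bait.class_label
        margin = best_eba - runner_score
    else:
        runner_class, margin = None, math.inf

    identity = path_identity(best_res.path, query.sequence, best_bait.record.sequence)
    rlr = rlr_map if rlr_map is not None else refset.rlr()
    region = triage_length(query.length, best_bait.class_label, rlr)
    agree = None
    if query.expected_class is not None:
        agree = query.expected_class == best_bait.class_label
    return ClassificationRecord(
        query_id=query.id,
        predicted_class=best_bait.class_label,
        best_bait_id=best_bait.id,
        eba_min=best_eba,
        runner_up_class=runner_class,
        margin=margin,
        region=region,
        identity_to_best=identity,
        expected_class=query.expected_class,
        agree=agree,
    )


def classify_set(
    queries: Sequence[tuple[ProteinRecord, EmbeddingMatrix]],
    refset: ReferenceSet,
    gap_open: float = -1.0,
    gap_extend: float = -0.1,
) -> tuple[list[ClassificationRecord], list[tuple[str, str]]]:
    """Classify a batch of queries against one reference set.

    Input order is preserved and output is deterministic.  Per-query
    failures do not abort the run: they are collected as ``(query_id,
    message)`` pairs and returned alongside the successful records.
    """
    rlr = refset.rlr()
    records: list[ClassificationRecord] = []
    failures: list[tuple[str, str]] = []
    for query, emb in queries:
        try:
            records.append(
                classify_query(query, emb, refset, gap_open=gap_open,
                               gap_extend=gap_extend, rlr_map=rlr)
            )
        except (ValueError, KeyError) as exc:
            failures.append((query.id, str(exc)))
    return records, failures


def write_calls_tsv(records: Iterable[ClassificationRecord], path) -> None:
    """Write classification records as a TSV with a fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(CALLS_COLUMNS) + "\n")
        for rec in records:
            fh.write(rec.tsv_row() + "\n")
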