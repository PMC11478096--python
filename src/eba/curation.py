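"""Dataset-preparation filters: sequence identity and redundancy removal.

Query sets assembled from large sequence databases overlap the curated
reference set; near-duplicates of a bait would make any benchmark of
annotation transfer trivially optimistic.  The redundancy filter drops
every query whose best global-alignment identity to any bait exceeds a
threshold (default 95%, strict inequality: a query at exactly the
threshold is retained).

Identity here is letter-based, not embedding-based: matches divided by
aligned (non-gap) pairs under global alignment with BLOSUM62 scoring and
affine gaps (open -11, extend -1) — the standard convention of
protein-database pipelines.  The scoring is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .refset import ProteinRecord, ReferenceSet

__all__ = ["FilterReport", "sequence_identity", "redundancy_filter"]


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class FilterReport:
    """Accounting for one redundancy-filter run.

    ``retained_count + len(removed_ids)`` always equals ``input_count``.
    """

    input_count: int
    removed_ids: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    retained_count: int = 0

    def check(self) -> None:
        if self.retained_count + len(self.removed_ids) != self.input_count:
            raise AssertionError("filter report counts do not reconcile")


def sequence_identity(seq1: str, seq2: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity between two sequences under global alignment.

    Computed as 100 x matches / aligned residue pairs, gap columns
    excluded.  Uses BLOSUM62 with affine gaps (open -11, extend -1) by
    default; pass a configured Biopython ``PairwiseAligner`` to change
    the scoring.
    """
    if not seq1 or not seq2:
        raise ValueError("cannot compute identity of an empty sequence")
    if aligner is None:
        aligner = _default_aligner()
    aln = next(iter(aligner.align(seq1, seq2)))
    matches = 0
    pairs = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        for a, b in zip(seq1[s1:e1], seq2[s2:e2]):
            pairs += 1
            if a == b:
                matches += 1
    if pairs == 0:
        return 0.0
    return 100.0 * matches / pairs


def redundancy_filter(
    queries: Sequence[ProteinRecord],
    references: ReferenceSet | Sequence[ProteinRecord],
    threshold: float = 95.0,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[ProteinRecord], FilterReport]:
    """Drop queries more than ``threshold`` percent identical to any bait.

    ``references`` is a :class:`~eba.refset.ReferenceSet` or a plain list
    of protein records (embeddings are not needed for this filter).
    Removal is strict: a query is removed iff its maximum identity to the
    reference set is strictly greater than ``threshold``.  Raising the
    threshold therefore never removes more queries.
    """
    if not (0.0 < threshold <= 100.0):
        raise ValueError(f"threshold must be in (0, 100], got {threshold}")
    if aligner is None:
        aligner = _default_aligner()
    if isinstance(references, ReferenceSet):
        ref_records = [(b.id, b.record.sequence) for b in references.baits]
    else:
        ref_records = [(r.id, r.sequence) for r in references]
    report = FilterReport(input_count=len(queries))
    retained: list[ProteinRecord] = []
    for q in queries:
        best_id, best_bait = 0.0, None
        for rid, rseq in ref_records:
            ident = sequence_identity(q.sequence, rseq, aligner)
            if ident > best_id:
                best_id, best_bait = ident, rid
            if best_id > threshold:
                break
        if best_id > threshold:
            report.removed_ids.append(
                (q.id, f"identity {best_id:.1f}% to bait {best_bait} exceeds {threshold:g}%")
            )
        else:
            retained.append(q)
    report.retained_count = len(retained)
    report.check()
    return retained, report
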