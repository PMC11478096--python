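"""Aggregation of classification outcomes into summary reports.

Two modes mirror the two kinds of experiment the pipeline supports:

* *labeled* — queries carry an expected class (e.g. from a rule-based
  annotation system); the report gives the overall agreement percentage
  and the fraction of queries lying outside the reference length range
  (RLR) of their class, broken down per class and per length region.
* *unlabeled* — queries have no prior class; the report gives the
  fractions of calls within / outside the RLR of their predicted class.

Rounding conventions are pinned: agreement to one decimal, region
fractions to integer percent (half away from zero), so printed summaries
are stable and comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .classify import ClassificationRecord

__all__ = ["SummaryReport", "summarize_labeled", "summarize_unlabeled"]

_T2_COLS = ["exp_within", "pred_within", "exp_below", "pred_below", "exp_above", "pred_above"]


def _round_half_up(x: float, ndigits: int = 0) -> float:
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SummaryReport:
    """Aggregated counts and headline percentages of one run."""

    mode: str  # "labeled" | "unlabeled"
    n_total: int
    within: int
    below: int
    above: int
    agreement_pct: float | None = None   # labeled mode, 1 decimal
    outside_rlr_pct: float | None = None  # integer percent
    within_rlr_pct: float | None = None   # integer percent
    per_class: pd.DataFrame | None = None

    def to_text(self) -> str:
        lines = [f"mode: {self.mode}", f"queries: {self.n_total}"]
        lines.append(f"within RLR: {self.within}  below: {self.below}  above: {self.above}")
        if self.within_rlr_pct is not None:
            lines.append(f"within-RLR fraction: {self.within_rlr_pct:.0f}%")
        if self.outside_rlr_pct is not None:
            lines.append(f"outside-RLR fraction: {self.outside_rlr_pct:.0f}%")
        if self.agreement_pct is not None:
            lines.append(f"agreement: {self.agreement_pct:.1f}%")
        if self.per_class is not None:
            lines.append("")
            lines.append(self.per_class.to_string())
        return "\n".join(lines)


def _is_table2(obj) -> bool:
    return isinstance(obj, pd.DataFrame) and set(_T2_COLS) <= set(obj.columns)


def summarize_labeled(
    data: Sequence[ClassificationRecord] | pd.DataFrame,
) -> SummaryReport:
    """Summarise a labeled run from records or a per-class count table.

    Accepts either classification records with expected labels, or a
    count table whose rows are classes and whose columns are
    ``total, exp_within, pred_within, exp_below, pred_below, exp_above,
    pred_above`` (``exp`` = expected queries in that length region,
    ``pred`` = those whose prediction agrees with the expectation).

    Agreement is the ratio of agreeing to expected counts summed over
    the three regions, as a percentage rounded to one decimal; the
    outside-RLR fraction is ``(below + above) / total`` rounded to
    integer percent.
    """
    if not _is_table2(data):
        from .synthetic import counts_from_records

        records = list(data)
        if not records:
            raise ValueError("no records to summarise")
        data = counts_from_records(records)
    table = data
    if "total" not in table.columns:
        table = table.copy()
        table["total"] = table["exp_within"] + table["exp_below"] + table["exp_above"]
    exp_w, exp_b, exp_a = (int(table[c].sum()) for c in ("exp_within", "exp_below", "exp_above"))
    pred = int(table[["pred_within", "pred_below", "pred_above"]].sum().sum())
    total = int(table["total"].sum())
    n_exp = exp_w + exp_b + exp_a
    if n_exp == 0:
        raise ValueError("count table is empty")
    if n_exp != total:
        raise ValueError(f"region counts ({n_exp}) do not reconcile with totals ({total})")
    return SummaryReport(
        mode="labeled",
        n_total=total,
        within=exp_w,
        below=exp_b,
        above=exp_a,
        agreement_pct=_round_half_up(100.0 * pred / n_exp, 1),
        outside_rlr_pct=_round_half_up(100.0 * (exp_b + exp_a) / total),
        within_rlr_pct=_round_half_up(100.0 * exp_w / total),
        per_class=table,
    )


def summarize_unlabeled(
    data: Sequence[ClassificationRecord] | pd.DataFrame,
) -> SummaryReport:
    """Summarise an unlabeled run from records or a region-count table.

    Accepts classification records (regions taken from each record's
    triage call) or a table carrying rows ``Within RLR``, ``Below RLR``,
    ``Above RLR`` and ``Total`` with a ``total`` column (the grand total
    may exceed the three regions when some queries were left
    unclassified).  Reports within- and outside-RLR fractions as integer
    percentages of the grand total.
    """
    per_class = None
    if isinstance(data, pd.DataFrame):
        needed = {"Within RLR", "Below RLR", "Above RLR", "Total"}
        if not needed <= set(data.index):
            raise ValueError(f"count table must have rows {sorted(needed)}")
        within = int(data.loc["Within RLR", "total"])
        below = int(data.loc["Below RLR", "total"])
        above = int(data.loc["Above RLR", "total"])
        total = int(data.loc["Total", "total"])
        per_class = data
    else:
        records = list(data)
        if not records:
            raise ValueError("no records to summarise")
        within = sum(1 for r in records if r.region == "within")
        below = sum(1 for r in records if r.region == "below")
        above = sum(1 for r in records if r.region == "above")
        total = len(records)
    if total < within + below + above:
        raise ValueError("grand total smaller than region counts")
    return SummaryReport(
        mode="unlabeled",
        n_total=total,
        within=within,
        below=below,
        above=above,
        within_rlr_pct=_round_half_up(100.0 * within / total),
        outside_rlr_pct=_round_half_up(100.0 * (below + above) / total),
        per_class=per_class,
    )
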