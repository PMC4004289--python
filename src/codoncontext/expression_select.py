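"""Selection of condition-specific gene sets from expression summaries.

Upstream microarray/RNA-seq preprocessing (RMA normalization, limma
model fits) happens in off-the-shelf tools; this module consumes their
summary tables — either absolute expression values or log-fold changes
with adjusted p-values — and applies the selection rules that define a
condition-specific gene set: the N most highly expressed genes, or the
genes passing differential-expression thresholds (adjusted p < 0.05 and
|logFC| > 1 by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from codoncontext.seq_core import CodingSequence

__all__ = [
    "ExpressionRecord",
    "read_expression_table",
    "select_top_expressed",
    "select_differential",
    "fetch_sequences",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's expression summary.

    Carries either an absolute expression ``value`` (arbitrary units)
    or a differential-expression pair (``logfc``, ``adj_p``) — or both.
    """

    gene_id: str
    value: float | None = None
    logfc: float | None = None
    adj_p: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.adj_p is not None and not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p for {self.gene_id!r} outside [0, 1]: {self.adj_p}")


def _check_unique(records: Sequence[ExpressionRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene_id {r.gene_id!r} in expression table")
        seen.add(r.gene_id)


def read_expression_table(path) -> list[ExpressionRecord]:
    """Read a TSV expression table.

    Requires a ``gene_id`` column plus either ``value`` or
    ``logfc``/``adj_p`` (or all three).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'gene_id'")
    has_value = "value" in df.columns
    has_de = "logfc" in df.columns and "adj_p" in df.columns
    if not (has_value or has_de):
        raise ValueError(f"{path}: need 'value' or 'logfc'+'adj_p' columns")

    def _opt(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    records = [
        ExpressionRecord(
            gene_id=str(row["gene_id"]),
            value=_opt(row, "value"),
            logfc=_opt(row, "logfc"),
            adj_p=_opt(row, "adj_p"),
        )
        for _, row in df.iterrows()
    ]
    _check_unique(records)
    return records


def select_top_expressed(
    records: Sequence[ExpressionRecord], n: int
) -> list[str]:
    """Ids of the n most highly expressed genes, descending by value.

    Ties are broken by ascending gene id, making the selection
    deterministic and independent of input row order.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    _check_unique(records)
    with_value = [r for r in records if r.value is not None]
    if n > len(with_value):
        raise ValueError(
            f"requested top {n} but only {len(with_value)} records carry a value"
        )
    ranked = sorted(with_value, key=lambda r: (-r.value, r.gene_id))
    return [r.gene_id for r in ranked[:n]]


def select_differential(
    records: Sequence[ExpressionRecord],
    adj_p_max: float = 0.05,
    abs_logfc_min: float = 1.0,
    direction: str = "up",
    n: int | None = None,
) -> list[str]:
    """Ids of differentially expressed genes.

    A gene survives when ``adj_p < adj_p_max`` and its log-fold change
    clears ``abs_logfc_min`` in the requested direction (strictly
    ``logfc > abs_logfc_min`` for up, ``logfc < -abs_logfc_min`` for
    down, either for both).  Survivors are ranked by descending |logfc|
    (ties by ascending gene id) and truncated to ``n`` when given.  An
    empty result is not an error — it is logged as a warning.
    """
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    if n is not None and n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    _check_unique(records)

    def passes(r: ExpressionRecord) -> bool:
        if r.logfc is None or r.adj_p is None:
            raise ValueError(f"record {r.gene_id!r} lacks logfc/adj_p")
        if not (r.adj_p < adj_p_max):
            return False
        if direction == "up":
            return r.logfc > abs_logfc_min
        if direction == "down":
            return r.logfc < -abs_logfc_min
        return abs(r.logfc) > abs_logfc_min

    survivors = [r for r in records if passes(r)]
    if not survivors:
        logger.warning(
            "no genes pass adj_p<%g and |logfc|>%g (%s)",
            adj_p_max,
            abs_logfc_min,
            direction,
        )
        return []
    ranked = sorted(survivors, key=lambda r: (-abs(r.logfc), r.gene_id))
    ids = [r.gene_id for r in ranked]
    return ids[:n] if n is not None else ids


def fetch_sequences(
    gene_ids: Sequence[str], genome: Sequence[CodingSequence]
) -> tuple[list[CodingSequence], list[str]]:
    """Look up coding sequences for an ordered gene-id list.

    Returns the matched sequences in the requested order plus the list
    of unmatched ids.  Zero matches is an error (an empty request, or a
    request entirely disjoint from the genome, signals a broken join).
    """
    by_id = {s.id: s for s in genome}
    matched = [by_id[g] for g in gene_ids if g in by_id]
    unmatched = [g for g in gene_ids if g not in by_id]
    if not matched:
        raise ValueError(
            f"none of the {len(gene_ids)} requested ids matched the genome"
        )
    if unmatched:
        logger.warning("%d gene ids unmatched: %s", len(unmatched), unmatched[:10])
    return matched, unmatched
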