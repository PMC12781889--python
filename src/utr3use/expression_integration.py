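"""Differential-expression filters, gene-set intersections and enrichment.

Implements the expression-side bookkeeping of the pipeline: the
expressed-gene filter (RPKM >= 0.5, inclusive), the DE call
(adjusted p < 0.05 and |log2FC| > 0.5, both strict), intersections of
motif-containing gene sets with DE / alternative-polyadenylation gene
lists, exact hypergeometric enrichment, and the shared percentage
formatter (half-away-from-zero at caller-chosen precision, the
convention behind every reported percentage).
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
from scipy import stats

from utr3use.motif_scan import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class DeRecord:
    gene_id: str
    log2fc: float
    padj: float | None
    expression: float | None  # RPKM-style

    def __post_init__(self) -> None:
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"{self.gene_id}: padj {self.padj} outside [0, 1]")


@dataclass
class DeThresholds:
    padj_max: float = 0.05       # strict <
    lfc_min_abs: float = 0.5     # strict >
    rpkm_min: float = 0.5        # inclusive >=


@dataclass
class IntersectionReport:
    label_a: str
    label_b: str
    size_a: int
    size_b: int
    overlap: int
    denominator: str
    percent_raw: float
    percent_formatted: str


def read_de_table(
    path: str | Path,
    gene_col: str = "gene_id",
    lfc_col: str = "log2fc",
    padj_col: str = "padj",
    expr_col: str = "expression",
) -> list[DeRecord]:
    """Read a DE table from TSV; missing padj/expression stay missing."""
    df = pd.read_csv(path, sep="\t")
    for col in (gene_col, lfc_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    if df[gene_col].duplicated().any():
        dup = df[gene_col][df[gene_col].duplicated()].iloc[0]
        raise ValueError(f"duplicate gene_id {dup!r}")
    records = []
    for i, row in df.iterrows():
        try:
            padj = None if padj_col not in df.columns or pd.isna(row[padj_col]) else float(row[padj_col])
            expr = None if expr_col not in df.columns or pd.isna(row[expr_col]) else float(row[expr_col])
            records.append(
                DeRecord(str(row[gene_col]), float(row[lfc_col]), padj, expr)
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {i + 2}: {exc}") from exc
    return records


def filter_expressed(
    records: list[DeRecord], thresholds: DeThresholds = DeThresholds()
) -> list[DeRecord]:
    """Keep genes with expression present and >= rpkm_min (inclusive)."""
    kept = [r for r in records if r.expression is not None and r.expression >= thresholds.rpkm_min]
    n_missing = sum(1 for r in records if r.expression is None)
    if n_missing:
        logger.info("%d genes dropped for missing expression", n_missing)
    return kept


def classify_de(
    records: list[DeRecord], thresholds: DeThresholds = DeThresholds()
) -> dict[str, str]:
    """Per-gene label: up / down / ns.

    up iff padj < padj_max and log2fc > lfc_min_abs (both strict);
    down mirrored; missing padj means ns.
    """
    labels = {}
    for r in records:
        if r.padj is not None and r.padj < thresholds.padj_max:
            if r.log2fc > thresholds.lfc_min_abs:
                labels[r.gene_id] = "up"
                continue
            if r.log2fc < -thresholds.lfc_min_abs:
                labels[r.gene_id] = "down"
                continue
        labels[r.gene_id] = "ns"
    return labels


def intersect_sets(
    a: GeneSet, b: GeneSet, denominator: Literal["a", "b"], decimals: int = 0
) -> IntersectionReport:
    """Overlap of two gene sets with the percent over a stated denominator."""
    denom_set = a.gene_ids if denominator == "a" else b.gene_ids
    if not denom_set:
        raise ValueError("empty denominator set")
    overlap = len(a.gene_ids & b.gene_ids)
    return IntersectionReport(
        label_a=a.label,
        label_b=b.label,
        size_a=len(a.gene_ids),
        size_b=len(b.gene_ids),
        overlap=overlap,
        denominator=denominator,
        percent_raw=100.0 * overlap / len(denom_set),
        percent_formatted=format_percent(overlap, len(denom_set), decimals),
    )


def set_enrichment(overlap: int, size_a: int, size_b: int, universe: int) -> float:
    """One-sided hypergeometric upper-tail P(X >= overlap).

    X is the overlap of a random size_b draw from a universe containing
    size_a marked genes.  Exact tail sum, no approximation.  The
    universe must be stated explicitly by the caller.
    """
    if not (0 <= overlap <= min(size_a, size_b) and max(size_a, size_b) <= universe):
        raise ValueError("inconsistent counts")
    return float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))


def format_percent(numerator: int, denominator: int, decimals: int) -> str:
    """100*n/d rounded half-away-from-zero, rendered at fixed decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    value = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    q = decimal.Decimal(1).scaleb(-decimals)
    return str(value.quantize(q, rounding=decimal.ROUND_HALF_UP))
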