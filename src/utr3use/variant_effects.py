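"""SNV intersection with motif sites and motif gain/loss classification.

A single-nucleotide substitution can create a motif occurrence absent
from the reference (gain — the mechanism by which a disease risk
allele can introduce an ectopic regulatory element into a 3'UTR),
destroy one (loss), leave one intact (retained) or touch no possible
motif placement (none).  Classification compares motif content of the
reference and alternate sequence windows of length 2k-1 centred on the
variant — the minimal window covering every motif placement that
overlaps the variant base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from utr3use.genome_io import GenomeSequences, UtrRecord, reverse_complement
from utr3use.motif_scan import find_exact

logger = logging.getLogger(__name__)

_NUCS = set("ACGT")


@dataclass
class VariantRecord:
    contig: str
    position: int  # 0-based genomic
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt or self.ref not in _NUCS or self.alt not in _NUCS:
            raise ValueError(
                f"{self.id}: ref/alt must be distinct single bases, "
                f"got {self.ref!r}/{self.alt!r}"
            )


@dataclass
class MotifChange:
    variant: VariantRecord
    strand_evaluated: str
    ref_window: str
    alt_window: str
    classification: str  # gain | loss | retained | none
    diseases: list[str] = field(default_factory=list)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], int]:
    """Read SNVs from a VCF 4.x file (positions converted to 0-based).

    Multi-allelic records are split; non-SNV alleles (indels, symbolic)
    are skipped and counted.  Returns (records, n_skipped).
    """
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if (
                    rec.ref is None
                    or len(rec.ref) != 1
                    or len(alt) != 1
                    or rec.ref.upper() not in _NUCS
                    or alt.upper() not in _NUCS
                ):
                    skipped += 1
                    continue
                records.append(
                    VariantRecord(
                        contig=rec.contig,
                        position=rec.pos - 1,
                        id=rec.id or f"{rec.contig}:{rec.pos}",
                        ref=rec.ref,
                        alt=alt,
                    )
                )
    if skipped:
        logger.info("skipped %d non-SNV alleles", skipped)
    return records, skipped


def overlap_with_motifs(
    variants: list[VariantRecord],
    motif_intervals: list[tuple[str, int, int]],
) -> list[VariantRecord]:
    """Variants whose position falls inside a motif genomic interval.

    Intervals are (contig, start, end), 0-based half-open; a variant at
    ``end`` does not overlap.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, s, e in motif_intervals:
        by_contig.setdefault(contig, []).append((s, e))
    out = []
    for v in variants:
        if any(s <= v.position < e for s, e in by_contig.get(v.contig, ())):
            out.append(v)
    return out


def _classify(ref_window: str, alt_window: str, motif: str) -> str:
    in_ref = bool(find_exact(ref_window, motif))
    in_alt = bool(find_exact(alt_window, motif))
    if in_alt and not in_ref:
        return "gain"
    if in_ref and not in_alt:
        return "loss"
    if in_ref and in_alt:
        return "retained"
    return "none"


def classify_motif_change(
    variant: VariantRecord,
    genome: GenomeSequences,
    record: UtrRecord | None,
    motif: str = "TTGTTTT",
) -> list[MotifChange]:
    """Classify a variant's effect on motif content.

    With a containing UtrRecord the 2k-1 window is evaluated in the
    transcript orientation (one result); without one, both strands are
    evaluated and reported separately.
    """
    k = len(motif)
    contig_len = genome.length(variant.contig)
    lo = max(0, variant.position - (k - 1))
    hi = min(contig_len, variant.position + k)
    ref_window_plus = genome.fetch(variant.contig, lo, hi)
    centre = variant.position - lo
    if ref_window_plus[centre] != variant.ref:
        raise ValueError(
            f"{variant.id}: genome base {ref_window_plus[centre]!r} at "
            f"{variant.contig}:{variant.position} does not match ref {variant.ref!r}"
        )
    alt_window_plus = (
        ref_window_plus[:centre] + variant.alt + ref_window_plus[centre + 1:]
    )

    def one(strand: str) -> MotifChange:
        if strand == "-":
            ref_w = reverse_complement(ref_window_plus)
            alt_w = reverse_complement(alt_window_plus)
        else:
            ref_w, alt_w = ref_window_plus, alt_window_plus
        return MotifChange(
            variant=variant,
            strand_evaluated=strand,
            ref_window=ref_w,
            alt_window=alt_w,
            classification=_classify(ref_w, alt_w, motif),
        )

    if record is not None:
        return [one(record.strand)]
    return [one("+"), one("-")]


def join_disease(
    changes: list[MotifChange], table: pd.DataFrame | str | Path
) -> list[MotifChange]:
    """Left-join disease annotations onto classified variants.

    ``table`` is a TSV (or DataFrame) with columns variant_id and
    disease; duplicate rows for one id are concatenated and
    deduplicated, unmatched variants keep an empty list.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    terms: dict[str, list[str]] = {}
    for _, row in table.iterrows():
        bucket = terms.setdefault(str(row["variant_id"]), [])
        d = str(row["disease"])
        if d not in bucket:
            bucket.append(d)
    for change in changes:
        change.diseases = list(terms.get(change.variant.id, []))
    return changes
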