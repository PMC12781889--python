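"""RBP binding at motif sites from CLIP peaks: the full-containment rule.

A motif counts as bound by an RBP only when its ENTIRE genomic span is
encompassed within the RBP's binding interval(s); for motifs whose
projection spans a splice junction every genomic segment must be
contained (possibly by different peaks of the same RBP).  Enrichment
against sliding-window backgrounds and variant motifs is assessed with
two-sided Fisher exact tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from utr3use.genome_io import GenomeSequences, UtrRecord, extract_utr_sequence, map_to_genome
from utr3use.motif_scan import ArchitectureHit, ScanParams, scan_architecture

logger = logging.getLogger(__name__)

_NUCS = "ACGT"


@dataclass
class ClipPeak:
    contig: str
    start: int
    end: int
    strand: str  # '+', '-' or '.' (unknown)
    rbp: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak [{self.start}, {self.end}) has non-positive length")


@dataclass
class BindingSummary:
    rbp: str
    n_targets: int
    n_bound: int
    percent_raw: float
    percent_formatted: str


@dataclass
class EnrichmentResult:
    table: tuple[int, int, int, int]
    odds_ratio: float
    p_two_sided: float


@dataclass
class Target:
    """One tested sequence: genomic segments of a (possibly spliced) k-mer."""

    contig: str
    segments: list[tuple[int, int]]
    strand: str
    transcript_id: str = ""


class PeakIndex:
    """Containment-query index over one RBP's peaks, per contig."""

    def __init__(self, peaks: list[ClipPeak]):
        self.rbp = peaks[0].rbp if peaks else ""
        self._trees: dict[str, IntervalTree] = {}
        for p in peaks:
            self._trees.setdefault(p.contig, IntervalTree()).addi(p.start, p.end, p)

    def contains_segment(
        self, contig: str, start: int, end: int, strand: str, require_strand: bool
    ) -> bool:
        tree = self._trees.get(contig)
        if tree is None:
            return False
        for iv in tree.overlap(start, end):
            peak: ClipPeak = iv.data
            if peak.start <= start and end <= peak.end:
                if require_strand and peak.strand != "." and strand in "+-":
                    if peak.strand != strand:
                        continue
                return True
        return False


def read_peaks(path: str | Path, rbp: str) -> list[ClipPeak]:
    """Read CLIP peaks from BED3 or BED6 (strand honoured when present)."""
    peaks = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{ln}: start >= end")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            peaks.append(ClipPeak(f[0], start, end, strand, rbp))
    return peaks


def is_contained(
    target: Target, index: PeakIndex, require_strand: bool = True
) -> bool:
    """True iff EVERY genomic segment of the target lies fully within
    some peak of the RBP (shared boundaries allowed)."""
    return all(
        index.contains_segment(target.contig, s, e, target.strand, require_strand)
        for s, e in target.segments
    )


def targets_from_hits(
    hits: list[ArchitectureHit],
    records: dict[str, UtrRecord],
    dedupe_per_gene: bool = True,
) -> list[Target]:
    """Motif-occurrence targets from architecture hits.

    Occurrences are deduplicated by genomic interval within a gene when
    ``dedupe_per_gene`` (the same genomic motif shared by several
    transcripts of one gene counts once); set False for raw counts.
    """
    out: list[Target] = []
    seen: set[tuple] = set()
    for hit in hits:
        record = records[hit.motif.transcript_id]
        key = (record.gene_id, record.contig, tuple(hit.motif.g_intervals))
        if dedupe_per_gene and key in seen:
            continue
        seen.add(key)
        out.append(
            Target(
                contig=record.contig,
                segments=list(hit.motif.g_intervals),
                strand=record.strand,
                transcript_id=hit.motif.transcript_id,
            )
        )
    return out


def enumerate_windows(records: list[UtrRecord], k: int = 7) -> list[tuple[str, int]]:
    """Every transcript-space k-window (transcript_id, start) over the
    given (motif-containing) transcripts; L-k+1 windows per transcript."""
    windows = []
    for r in records:
        for i in range(r.spliced_length - k + 1):
            windows.append((r.transcript_id, i))
    return windows


def sample_windows(
    windows: list[tuple[str, int]], n: int = 100_000, seed: int | None = None
) -> list[tuple[str, int]]:
    """Uniform sample of windows without replacement (all if fewer than n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if len(windows) <= n:
        logger.info("window pool (%d) <= n (%d): returning all", len(windows), n)
        return list(windows)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(windows), size=n, replace=False)
    return [windows[i] for i in sorted(idx)]


def windows_to_targets(
    windows: list[tuple[str, int]], records: dict[str, UtrRecord], k: int = 7
) -> list[Target]:
    out = []
    for tx, start in windows:
        r = records[tx]
        out.append(
            Target(
                contig=r.contig,
                segments=map_to_genome(r, (start, start + k)),
                strand=r.strand,
                transcript_id=tx,
            )
        )
    return out


def summarize_binding(
    targets: list[Target],
    index: PeakIndex,
    label: str = "",
    decimals: int = 2,
    require_strand: bool = True,
) -> BindingSummary:
    """Bound count/fraction of targets under the full-containment rule."""
    from utr3use.expression_integration import format_percent

    if not targets:
        raise ValueError("no targets to test")
    n_bound = sum(is_contained(t, index, require_strand) for t in targets)
    return BindingSummary(
        rbp=label or index.rbp,
        n_targets=len(targets),
        n_bound=n_bound,
        percent_raw=100.0 * n_bound / len(targets),
        percent_formatted=format_percent(n_bound, len(targets), decimals),
    )


def fisher_two_sided(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Two-sided Fisher exact test on the 2x2 table (a, b; c, d).

    p is the sum of hypergeometric probabilities (margins fixed) of all
    tables at most as probable as the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("zero margin")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return EnrichmentResult(table=(a, b, c, d), odds_ratio=odds, p_two_sided=float(p))


@dataclass
class CobindingTable:
    n_targets: int
    pair_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    pair_percent: dict[tuple[str, str], str] = field(default_factory=dict)


def cobinding(
    targets: list[Target],
    indexes: dict[str, PeakIndex],
    decimals: int = 3,
    require_strand: bool = True,
) -> CobindingTable:
    """Per-RBP-pair counts of targets bound by both RBPs."""
    from utr3use.expression_integration import format_percent

    if len(indexes) < 2:
        raise ValueError("need peak sets for at least two RBPs")
    bound = {
        rbp: np.array([is_contained(t, ix, require_strand) for t in targets])
        for rbp, ix in indexes.items()
    }
    table = CobindingTable(n_targets=len(targets))
    for x, y in itertools.combinations(sorted(indexes), 2):
        n = int(np.sum(bound[x] & bound[y]))
        table.pair_counts[(x, y)] = n
        table.pair_percent[(x, y)] = format_percent(n, len(targets), decimals)
    return table


def generate_hamming_variants(motif: str, distance: int = 1) -> list[str]:
    """All sequences at exactly the given Hamming distance from ``motif``."""
    motif = motif.upper()
    out = []
    for positions in itertools.combinations(range(len(motif)), distance):
        choices = [[n for n in _NUCS if n != motif[p]] for p in positions]
        for subs in itertools.product(*choices):
            s = list(motif)
            for p, n in zip(positions, subs):
                s[p] = n
            out.append("".join(s))
    return out


def variant_binding(
    variants: list[str],
    records: list[UtrRecord],
    genome: GenomeSequences,
    params: ScanParams,
    index: PeakIndex,
    require_strand: bool = True,
) -> dict[str, tuple[BindingSummary, EnrichmentResult | None]]:
    """Binding of variant motifs vs the canonical motif.

    Each variant heptamer is scanned with the same PAS and distance
    constraint, its occurrences tested for containment, and compared
    to the canonical motif by a two-sided Fisher test on
    (bound, unbound) counts.  The canonical motif is reported under
    its own sequence with a None comparison.
    """
    for v in variants:
        if len(v) != len(params.motif):
            raise ValueError(f"variant {v!r} length != motif length")
    record_map = {r.transcript_id: r for r in records}
    utrs = [extract_utr_sequence(r, genome) for r in records]

    def summary_for(motif: str) -> BindingSummary | None:
        import dataclasses

        p = dataclasses.replace(params, motif=motif)
        hits = [h for u in utrs for h in scan_architecture(u, p)]
        targets = targets_from_hits(hits, record_map)
        if not targets:
            return None
        return summarize_binding(targets, index, label=motif,
                                 require_strand=require_strand)

    canonical = summary_for(params.motif)
    if canonical is None:
        raise ValueError("canonical motif has no architecture occurrences")
    out: dict[str, tuple[BindingSummary, EnrichmentResult | None]] = {
        params.motif: (canonical, None)
    }
    for v in variants:
        if v.upper() == params.motif.upper():
            continue  # already reported as the canonical scan
        s = summary_for(v.upper())
        if s is None:
            logger.info("variant %s: no occurrences", v)
            continue
        enr = fisher_two_sided(
            canonical.n_bound,
            canonical.n_targets - canonical.n_bound,
            s.n_bound,
            s.n_targets - s.n_bound,
        )
        out[v.upper()] = (s, enr)
    return out
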