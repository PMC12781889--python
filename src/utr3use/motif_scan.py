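"""Motif and motif+PAS architecture scanning in spliced 3'UTR sequences.

The scanned architecture is a short upstream sequence element (USE)
heptamer strictly 5' of a polyadenylation-signal hexamer, separated by
at most ``d_max`` nucleotides.  The gap is the number of bases strictly
between the last motif base and the first PAS base (gap = pas_start -
motif_end); gap = 0 means adjacency and the bound is inclusive
(gap <= d_max).  A start-to-start gap definition is available via
``ScanParams.gap_mode``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from utr3use.genome_io import TranscriptSequence, UtrRecord, map_to_genome

logger = logging.getLogger(__name__)

_NUCS = set("ACGT")


@dataclass
class ScanParams:
    """Scan parameters: motif, PAS, distance cap and histogram binning.

    ``d_max`` bounds the motif-to-PAS gap for architecture calls;
    ``d_cap`` bounds gaps considered by the distance histogram;
    ``bin_width`` is the histogram bin width in nt.
    """

    motif: str = "TTGTTTT"
    pas: str = "ATTAAA"
    d_max: int = 450
    d_cap: int = 3000
    bin_width: int = 50
    gap_mode: str = "end-to-start"  # or "start-to-start"

    def __post_init__(self) -> None:
        for name in ("motif", "pas"):
            value = getattr(self, name)
            if not value or set(value.upper()) - _NUCS:
                raise ValueError(f"{name} must be a non-empty string over ACGT")
        if not (0 <= self.d_max <= self.d_cap):
            raise ValueError("require 0 <= d_max <= d_cap")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.gap_mode not in {"end-to-start", "start-to-start"}:
            raise ValueError(f"unknown gap_mode {self.gap_mode!r}")


@dataclass
class MotifHit:
    transcript_id: str
    t_interval: tuple[int, int]
    g_intervals: list[tuple[int, int]]
    matched: str


@dataclass
class ArchitectureHit:
    """One motif occurrence paired with a downstream PAS occurrence."""

    motif: MotifHit
    pas_t_interval: tuple[int, int]
    gap: int


@dataclass
class DistanceHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class GeneSet:
    label: str
    gene_ids: set[str] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)


def find_exact(sequence: str, pattern: str) -> list[int]:
    """All (possibly overlapping) 0-based start positions of ``pattern``.

    Comparison is case-insensitive; N never matches any pattern base.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if set(pattern.upper()) - _NUCS:
        raise ValueError(f"pattern {pattern!r} contains non-ACGT characters")
    seq = sequence.upper()
    pat = pattern.upper()
    positions = []
    i = seq.find(pat)
    while i != -1:
        positions.append(i)
        i = seq.find(pat, i + 1)
    return positions


def _gap(motif_start: int, motif_end: int, pas_start: int, mode: str) -> int:
    if mode == "start-to-start":
        return pas_start - motif_start
    return pas_start - motif_end


def scan_architecture(
    utr: TranscriptSequence,
    params: ScanParams,
    all_pairs: bool = False,
) -> list[ArchitectureHit]:
    """Find motif+PAS architectures in one spliced 3'UTR.

    Each motif occurrence is paired with its NEAREST downstream PAS
    occurrence whose gap is <= ``d_max`` (one hit per qualifying motif);
    ``all_pairs=True`` instead reports every qualifying (motif, PAS)
    pair.  Motifs with no qualifying PAS yield nothing.
    """
    k = len(params.motif)
    motif_starts = find_exact(utr.sequence, params.motif)
    pas_starts = np.asarray(find_exact(utr.sequence, params.pas), dtype=int)
    hits: list[ArchitectureHit] = []
    for m in motif_starts:
        m_end = m + k
        downstream = pas_starts[pas_starts >= m_end]
        gaps = np.array([_gap(m, m_end, int(p), params.gap_mode) for p in downstream])
        ok = downstream[(gaps >= 0) & (gaps <= params.d_max)]
        if ok.size == 0:
            continue
        chosen = ok if all_pairs else ok[:1]  # pas_starts ascending -> first is nearest
        motif_hit = MotifHit(
            transcript_id=utr.transcript_id,
            t_interval=(m, m_end),
            g_intervals=map_to_genome(utr.record, (m, m_end)),
            matched=utr.sequence[m:m_end],
        )
        for p in chosen:
            p = int(p)
            hits.append(
                ArchitectureHit(
                    motif=motif_hit,
                    pas_t_interval=(p, p + len(params.pas)),
                    gap=_gap(m, m_end, p, params.gap_mode),
                )
            )
    return hits


def nearest_pas_distance(
    utr: TranscriptSequence, params: ScanParams
) -> tuple[list[tuple[int, int]], int]:
    """Minimal downstream motif-to-PAS gap for each motif occurrence.

    Returns (list of (motif_start, gap) for motifs with a downstream
    PAS at gap <= ``d_cap``, count of motifs with none).
    """
    k = len(params.motif)
    motif_starts = find_exact(utr.sequence, params.motif)
    pas_starts = np.asarray(find_exact(utr.sequence, params.pas), dtype=int)
    out: list[tuple[int, int]] = []
    omitted = 0
    for m in motif_starts:
        m_end = m + k
        downstream = pas_starts[pas_starts >= m_end]
        gaps = np.array(
            [_gap(m, m_end, int(p), params.gap_mode) for p in downstream], dtype=int
        )
        gaps = gaps[(gaps >= 0) & (gaps <= params.d_cap)]
        if gaps.size == 0:
            omitted += 1
        else:
            out.append((m, int(gaps.min())))
    return out, omitted


def bin_distances(gaps: list[int], params: ScanParams) -> DistanceHistogram:
    """Histogram of gaps in ``bin_width`` bins over [0, d_cap].

    Bin b covers [b*w, (b+1)*w) half-open; the final bin is closed at
    ``d_cap`` (a gap of exactly d_cap falls in the last bin).
    """
    gaps = np.asarray(gaps, dtype=int)
    if gaps.size and gaps.min() < 0:
        raise ValueError("negative gap")
    if gaps.size and gaps.max() > params.d_cap:
        raise ValueError("gap exceeds d_cap")
    edges = np.arange(0, params.d_cap + params.bin_width, params.bin_width)
    if edges[-1] > params.d_cap:
        edges[-1] = params.d_cap
    counts, _ = np.histogram(gaps, bins=edges)
    return DistanceHistogram(bin_edges=edges, counts=counts)


def collapse_to_genes(
    hits: list[ArchitectureHit], records: list[UtrRecord], label: str
) -> GeneSet:
    """Collapse architecture hits to gene/transcript presence sets.

    A gene is in the set iff at least one of its transcripts has at
    least one hit; a transcript with an unknown id is an error.
    """
    tx_to_gene = {r.transcript_id: r.gene_id for r in records}
    out = GeneSet(label=label)
    for hit in hits:
        tx = hit.motif.transcript_id
        if tx not in tx_to_gene:
            raise KeyError(f"transcript {tx!r} not present in records")
        out.transcript_ids.add(tx)
        out.gene_ids.add(tx_to_gene[tx])
    return out
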