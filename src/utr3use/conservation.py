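"""Per-base conservation summarisation at motif sites.

Works with phyloP-style per-nucleotide scores (positive = more
conserved than neutral drift, negative = faster).  Positions absent
from the track are "no data" and are excluded from every mean, never
imputed as zero (zero means neutral, not unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from utr3use.genome_io import UtrRecord, genomic_position_extended
from utr3use.motif_scan import ArchitectureHit

logger = logging.getLogger(__name__)


@dataclass
class ConservationTrack:
    """Sparse per-base scores: contig -> {0-based position: score}."""

    scores: dict[str, dict[int, float]]

    def get(self, contig: str, position: int) -> float | None:
        return self.scores.get(contig, {}).get(position)


@dataclass
class MotifConservationSummary:
    gene_id: str
    motif_mean: float
    utr_rest_mean: float
    difference: float
    n_motif_covered: int
    n_rest_covered: int


@dataclass
class PositionProfile:
    """Per-slot conservation means over the motif and +/- flank window.

    ``positions`` are labels in transcript 5'->3' order, e.g. for a
    7-mer with 3-nt flanks: [-3, -2, -1, 1..7, +1, +2, +3].
    """

    positions: list[str]
    mean_per_position: list[float]
    n_per_position: list[int]


def read_track(path: str | Path) -> ConservationTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) track.

    bedGraph intervals are 0-based half-open; wiggle coordinates are
    1-based and converted on read.  Interval scores are expanded to
    per-base entries; a later entry overwrites an earlier one with a
    warning.
    """
    path = Path(path)
    scores: dict[str, dict[int, float]] = {}
    mode = "bedgraph"
    chrom = ""
    step = span = 1
    cursor = 0  # 0-based position of the next fixedStep value
    overwrites = 0

    def put(c: str, pos: int, value: float) -> None:
        nonlocal overwrites
        d = scores.setdefault(c, {})
        if pos in d:
            overwrites += 1
        d[pos] = value

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if fields[0] == "fixedStep":
                    kv = dict(f.split("=") for f in fields[1:])
                    mode, chrom = "fixed", kv["chrom"]
                    cursor = int(kv["start"]) - 1
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                elif fields[0] == "variableStep":
                    kv = dict(f.split("=") for f in fields[1:])
                    mode, chrom = "variable", kv["chrom"]
                    span = int(kv.get("span", 1))
                elif mode == "fixed" and len(fields) == 1:
                    value = float(fields[0])
                    for off in range(span):
                        put(chrom, cursor + off, value)
                    cursor += step
                elif mode == "variable" and len(fields) == 2:
                    start = int(fields[0]) - 1
                    value = float(fields[1])
                    for off in range(span):
                        put(chrom, start + off, value)
                else:  # bedGraph data line
                    c, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    if e <= s:
                        raise ValueError("empty interval")
                    for pos in range(s, e):
                        put(c, pos, v)
            except (KeyError, ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{ln}: malformed track line: {exc}") from exc
    if overwrites:
        logger.warning("%s: %d overlapping positions (last value wins)", path, overwrites)
    return ConservationTrack(scores)


def _motif_positions(hits: list[ArchitectureHit]) -> set[int]:
    pos: set[int] = set()
    for hit in hits:
        for s, e in hit.motif.g_intervals:
            pos.update(range(s, e))
    return pos


def summarize_gene(
    record: UtrRecord,
    hits: list[ArchitectureHit],
    track: ConservationTrack,
) -> MotifConservationSummary | None:
    """Mean score over motif bases vs the rest of the 3'UTR for one gene.

    All motif occurrences of the gene pool into one motif mean.
    Returns None (and logs) when either part has no covered position.
    """
    if not hits:
        raise ValueError("hits must be non-empty for the gene")
    motif_pos = _motif_positions(hits)
    utr_pos = set()
    for s, e in record.exons:
        utr_pos.update(range(s, e))
    rest_pos = utr_pos - motif_pos

    motif_scores = [v for p in motif_pos if (v := track.get(record.contig, p)) is not None]
    rest_scores = [v for p in rest_pos if (v := track.get(record.contig, p)) is not None]
    if not motif_scores or not rest_scores:
        logger.info("gene %s omitted: no conservation coverage", record.gene_id)
        return None
    motif_mean = float(np.mean(motif_scores))
    rest_mean = float(np.mean(rest_scores))
    return MotifConservationSummary(
        gene_id=record.gene_id,
        motif_mean=motif_mean,
        utr_rest_mean=rest_mean,
        difference=motif_mean - rest_mean,
        n_motif_covered=len(motif_scores),
        n_rest_covered=len(rest_scores),
    )


def positional_profile(
    hits: list[ArchitectureHit],
    records: dict[str, UtrRecord],
    track: ConservationTrack,
    flank: int = 3,
    per_gene: bool = False,
) -> PositionProfile:
    """Per-position conservation profile over motif +/- flank windows.

    For each motif occurrence the window is read in transcript
    orientation (minus-strand motifs genomically right-to-left); flank
    positions outside the annotated UTR extend along the genome in
    transcript orientation.  ``per_gene=True`` averages occurrences
    within a gene before pooling across genes.
    """
    if not hits:
        raise ValueError("no hits")
    k = hits[0].motif.t_interval[1] - hits[0].motif.t_interval[0]
    n_slots = k + 2 * flank
    labels = [str(-i) for i in range(flank, 0, -1)] + [str(i + 1) for i in range(k)] + [
        f"+{i + 1}" for i in range(flank)
    ]

    rows: list[tuple[str, np.ndarray]] = []  # (gene_id, per-slot values w/ nan)
    for hit in hits:
        record = records[hit.motif.transcript_id]
        t_start = hit.motif.t_interval[0]
        vals = np.full(n_slots, np.nan)
        for slot in range(n_slots):
            t = t_start - flank + slot
            g = genomic_position_extended(record, t)
            v = track.get(record.contig, g)
            if v is not None:
                vals[slot] = v
        rows.append((record.gene_id, vals))

    if per_gene:
        by_gene: dict[str, list[np.ndarray]] = {}
        for gene, vals in rows:
            by_gene.setdefault(gene, []).append(vals)
        pooled = [np.nanmean(np.vstack(v), axis=0) for v in by_gene.values()]
    else:
        pooled = [vals for _, vals in rows]

    mat = np.vstack(pooled)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(mat, axis=0)
    ns = np.sum(~np.isnan(mat), axis=0)
    return PositionProfile(
        positions=labels,
        mean_per_position=[float(m) for m in means],
        n_per_position=[int(n) for n in ns],
    )


def fraction_motif_more_conserved(
    summaries: list[MotifConservationSummary],
) -> tuple[int, int, str]:
    """(count higher, count lower-or-tied, formatted percent higher).

    A gene counts as "higher" iff its motif mean strictly exceeds the
    rest-of-UTR mean; ties count as lower and are logged.
    """
    from utr3use.expression_integration import format_percent

    if not summaries:
        raise ValueError("summaries must be non-empty")
    higher = sum(1 for s in summaries if s.difference > 0)
    ties = sum(1 for s in summaries if s.difference == 0)
    if ties:
        logger.info("%d genes tied (difference 0); counted as not higher", ties)
    lower = len(summaries) - higher
    return higher, lower, format_percent(higher, len(summaries), 0)
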