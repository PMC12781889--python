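"""Genome and 3'UTR annotation I/O and transcript/genome coordinate mapping.

All internal coordinates are 0-based half-open; 1-based formats (GTF,
VCF, wiggle) are converted at the file boundary.  3'UTRs are modelled
as ordered genomic exon intervals with a strand; spliced sequences are
always reported in mRNA-sense (5'->3') orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pyfaidx

logger = logging.getLogger(__name__)

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequences:
    """In-memory genome: contig identifier -> nucleotide string.

    Case is preserved on read; every comparison downstream is
    case-insensitive (soft-masked lowercase bases count as their
    uppercase equivalents).
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Uppercase slice [start, end) of a contig."""
        if contig not in self.contigs:
            raise KeyError(f"contig {contig!r} not in genome")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"interval [{start}, {end}) outside contig {contig!r} "
                f"of length {len(seq)}"
            )
        return seq[start:end].upper()


@dataclass
class UtrRecord:
    """A gene/transcript 3'UTR as ordered genomic exon intervals.

    ``exons`` are 0-based half-open, sorted by ascending genomic start,
    non-overlapping, each of positive length.
    """

    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for s, e in exons:
            if e <= s:
                raise ValueError(f"exon [{s}, {e}) has non-positive length")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.exons = exons

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genomic_positions(self) -> np.ndarray:
        """Genomic position of each transcript position, 5'->3'.

        Index t of the returned array is the genomic coordinate of
        transcript position t; descending for minus-strand records.
        """
        pos = np.concatenate([np.arange(s, e) for s, e in self.exons])
        if self.strand == "-":
            pos = pos[::-1]
        return pos


@dataclass
class TranscriptSequence:
    """Spliced 3'UTR sequence in mRNA-sense orientation with its coordinate map."""

    transcript_id: str
    sequence: str
    record: UtrRecord
    coordinate_map: np.ndarray  # transcript position -> genomic position

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_genome(path: str | Path) -> GenomeSequences:
    """Read a (plain or bgzip-compressed) FASTA file into memory.

    The header token before the first whitespace is the contig
    identifier.  Duplicate identifiers and non-nucleotide characters
    are hard errors.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("empty FASTA file %s", path)
        return GenomeSequences({})
    fasta = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=False,
                          build_index=True, rebuild=True)
    contigs: dict[str, str] = {}
    for name in fasta.keys():
        seq = str(fasta[name][:])
        if not _VALID_SEQ.match(seq):
            bad = re.search(r"[^ACGTNacgtn]", seq)
            raise ValueError(
                f"non-nucleotide character {seq[bad.start()]!r} in record "
                f"{name!r} at position {bad.start()}"
            )
        contigs[name] = seq
    fasta.close()
    return GenomeSequences(contigs)


def _read_bed12(path: Path, gene_map: Mapping[str, str] | None) -> list[UtrRecord]:
    records = []
    seen: set[str] = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: BED12 needs 12 fields, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"{path}:{ln}: blockCount inconsistent")
            exons = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
            if name in seen:
                raise ValueError(f"{path}:{ln}: duplicate transcript_id {name!r}")
            seen.add(name)
            gene = gene_map.get(name, name) if gene_map else name
            records.append(UtrRecord(gene, name, chrom, strand, exons))
    return records


def _read_gtf(path: Path) -> list[UtrRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    by_tx: dict[str, list] = {}
    for feat in db.features_of_type("three_prime_utr"):
        tx = feat.attributes["transcript_id"][0]
        by_tx.setdefault(tx, []).append(feat)
    records = []
    for tx, feats in by_tx.items():
        feats.sort(key=lambda f: f.start)
        # GTF is 1-based inclusive -> 0-based half-open
        exons = [(f.start - 1, f.end) for f in feats]
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping three_prime_utr features for {tx!r}")
        gene = feats[0].attributes["gene_id"][0]
        contig = feats[0].seqid
        strand = feats[0].strand
        records.append(UtrRecord(gene, tx, contig, strand, exons))
    return records


def read_annotation(
    path: str | Path,
    dialect: str,
    gene_map: Mapping[str, str] | None = None,
) -> list[UtrRecord]:
    """Read 3'UTR annotations from BED12 or GTF.

    BED12 blocks describe the UTR exons directly (name column =
    transcript id; ``gene_map`` maps transcript id -> gene id and
    defaults to the identity).  GTF records with feature type
    ``three_prime_utr`` are grouped by ``transcript_id``.
    """
    path = Path(path)
    if dialect == "bed12":
        return _read_bed12(path, gene_map)
    if dialect == "gtf":
        return _read_gtf(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def extract_utr_sequence(record: UtrRecord, genome: GenomeSequences) -> TranscriptSequence:
    """Spliced sense-strand (5'->3') sequence of a 3'UTR, uppercase.

    Plus strand: concatenation of exon substrings in genomic order;
    minus strand: reverse complement of that concatenation.
    """
    if record.contig not in genome:
        raise KeyError(f"contig {record.contig!r} not in genome")
    parts = [genome.fetch(record.contig, s, e) for s, e in record.exons]
    seq = "".join(parts)
    if record.strand == "-":
        seq = reverse_complement(seq)
    return TranscriptSequence(
        transcript_id=record.transcript_id,
        sequence=seq.upper(),
        record=record,
        coordinate_map=record.genomic_positions(),
    )


def map_to_genome(
    record: UtrRecord, t_interval: tuple[int, int]
) -> list[tuple[int, int]]:
    """Project a transcript-space interval onto genomic intervals.

    Returns 1..k genomic 0-based half-open intervals ordered 5'->3' in
    transcript orientation (k > 1 iff the interval spans a splice
    junction); total genomic length equals the transcript interval
    length.
    """
    start, end = t_interval
    L = record.spliced_length
    if not (0 <= start < end <= L):
        raise ValueError(f"t_interval [{start}, {end}) out of range for length {L}")
    pos = record.genomic_positions()[start:end]
    step = -1 if record.strand == "-" else 1
    intervals: list[tuple[int, int]] = []
    run_start = pos[0]
    prev = pos[0]
    for p in pos[1:]:
        if p != prev + step:
            lo, hi = (run_start, prev) if step == 1 else (prev, run_start)
            intervals.append((int(lo), int(hi) + 1))
            run_start = p
        prev = p
    lo, hi = (run_start, prev) if step == 1 else (prev, run_start)
    intervals.append((int(lo), int(hi) + 1))
    return intervals


def map_to_transcript(record: UtrRecord, g_position: int) -> int:
    """Transcript position of a genomic position inside the UTR."""
    offset = 0
    exons = record.exons
    for s, e in exons:
        if s <= g_position < e:
            plus_pos = offset + (g_position - s)
            if record.strand == "+":
                return plus_pos
            return record.spliced_length - 1 - plus_pos
        offset += e - s
    raise ValueError(
        f"genomic position {g_position} not in any exon of {record.transcript_id}"
    )


def genomic_position_extended(record: UtrRecord, t_position: int) -> int:
    """Genomic position of a transcript position, extended past UTR edges.

    Positions outside [0, L) continue along the genome in transcript
    orientation (used for conservation flanks at UTR boundaries).
    """
    L = record.spliced_length
    pos = record.genomic_positions()
    sign = -1 if record.strand == "-" else 1
    if t_position < 0:
        return int(pos[0] + sign * t_position)
    if t_position >= L:
        return int(pos[L - 1] + sign * (t_position - (L - 1)))
    return int(pos[t_position])
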