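"""Synthetic data generator with a planted ground-truth manifest.

Emits every input the pipeline consumes — genome FASTA, 3'UTR BED12
annotation, transcript->gene map, per-base conservation bedGraph,
per-RBP BED6 CLIP peaks, VCF variants, and a DE table — with known
planted structure: motif+PAS architectures at recorded positions and
gap distances, conservation uplift at motif bases, per-RBP peak
coverage of a controlled fraction of motifs, variants that create or
destroy the motif, and DE labels enriched among motif genes.  The
manifest records everything planted plus an independent naive re-scan
of the emitted sequences, so every pipeline stage can be scored
without re-deriving intent.

Identical (config, seed) produces byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from utr3use.genome_io import UtrRecord, reverse_complement

logger = logging.getLogger(__name__)

_NUCS = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_MAX_TRIES = 200


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate a vertebrate 3'UTR cohort.

    UTR lengths centre on 600 nt (the typical single-UTR 3'UTR median);
    base composition is AT-rich as 3'UTRs are; per-RBP bind fractions
    default to the occupancy levels observed for HuR, hnRNPC and PTBP1
    in HeLa CLIP data; conservation is baseline Gaussian noise plus a
    fixed uplift delta at motif bases.
    """

    n_genes: int = 200
    utr_length_mean: float = 600.0
    utr_length_sd: float = 200.0
    utr_length_min: int = 80
    strand_minus_fraction: float = 0.5
    spliced_fraction: float = 0.2
    two_transcript_fraction: float = 0.1
    arch_fraction: float = 0.3
    gap_distribution: str = "uniform"  # uniform on [0, d_max] | geometric
    gap_geometric_mean: float = 80.0
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # ACGT
    motif: str = "TTGTTTT"
    pas: str = "ATTAAA"
    d_max: int = 450
    conservation_baseline_mean: float = 0.0
    conservation_baseline_sd: float = 0.3
    conservation_uplift: float = 1.0
    rbp_bind_fraction: dict[str, float] = field(
        default_factory=lambda: {"HuR": 0.0725, "hnRNPC": 0.0855, "PTBP1": 0.0017}
    )
    peak_halfwidth: int = 15
    cobind_pair: tuple[str, str] = ("HuR", "hnRNPC")
    cobind_fraction: float = 0.0
    background_peaks_per_kb: float = 0.1
    n_variants: int = 20
    gain_fraction: float = 0.4
    loss_fraction: float = 0.4
    de_p_motif: float = 0.3      # P(DE) for architecture genes
    de_p_background: float = 0.05
    strict: bool = False         # global rejection of accidental architectures
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = [
            self.strand_minus_fraction, self.spliced_fraction, self.arch_fraction,
            self.two_transcript_fraction, self.cobind_fraction, self.gain_fraction,
            self.loss_fraction, self.de_p_motif, self.de_p_background,
            *self.rbp_bind_fraction.values(),
        ]
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")


@dataclass
class TruthManifest:
    """Ground-truth record of everything the generator planted."""

    seed: int
    config: dict
    genes: dict[str, dict]          # gene_id -> plant record
    rescan: dict[str, list[dict]]   # transcript_id -> naive architecture re-scan
    rbp_bound: dict[str, list[str]]  # rbp -> gene ids whose motif is peak-covered
    variants: list[dict]            # id, gene, kind, contig, pos0, ref, alt
    de_labels: dict[str, str]       # gene_id -> up | down | ns

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _find_all(seq: str, pat: str) -> list[int]:
    out, i = [], seq.find(pat)
    while i != -1:
        out.append(i)
        i = seq.find(pat, i + 1)
    return out


def _naive_arch_scan(seq: str, motif: str, pas: str, d_max: int) -> list[dict]:
    """Independent nested-loop architecture scan (nearest downstream PAS)."""
    hits = []
    for m in _find_all(seq, motif):
        m_end = m + len(motif)
        best = None
        for p in _find_all(seq, pas):
            gap = p - m_end
            if 0 <= gap <= d_max and (best is None or gap < best[1]):
                best = (p, gap)
        if best is not None:
            hits.append({"motif_start": m, "pas_start": best[0], "gap": best[1]})
    return hits


def _random_seq(rng: np.random.Generator, n: int, comp) -> str:
    return "".join(rng.choice(list(_NUCS), size=n, p=list(comp)))


def plant_variant(
    sequence: str, kind: str, motif: str, rng: np.random.Generator
) -> tuple[str, int, str, str]:
    """Plant a single-nucleotide gain or loss variant in a transcript-sense
    sequence.

    gain requires a context one mismatch away from the motif to be
    present; loss requires a motif occurrence.  Returns
    (edited_sequence, position, ref_base, alt_base) where the EDITED
    sequence carries the reference allele (the edit, if any, installs
    the context) — the variant substitutes ref -> alt at ``position``.
    Verified closed-loop: substituting alt yields the intended
    classification.
    """
    k = len(motif)

    def window(seq: str, pos: int) -> str:
        return seq[max(0, pos - (k - 1)): pos + k]

    if kind == "loss":
        starts = _find_all(sequence, motif)
        if not starts:
            raise ValueError("loss variant requires a motif occurrence")
        for m in rng.permutation(starts):
            for j in rng.permutation(k):
                pos = int(m) + int(j)
                ref = sequence[pos]
                for alt in rng.permutation([n for n in _NUCS if n != ref]):
                    edited = sequence[:pos] + alt + sequence[pos + 1:]
                    if motif not in window(edited, pos):
                        return sequence, pos, ref, str(alt)
        raise ValueError("no loss-inducing substitution found")

    if kind == "gain":
        # find an existing near-motif context: a position whose single
        # substitution creates the motif without one being present
        candidates = []
        for c in range(len(sequence) - k + 1):
            sub = sequence[c:c + k]
            mismatches = [j for j in range(k) if sub[j] != motif[j]]
            if len(mismatches) == 1:
                candidates.append((c, mismatches[0]))
        for c, j in [candidates[i] for i in rng.permutation(len(candidates))]:
            pos = c + j
            ref, alt = sequence[pos], motif[j]
            altered = sequence[:pos] + alt + sequence[pos + 1:]
            if motif not in window(sequence, pos) and motif in window(altered, pos):
                return sequence, pos, ref, alt
        raise ValueError("gain variant requires a one-mismatch motif context")

    raise ValueError(f"unknown variant kind {kind!r}")


def _plant_gain_context(
    seq: str, motif: str, rng: np.random.Generator, forbidden: set[int]
) -> str:
    """Write a one-mismatch motif context at a free location."""
    k = len(motif)
    for _ in range(_MAX_TRIES):
        c = int(rng.integers(0, len(seq) - k + 1))
        span = set(range(c - (k - 1), c + 2 * k - 1))
        if span & forbidden:
            continue
        j = int(rng.integers(0, k))
        wrong = str(rng.choice([n for n in _NUCS if n != motif[j]]))
        context = motif[:j] + wrong + motif[j + 1:]
        edited = seq[:c] + context + seq[c + k:]
        region = edited[max(0, c - (k - 1)): c + 2 * k - 1]
        if motif not in region:
            return edited
    raise RuntimeError("could not plant a gain context; lower motif density")


def _gen_utr_sequence(
    rng: np.random.Generator, cfg: SimConfig, L: int, plant_arch: bool
) -> tuple[str, dict | None]:
    """Background sequence with an optional planted motif+PAS architecture.

    Rejection guarantees no accidental motif or PAS inside the planted
    architecture window; with ``cfg.strict`` the whole sequence carries
    exactly the planted architecture (or none).
    """
    k, pk = len(cfg.motif), len(cfg.pas)
    for _ in range(_MAX_TRIES):
        seq = _random_seq(rng, L, cfg.base_composition)
        plant = None
        if plant_arch:
            if cfg.gap_distribution == "geometric":
                gap = int(min(rng.geometric(1.0 / cfg.gap_geometric_mean), cfg.d_max))
            else:
                gap = int(rng.integers(0, cfg.d_max + 1))
            span = k + gap + pk
            if span > L:
                gap = max(0, L - k - pk)
                span = k + gap + pk
            m = int(rng.integers(0, L - span + 1))
            p = m + k + gap
            seq = seq[:m] + cfg.motif + seq[m + k:p] + cfg.pas + seq[p + pk:]
            lo = max(0, m - (k - 1))
            hi = min(L, p + pk + max(k, pk) - 1)
            win = seq[lo:hi]
            if [x + lo for x in _find_all(win, cfg.motif)] != [m]:
                continue
            if [x + lo for x in _find_all(win, cfg.pas)] != [p]:
                continue
            plant = {"motif_start": m, "pas_start": p, "gap": gap}
        if cfg.strict:
            hits = _naive_arch_scan(seq, cfg.motif, cfg.pas, cfg.d_max)
            expected = [] if plant is None else [
                {"motif_start": plant["motif_start"], "pas_start": plant["pas_start"],
                 "gap": plant["gap"]}
            ]
            if hits != expected:
                continue
        return seq, plant
    raise RuntimeError(
        "background rejection budget exhausted; lower motif density or UTR length"
    )


def simulate(config: SimConfig, outdir: str | Path) -> TruthManifest:
    """Generate all pipeline inputs under ``outdir`` and the manifest.

    Writes genome.fa, utrs.bed (BED12), genes.tsv, conservation.bedgraph,
    peaks_<RBP>.bed, variants.vcf, de_table.tsv, expressed_genes.tsv and
    manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    k = len(config.motif)

    n = config.n_genes
    strands = np.where(rng.random(n) < config.strand_minus_fraction, "-", "+")
    lengths = np.maximum(
        config.utr_length_min,
        rng.normal(config.utr_length_mean, config.utr_length_sd, n).astype(int),
    )
    spliced = rng.random(n) < config.spliced_fraction
    two_tx = rng.random(n) < config.two_transcript_fraction
    arch = rng.random(n) < config.arch_fraction

    # variant plan: losses in architecture genes, gains and "none"
    # variants in non-architecture genes (one variant per gene)
    n_gain = int(round(config.n_variants * config.gain_fraction))
    n_loss = int(round(config.n_variants * config.loss_fraction))
    n_none = max(0, config.n_variants - n_gain - n_loss)
    arch_idx = [i for i in range(n) if arch[i]]
    other_idx = [i for i in range(n) if not arch[i]]
    if n_loss > len(arch_idx) or (n_gain + n_none) > len(other_idx):
        raise ValueError("not enough genes to host the requested variants")
    loss_genes = list(rng.choice(arch_idx, size=n_loss, replace=False))
    picked = list(rng.choice(other_idx, size=n_gain + n_none, replace=False))
    gain_genes, none_genes = picked[:n_gain], picked[n_gain:]

    sequences: list[str] = []
    plants: list[dict | None] = []
    for i in range(n):
        seq, plant = _gen_utr_sequence(rng, config, int(lengths[i]), bool(arch[i]))
        if i in gain_genes:
            forbidden: set[int] = set()
            seq = _plant_gain_context(seq, config.motif, rng, forbidden)
        sequences.append(seq)
        plants.append(plant)

    # assemble the genome: one contig, loci separated by random padding
    pad = 100
    genome_parts: list[str] = []
    cursor = 0
    records: list[UtrRecord] = []
    gene_tx: list[tuple[str, str]] = []
    for i in range(n):
        gene = f"gene{i:04d}"
        tx = f"tx{i:04d}"
        genome_parts.append(_random_seq(rng, pad, config.base_composition))
        cursor += pad
        seq = sequences[i]
        L = len(seq)
        concat_g = reverse_complement(seq) if strands[i] == "-" else seq
        if spliced[i] and L >= 40:
            l1 = int(rng.integers(10, L - 9))
            intron = _random_seq(rng, int(rng.integers(60, 200)), config.base_composition)
            genome_parts.append(concat_g[:l1] + intron + concat_g[l1:])
            exons = [
                (cursor, cursor + l1),
                (cursor + l1 + len(intron), cursor + l1 + len(intron) + (L - l1)),
            ]
            cursor += L + len(intron)
        else:
            genome_parts.append(concat_g)
            exons = [(cursor, cursor + L)]
            cursor += L
        records.append(UtrRecord(gene, tx, "chr1", str(strands[i]), exons))
        gene_tx.append((tx, gene))
        if two_tx[i]:
            tx2 = f"tx{i:04d}b"
            records.append(UtrRecord(gene, tx2, "chr1", str(strands[i]), list(exons)))
            gene_tx.append((tx2, gene))
    genome_seq = "".join(genome_parts)

    primary = {r.transcript_id: r for r in records if not r.transcript_id.endswith("b")}

    def t_to_g(i: int, t: int) -> int:
        return int(primary[f"tx{i:04d}"].genomic_positions()[t])

    # ---- variants -------------------------------------------------------
    variant_rows: list[dict] = []
    vid = 0
    for i, kind in [(g, "gain") for g in gain_genes] + [(g, "loss") for g in loss_genes]:
        _, t_pos, ref_t, alt_t = plant_variant(sequences[i], kind, config.motif, rng)
        g_pos = t_to_g(i, t_pos)
        minus = strands[i] == "-"
        ref_g = _COMP[ref_t] if minus else ref_t
        alt_g = _COMP[alt_t] if minus else alt_t
        variant_rows.append(
            {"id": f"snv{vid:04d}", "gene": f"gene{i:04d}", "kind": kind,
             "contig": "chr1", "pos0": g_pos, "ref": ref_g, "alt": alt_g}
        )
        vid += 1
    for i in none_genes:
        seq = sequences[i]
        placed = False
        for _ in range(_MAX_TRIES):
            t_pos = int(rng.integers(0, len(seq)))
            ref_t = seq[t_pos]
            alt_t = str(rng.choice([b for b in _NUCS if b != ref_t]))
            win_ref = seq[max(0, t_pos - (k - 1)): t_pos + k]
            win_alt = (seq[:t_pos] + alt_t + seq[t_pos + 1:])[
                max(0, t_pos - (k - 1)): t_pos + k
            ]
            if config.motif not in win_ref and config.motif not in win_alt:
                placed = True
                break
        if not placed:
            raise RuntimeError("could not place a neutral variant")
        g_pos = t_to_g(i, t_pos)
        minus = strands[i] == "-"
        variant_rows.append(
            {"id": f"snv{vid:04d}", "gene": f"gene{i:04d}", "kind": "none",
             "contig": "chr1", "pos0": g_pos,
             "ref": _COMP[ref_t] if minus else ref_t,
             "alt": _COMP[alt_t] if minus else alt_t}
        )
        vid += 1
    variant_rows.sort(key=lambda v: v["pos0"])

    # ---- motif genomic spans & CLIP peaks -------------------------------
    motif_spans: list[tuple[int, str, int, int, str]] = []  # (gene idx, gene, lo, hi, strand)
    for i in range(n):
        if plants[i] is None:
            continue
        m = plants[i]["motif_start"]
        rec = primary[f"tx{i:04d}"]
        gpos = rec.genomic_positions()[m:m + k]
        motif_spans.append(
            (i, f"gene{i:04d}", int(gpos.min()), int(gpos.max()) + 1, rec.strand)
        )

    hw = config.peak_halfwidth
    rbp_bound: dict[str, list[str]] = {}
    bound_mask: dict[str, np.ndarray] = {}
    for rbp in sorted(config.rbp_bind_fraction):
        bound_mask[rbp] = rng.random(len(motif_spans)) < config.rbp_bind_fraction[rbp]
    if config.cobind_fraction > 0 and len(motif_spans) > 0:
        x, y = config.cobind_pair
        n_co = int(round(config.cobind_fraction * len(motif_spans)))
        co_idx = rng.choice(len(motif_spans), size=n_co, replace=False)
        for rbp in (x, y):
            bound_mask[rbp][co_idx] = True

    utr_kb = float(sum(r.spliced_length for r in primary.values())) / 1000.0
    peak_files: dict[str, list[str]] = {}
    for rbp in sorted(config.rbp_bind_fraction):
        lines = []
        bound_genes = []
        for j, (i, gene, lo, hi, strand) in enumerate(motif_spans):
            if not bound_mask[rbp][j]:
                continue
            jl = int(rng.integers(3, hw + 1))
            jr = int(rng.integers(3, hw + 1))
            lines.append(f"chr1\t{lo - jl}\t{hi + jr}\t{rbp}_{j}\t0\t{strand}")
            bound_genes.append(gene)
        # decoy background peaks away from any planted motif
        motif_zone = set()
        for _, _, lo, hi, _ in motif_spans:
            motif_zone.update(range(lo - hw - 1, hi + hw + 1))
        n_decoys = int(round(config.background_peaks_per_kb * utr_kb))
        placed = 0
        tries = 0
        while placed < n_decoys and tries < _MAX_TRIES * max(1, n_decoys):
            tries += 1
            i = int(rng.integers(0, n))
            rec = primary[f"tx{i:04d}"]
            if rec.spliced_length < 2 * hw + k:
                continue
            t0 = int(rng.integers(0, rec.spliced_length - k))
            gpos = rec.genomic_positions()[t0:t0 + k]
            lo, hi = int(gpos.min()) - hw, int(gpos.max()) + 1 + hw
            if any(p in motif_zone for p in (lo, hi)) or set(range(lo, hi)) & motif_zone:
                continue
            lines.append(f"chr1\t{lo}\t{hi}\t{rbp}_bg{placed}\t0\t{rec.strand}")
            placed += 1
        lines.sort(key=lambda s: int(s.split("\t")[1]))
        peak_files[rbp] = lines
        rbp_bound[rbp] = sorted(bound_genes)

    # ---- DE table -------------------------------------------------------
    de_labels: dict[str, str] = {}
    de_rows = []
    for i in range(n):
        gene = f"gene{i:04d}"
        p_de = config.de_p_motif if plants[i] is not None else config.de_p_background
        if rng.random() < p_de:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            lfc = sign * rng.uniform(0.8, 3.0)
            padj = rng.uniform(1e-8, 0.04)
            de_labels[gene] = "up" if sign > 0 else "down"
        else:
            lfc = rng.uniform(-0.45, 0.45)
            padj = rng.uniform(0.1, 1.0)
            de_labels[gene] = "ns"
        rpkm = float(np.exp(rng.normal(1.0, 1.0)))
        de_rows.append((gene, lfc, padj, rpkm))

    # ---- emit files -----------------------------------------------------
    with open(outdir / "genome.fa", "w") as fh:
        fh.write(">chr1\n")
        for j in range(0, len(genome_seq), 80):
            fh.write(genome_seq[j:j + 80] + "\n")

    with open(outdir / "utrs.bed", "w") as fh:
        for r in records:
            start, end = r.exons[0][0], r.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in r.exons) + ","
            starts = ",".join(str(s - start) for s, e in r.exons) + ","
            fh.write(
                f"{r.contig}\t{start}\t{end}\t{r.transcript_id}\t0\t{r.strand}"
                f"\t{start}\t{end}\t0\t{len(r.exons)}\t{sizes}\t{starts}\n"
            )

    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("transcript_id\tgene_id\n")
        for tx, gene in gene_tx:
            fh.write(f"{tx}\t{gene}\n")

    motif_positions = set()
    for _, _, lo, hi, _ in motif_spans:
        motif_positions.update(range(lo, hi))
    with open(outdir / "conservation.bedgraph", "w") as fh:
        all_pos = sorted({p for r in primary.values() for s, e in r.exons
                          for p in range(s, e)})
        noise = rng.normal(config.conservation_baseline_mean,
                           config.conservation_baseline_sd, len(all_pos))
        for p, v in zip(all_pos, noise):
            val = v + (config.conservation_uplift if p in motif_positions else 0.0)
            fh.write(f"chr1\t{p}\t{p + 1}\t{val:.4f}\n")

    for rbp, lines in peak_files.items():
        with open(outdir / f"peaks_{rbp}.bed", "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))

    with open(outdir / "variants.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={len(genome_seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variant_rows:
            fh.write(
                f"{v['contig']}\t{v['pos0'] + 1}\t{v['id']}\t{v['ref']}"
                f"\t{v['alt']}\t.\tPASS\t.\n"
            )

    with open(outdir / "de_table.tsv", "w") as fh:
        fh.write("gene_id\tlog2fc\tpadj\texpression\n")
        for gene, lfc, padj, rpkm in de_rows:
            fh.write(f"{gene}\t{lfc:.4f}\t{padj:.3e}\t{rpkm:.4f}\n")

    with open(outdir / "expressed_genes.tsv", "w") as fh:
        fh.write("gene_id\n")
        for gene, _, _, rpkm in de_rows:
            if rpkm >= 0.5:
                fh.write(gene + "\n")

    # ---- manifest -------------------------------------------------------
    genes_info = {}
    for i in range(n):
        genes_info[f"gene{i:04d}"] = {
            "transcript_id": f"tx{i:04d}",
            "strand": str(strands[i]),
            "length": int(lengths[i]),
            "spliced": bool(spliced[i]),
            "two_transcripts": bool(two_tx[i]),
            "architecture": plants[i],
        }
    rescan = {
        r.transcript_id: _naive_arch_scan(
            sequences[int(r.transcript_id[2:6])], config.motif, config.pas, config.d_max
        )
        for r in records
    }
    cfg_dict = asdict(config)
    cfg_dict["cobind_pair"] = list(config.cobind_pair)
    cfg_dict["base_composition"] = list(config.base_composition)
    manifest = TruthManifest(
        seed=config.seed,
        config=cfg_dict,
        genes=genes_info,
        rescan=rescan,
        rbp_bound=rbp_bound,
        variants=variant_rows,
        de_labels=de_labels,
    )
    manifest.save(outdir / "manifest.json")
    return manifest
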