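# utr3use

Analysis toolkit for **3′UTR upstream sequence elements (USEs)** — short
cis-regulatory motifs that sit upstream of a polyadenylation signal (PAS)
and recruit RNA-binding proteins to modulate 3′-end processing and gene
expression.

The default target is the conserved heptamer **TTGTTTT** (RNA UUGUUUU,
first characterised within the *Drosophila polo* USE and present in the
3′UTRs of many vertebrate genes) positioned at most **450 nt** upstream of
the non-canonical PAS **ATTAAA**. The package provides, as a reusable
library and a thin `utr3` command line:

- **genome_io** — FASTA/BED12/GTF reading, spliced sense-strand 3′UTR
  extraction, exact transcript↔genome coordinate mapping (0-based
  half-open everywhere internally).
- **motif_scan** — exact overlapping motif search; motif+PAS
  *architecture* calls pairing each motif with its nearest downstream PAS
  within the distance bound; motif→PAS distance histograms (50-nt bins up
  to 3000 nt); collapse of hits to transcript and gene sets.
- **conservation** — per-base phyloP-style track parsing (bedGraph /
  wiggle), motif-vs-rest-of-UTR mean comparison per gene, and per-position
  profiles over the motif ± 3-nt flanks.
- **clip_enrichment** — RBP occupancy of motif sites from CLIP peak BED
  files under the **full-containment rule** (a motif counts as bound only
  if its entire span lies inside a binding interval), sliding-window
  backgrounds with seeded sampling, co-binding tables, variant-motif
  scans, and two-sided Fisher exact enrichment.
- **variant_effects** — SNV↔motif intersection and classification of each
  variant as motif **gain / loss / retained / none** by comparing the
  reference and alternate 2k−1 windows (the mechanism by which a disease
  risk allele can create an ectopic USE in a 3′UTR).
- **expression_integration** — expressed-gene filter (RPKM ≥ 0.5), DE
  calls (adjusted p < 0.05 and |log2FC| > 0.5, both strict), gene-set
  intersections with exact hypergeometric enrichment, and the shared
  half-away-from-zero percentage formatter.
- **synthetic_data** — a generator that emits every input format the
  pipeline consumes (FASTA, BED12, bedGraph, BED6, VCF, TSV) with planted,
  manifest-recorded ground truth: architectures at known gaps,
  conservation uplift at motifs, controlled per-RBP peak coverage,
  gain/loss variants, and DE labels enriched among motif genes.

## Worked example

Simulate a cohort with known ground truth, then scan and test binding:

```sh
utr3 simulate --seed 9 --out sim/
utr3 scan --genome sim/genome.fa --annotation sim/utrs.bed \
    --gene-map sim/genes.tsv --out hits.tsv --genes motif_genes.tsv
utr3 clip --genome sim/genome.fa --annotation sim/utrs.bed \
    --gene-map sim/genes.tsv --peaks sim/peaks_HuR.bed:HuR \
    --peaks sim/peaks_hnRNPC.bed:hnRNPC --seed 17 --out clip.tsv
```

prints

```
simulated 200 genes (58 with planted architectures) into sim/
63 architecture hits; 63 transcripts
# seed=17 nwindows=36531 n_motifs=59
rbp     n_bound n_targets percent window_percent fisher_p
HuR     3       59        5.08    0.39           1.752e-03
hnRNPC  7       59        11.86   0.75           3.546e-07
HuR-hnRNPC 0    59        0.000
```

Reading: 58 genes carry a planted motif+PAS architecture and the scanner
recovers them (63 hits because some genes have two annotated transcripts
and one background architecture arises by chance). 5.08 % of the 59
deduplicated motif occurrences are fully contained in a HuR peak versus
0.39 % of random 7-nt windows in the same 3′UTRs — a significant
enrichment by Fisher's exact test (p ≈ 1.8 × 10⁻³) — and no motif is
co-bound by both RBPs at these low occupancy levels.

The same objects are available as a library:

```python
from utr3use import ScanParams, read_genome, read_annotation, \
    extract_utr_sequence, scan_architecture

genome = read_genome("sim/genome.fa")
records = read_annotation("sim/utrs.bed", "bed12")
hits = [h for r in records
        for h in scan_architecture(extract_utr_sequence(r, genome),
                                   ScanParams())]
```

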