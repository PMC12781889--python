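# Methods

## The scanned architecture

The unit of analysis is a motif+PAS *architecture* inside a spliced 3′UTR:
an exact occurrence of a USE heptamer (default `TTGTTTT`) strictly 5′ of an
exact occurrence of a PAS hexamer (default `ATTAAA`), with at most `d_max`
(default 450) nucleotides between them. Scanning happens on the spliced
mRNA-sense sequence, so elements cannot extend into introns but may span a
3′UTR splice junction. All coordinates are 0-based half-open internally;
GTF, VCF and wiggle are converted at the file boundary.

**Gap definition.** The gap is the number of bases strictly between the
last motif base and the first PAS base (`gap = pas_start − motif_end`), so
`gap = 0` means adjacency and the bound is inclusive (`gap ≤ d_max`). This
is the most literal reading of elements "spaced at" a maximum distance; a
start-to-start definition is available through `ScanParams.gap_mode` for
sensitivity analyses.

**Pairing rule.** Each motif occurrence is paired with its *nearest
downstream* PAS within the bound — one architecture per qualifying motif —
keeping the gene-list scan and the distance histogram consistent. Upstream
PAS occurrences are never considered; an all-pairs mode exists behind a
flag. Distance histograms use half-open 50-nt bins up to `d_cap`
(default 3000), with the final bin closed at the cap; motifs with no
downstream PAS within the cap are excluded from the histogram and counted
separately, so binned counts plus the excluded count always equal the
number of motif occurrences.

**Granularity.** One gene may own several transcripts; identical UTR
interval sets are deliberately *not* deduplicated across transcript IDs, so
both transcript-level and gene-level tallies survive. Occurrence-level
statistics count every motif occurrence; transcript and gene sets use
presence/absence. For binding tests, occurrences are deduplicated by
genomic interval *within* a gene (the same genomic motif shared by two
isoforms counts once), with raw counts available via a flag.

Soft-masked (lowercase) bases are uppercased before every comparison:
motif content should not depend on repeat masking. `N` never matches any
pattern base.

## Conservation

Tracks are per-base phyloP-style scores (positive = conserved relative to
neutral drift). Positions missing from a track are treated as *no data*
and excluded from every mean — never imputed as 0, because 0 means
"neutral", not "unknown". Per gene, all motif occurrences pool into one
motif mean, compared with the mean over the remaining annotated 3′UTR
positions; a gene with zero coverage on either side is omitted and logged.
A gene counts as "more conserved at the motif" only when the difference is
strictly positive; ties count as not higher.

The positional profile averages per slot over a window of the motif plus
3-nt flanks (13 slots for a heptamer), read in transcript orientation so
minus-strand motifs traverse the genome right-to-left. Flank positions
falling outside the annotated UTR are extended along the genome in
transcript orientation, since conservation is defined genomically. The
profile averages over occurrences by default; per-gene averaging first is
available via a flag.

## CLIP binding and enrichment

A motif (or background window) counts as bound by an RBP only under the
**full-containment rule**: every genomic segment of its projection must lie
entirely within a binding interval, shared boundaries allowed. For
occurrences spanning a splice junction each segment must be contained,
possibly by different peaks of the same RBP — the most conservative reading
of "entirely encompassed". Strand agreement with the peak is required when
the peak declares a strand (iCLIP peaks are strand-specific) and can be
disabled.

The background is the set of all 7-nt sliding windows over the
motif-containing transcripts, sampled uniformly without replacement
(default 100 000; everything if fewer exist) with a mandatory recorded
seed. Enrichment uses the two-sided Fisher exact test on
(motif bound, motif unbound; window bound, window unbound); the
implementation delegates to `scipy.stats.fisher_exact`, and the test suite
checks it against exhaustive hypergeometric enumeration to 1e−10 for
margins ≤ 30. Variant heptamers are scanned with the same PAS and distance
constraint and compared to the canonical motif by the same test; a
systematic Hamming-distance generator supplies variant panels when no
explicit list is given.

## Variant classification

Only single-nucleotide substitutions are classified (the gain/loss window
logic is substitution-specific); indels are skipped with a count. The
evaluation window is the 2k−1 bases centred on the variant — the minimal
window containing every possible motif placement that overlaps the variant
base — read in transcript orientation when a containing UTR annotation is
supplied, otherwise both strands are evaluated and reported separately.
Classification compares exact motif content of the reference and alternate
windows: gain / loss / retained / none. Exchanging ref and alt provably
swaps gain and loss. Gain calls test sequence identity only; requiring the
full downstream-PAS architecture as well is left to the caller, separating
motif creation from architecture validity.

## Expression integration

Expressed genes: expression present and ≥ 0.5 (inclusive). DE calls:
adjusted p < 0.05 *and* log2FC > 0.5 or < −0.5, all strict inequalities;
missing adjusted p means not-significant. Intersections report the overlap
with the percentage over an explicitly stated denominator set. Enrichment
is the exact one-sided hypergeometric upper tail P(X ≥ k); the universe is
a mandatory explicit parameter — the package refuses to guess a hidden
denominator. All percentages go through one formatter: half-away-from-zero
rounding at caller-chosen precision, rendered with exactly that many
decimals, which reproduces every conventional reported figure (e.g. 7.25,
0.17, 1.575, 18.5, 68).

## Synthetic data

The generator emulates a vertebrate 3′UTR cohort: UTR lengths normal with
mean 600 nt (the typical median for single-UTR genes) and floor 80 nt,
AT-rich composition (A/T 0.3, C/G 0.2), half the genes on the minus
strand, 20 % with a two-exon (spliced) UTR, 10 % with a second identical
transcript, and 30 % carrying a planted architecture with a uniform gap on
[0, 450]. Conservation is baseline Gaussian noise (mean 0, sd 0.3) plus a
fixed uplift δ = 1.0 on motif bases. Per-RBP bind fractions default to the
occupancy levels observed for HuR (0.0725), hnRNPC (0.0855) and PTBP1
(0.0017) in HeLa CLIP data; peaks are centred on their target motif with
jittered margins of at least 3 nt so containment holds by construction,
decoy peaks land away from motifs, and a configurable co-binding fraction
forces pairwise overlap. Variants are planted closed-loop: each emitted
VCF record is verified to classify as its intended gain/loss/none before
emission. DE labels are drawn with probability 0.3 for architecture genes
versus 0.05 for the rest.

Background sequence is generated with rejection so no accidental motif or
PAS lands inside a planted-architecture window; in the default (lenient)
mode accidental occurrences elsewhere are allowed — realistic — and an
independent naive nested-loop re-scan of every emitted sequence is stored
in the manifest so tests remain exact. A `strict` mode rejects until each
sequence carries exactly its planted architecture (or none), which makes
planted-set recovery an equality check. Identical (config, seed) yields
byte-identical files.

**What passing means.** The generator reproduces the *statistical
structure* the pipeline assumes — motif near PAS, conservation uplift,
partial containment-consistent occupancy, DE enrichment — not the
correlated realities of genomes (repeat structure, compositional
heterogeneity, peak width distributions, LD, annotation error). Recovery
on synthetic data therefore validates the bookkeeping and the statistics,
not biological conclusions about any particular genome.

## Problem sizes and numerical choices

The test and acceptance runs use cohorts of 100–500 genes with mean UTR
lengths of 300–600 nt, sizes at which every planted quantity is
statistically identifiable (binding at n = 200 against a central 99 %
binomial interval; conservation uplift at 500 occurrences against ±3
standard errors; DE enrichment at p < 0.01) while the full suite runs in
seconds. Fisher ties use scipy's relative tolerance (~1e−7); percentage
rounding is decimal, not binary-float. Degenerate inputs (empty FASTA,
zero-length windows, zero-coverage genes, empty gap lists) return empty
results or are omitted with a log, never silently imputed; inconsistent
inputs (duplicate contigs or gene IDs, inverted intervals, ref-allele
mismatches, zero margins) are hard errors.

## Known limitations

- Exact string matching only: no IUPAC degeneracy, PWMs or PAS-strength
  modelling.
- Conservation is consumed, not computed: no alignments, no phyloP/
  phastCons estimation, no cross-species consensus derivation.
- No peak calling, APA-site calling, DE model fitting or GO enrichment —
  those upstream outputs are inputs here.
- Whether the original distance-histogram convention considered upstream
  PAS occurrences, and whether its distance was end-to-start or
  start-to-start, is not documented; this package defaults to
  downstream-only, end-to-start, with start-to-start available.
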