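import numpy as np
import pytest

from utr3use.genome_io import GenomeSequences, UtrRecord

NUCS = "ACGT"


def random_sequence(rng: np.random.Generator, n: int, at_rich: bool = True) -> str:
    p = [0.3, 0.2, 0.2, 0.3] if at_rich else [0.25] * 4
    return "".join(rng.choice(list(NUCS), size=n, p=p))


def make_single_exon(seq: str, strand: str = "+", offset: int = 0,
                     contig: str = "chrT", gene: str = "G", tx: str = "T"):
    """Genome + UtrRecord whose spliced sense sequence equals ``seq``."""
    from utr3use.genome_io import reverse_complement

    genomic = reverse_complement(seq) if strand == "-" else seq
    genome = GenomeSequences({contig: "A" * offset + genomic})
    record = UtrRecord(gene, tx, contig, strand,
                       [(offset, offset + len(seq))])
    return genome, record


def random_record(rng: np.random.Generator, contig_len: int = 2000,
                  max_exons: int = 4) -> UtrRecord:
    """Random multi-exon UtrRecord inside a contig of the given length."""
    n_exons = int(rng.integers(1, max_exons + 1))
    cuts = sorted(rng.choice(contig_len, size=2 * n_exons, replace=False))
    exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
    strand = "+" if rng.random() < 0.5 else "-"
    return UtrRecord("G", "T", "chrT", strand, exons)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
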