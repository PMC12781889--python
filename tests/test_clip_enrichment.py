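"""Full-containment binding tests, window backgrounds, Fisher exact."""

from math import comb

import numpy as np
import pytest

from utr3use.clip_enrichment import (
    ClipPeak,
    PeakIndex,
    Target,
    cobinding,
    enumerate_windows,
    fisher_two_sided,
    generate_hamming_variants,
    is_contained,
    read_peaks,
    sample_windows,
    summarize_binding,
    variant_binding,
    windows_to_targets,
)
from utr3use.genome_io import GenomeSequences, UtrRecord
from utr3use.motif_scan import ScanParams


def index(*spans, strand="+", contig="chr1", rbp="X"):
    return PeakIndex([ClipPeak(contig, s, e, strand, rbp) for s, e in spans])


def target(*segments, strand="+", contig="chr1"):
    return Target(contig=contig, segments=list(segments), strand=strand)


class TestReadPeaks:
    def test_bed6(self, tmp_path):
        f = tmp_path / "p.bed"
        f.write_text("chr1\t100\t120\tp1\t0\t+\n")
        (p,) = read_peaks(f, "HuR")
        assert (p.start, p.end, p.strand, p.rbp) == (100, 120, "+", "HuR")

    def test_bed3_unknown_strand(self, tmp_path):
        f = tmp_path / "p.bed"
        f.write_text("chr1\t5\t9\n")
        assert read_peaks(f, "X")[0].strand == "."

    def test_inverted_interval_rejected(self, tmp_path):
        f = tmp_path / "p.bed"
        f.write_text("chr1\t9\t5\n")
        with pytest.raises(ValueError):
            read_peaks(f, "X")


class TestContainment:
    def test_strict_containment(self):
        assert is_contained(target((105, 112)), index((100, 120)))

    def test_one_base_overhang_unbound(self):
        assert not is_contained(target((114, 121)), index((100, 120)))

    def test_shared_boundaries_bound(self):
        assert is_contained(target((100, 107)), index((100, 120)))
        assert is_contained(target((113, 120)), index((100, 120)))

    def test_spliced_target_needs_every_segment(self):
        ix = index((0, 10), (50, 60))
        assert is_contained(target((2, 5), (52, 55)), ix)
        assert not is_contained(target((2, 5), (45, 55)), ix)

    def test_strand_mismatch_configurable(self):
        ix = index((100, 120), strand="-")
        t = target((105, 112), strand="+")
        assert not is_contained(t, ix, require_strand=True)
        assert is_contained(t, ix, require_strand=False)

    def test_unknown_peak_strand_always_matches(self):
        ix = index((100, 120), strand=".")
        assert is_contained(target((105, 112), strand="+"), ix)


class TestWindows:
    def test_window_count(self):
        r = UtrRecord("g", "t", "c", "+", [(0, 10)])
        assert len(enumerate_windows([r], k=7)) == 4

    def test_short_utr_no_windows(self):
        r = UtrRecord("g", "t", "c", "+", [(0, 6)])
        assert enumerate_windows([r], k=7) == []

    def test_count_conservation(self, rng):
        records = [
            UtrRecord("g", f"t{i}", "c", "+", [(0, int(rng.integers(3, 200)))])
            for i in range(100)
        ]
        total = sum(max(r.spliced_length - 6, 0) for r in records)
        assert len(enumerate_windows(records, k=7)) == total

    def test_spliced_window_projection(self):
        r = UtrRecord("g", "t", "c", "+", [(0, 5), (10, 15)])
        windows = enumerate_windows([r], k=7)
        targets = windows_to_targets(windows, {"t": r}, k=7)
        t = next(x for w, x in zip(windows, targets) if w[1] == 3)
        assert t.segments == [(3, 5), (10, 15)]

    def test_sampling_deterministic(self):
        windows = [("t", i) for i in range(10)]
        a = sample_windows(windows, 3, seed=7)
        b = sample_windows(windows, 3, seed=7)
        assert a == b and len(a) == 3

    def test_exhaustion_returns_all(self):
        windows = [("t", i) for i in range(10)]
        assert sample_windows(windows, 100_000, seed=1) == windows

    def test_uniform_inclusion_rate(self, rng):
        windows = [("t", i) for i in range(10_000)]
        hits = np.zeros(10_000)
        for seed in range(30):
            for _, i in sample_windows(windows, 1000, seed=seed):
                hits[i] += 1
        rate = hits.mean() / 30
        assert abs(rate - 0.1) < 0.01


def fisher_enumeration(a, b, c, d):
    """Exhaustive two-sided Fisher: sum over tables with fixed margins of
    point probabilities <= the observed one (relative tie tolerance)."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


class TestFisher:
    def test_small_table_closed_form(self):
        r = fisher_two_sided(3, 1, 1, 3)
        assert r.p_two_sided == pytest.approx(34 / 70, abs=1e-10)

    def test_identical_proportions(self):
        assert fisher_two_sided(10, 90, 10, 90).p_two_sided == pytest.approx(1.0)

    def test_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 20, 4) + 1)
            assert fisher_two_sided(a, b, c, d).p_two_sided == pytest.approx(
                fisher_two_sided(c, d, a, b).p_two_sided, abs=1e-12
            )

    def test_matches_enumeration_oracle(self, rng):
        """p equals exhaustive hypergeometric enumeration (margins <= 30)."""
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            got = fisher_two_sided(a, b, c, d).p_two_sided
            assert got == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided(0, 0, 1, 2)

    def test_null_calibration(self, rng):
        """With peaks placed at random, motif-vs-window p is super-uniform."""
        n_below = 0
        n_sims = 200
        for _ in range(n_sims):
            # motif and window bound counts drawn from the same binomial
            p_bind = 0.2
            motif_bound = rng.binomial(100, p_bind)
            win_bound = rng.binomial(400, p_bind)
            p = fisher_two_sided(
                motif_bound, 100 - motif_bound, win_bound, 400 - win_bound
            ).p_two_sided
            if p < 0.05:
                n_below += 1
        # binomial(200, 0.05) 99.9% upper bound ~ 21
        assert n_below <= 21


class TestBindingSummaries:
    def _targets(self, n, bound):
        ts = [target((10 * i, 10 * i + 7)) for i in range(n)]
        ix = index(*[(10 * i - 1, 10 * i + 8) for i in range(bound)])
        return ts, ix

    @pytest.mark.parametrize(
        "bound,n,decimals,expected",
        [(336, 4634, 2, "7.25"), (8, 4634, 2, "0.17"), (0, 10, 2, "0.00")],
    )
    def test_bound_percentages(self, bound, n, decimals, expected):
        ts, ix = self._targets(n, bound)
        s = summarize_binding(ts, ix, decimals=decimals)
        assert s.n_bound == bound and s.percent_formatted == expected

    def test_counted_targets_satisfy_predicate(self):
        """Containment soundness spot check on all counted targets."""
        ts, ix = self._targets(50, 20)
        s = summarize_binding(ts, ix)
        assert s.n_bound == sum(
            all(ix.contains_segment(t.contig, a, b, t.strand, True)
                for a, b in t.segments)
            for t in ts
        )

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            summarize_binding([], index((0, 10)))


class TestCobinding:
    def test_conjunction_and_exclusion(self):
        ts = [target((0, 7)), target((20, 27))]
        ix_a = index((0, 10), rbp="A")  # binds target 0 only
        ix_b = index((0, 10), (19, 30), rbp="B")  # binds both
        co = cobinding(ts, {"A": ix_a, "B": ix_b})
        assert co.pair_counts[("A", "B")] == 1

    def test_pair_percent_73_of_4634(self):
        ts = [target((10 * i, 10 * i + 7)) for i in range(4634)]
        both = [(10 * i - 1, 10 * i + 8) for i in range(73)]
        co = cobinding(ts, {"A": index(*both, rbp="A"), "B": index(*both, rbp="B")})
        assert co.pair_counts[("A", "B")] == 73
        assert co.pair_percent[("A", "B")] == "1.575"

    def test_needs_two_rbps(self):
        with pytest.raises(ValueError):
            cobinding([target((0, 7))], {"A": index((0, 10))})


class TestVariants:
    def test_hamming_1_count_and_distance(self):
        variants = generate_hamming_variants("TTGTTTT", 1)
        assert len(variants) == 21 and len(set(variants)) == 21
        for v in variants:
            assert sum(a != b for a, b in zip(v, "TTGTTTT")) == 1

    def test_variant_identical_to_canonical(self):
        seq = "TTGTTTTATTAAA" + "A" * 20
        genome = GenomeSequences({"chr1": seq})
        record = UtrRecord("g", "t", "chr1", "+", [(0, len(seq))])
        ix = index((0, 10))
        out = variant_binding(["TTGTTTT"], [record], genome, ScanParams(), ix)
        (summary, enr) = out["TTGTTTT"]
        assert summary.n_bound == 1 and enr is None

    def test_length_mismatch_rejected(self):
        genome = GenomeSequences({"chr1": "TTGTTTTATTAAA"})
        record = UtrRecord("g", "t", "chr1", "+", [(0, 13)])
        with pytest.raises(ValueError):
            variant_binding(["TTGT"], [record], genome, ScanParams(), index((0, 5)))

    def test_planted_fraction_recovery(self, rng):
        """Planted 50% canonical / 10% variant bound fractions recovered;
        Fisher detects the difference at n=500 each."""
        n = 500
        canon, var = "TTGTTTT", "TTGTTTA"
        pieces, records = [], []
        cursor = 0
        peaks = []
        rng_local = np.random.default_rng(99)
        for i, motif in enumerate([canon] * n + [var] * n):
            seq = "CC" + motif + "ATTAAA" + "CC"
            records.append(
                UtrRecord(f"g{i}", f"t{i}", "chr1", "+",
                          [(cursor, cursor + len(seq))])
            )
            frac = 0.5 if motif == canon else 0.1
            if rng_local.random() < frac:
                peaks.append((cursor, cursor + len(seq)))
            pieces.append(seq)
            cursor += len(seq)
        genome = GenomeSequences({"chr1": "".join(pieces)})
        ix = index(*peaks)
        out = variant_binding([var], records, genome, ScanParams(), ix)
        s_can, _ = out[canon]
        s_var, enr = out[var]
        # central 99.9% binomial intervals around the planted fractions
        from scipy import stats
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.5)
        assert lo <= s_can.n_bound <= hi
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.1)
        assert lo <= s_var.n_bound <= hi
        assert enr.p_two_sided < 0.01
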