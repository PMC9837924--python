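"""Interval model, BED/GFF3 I/O, interval algebra, peak assignment and
shuffling, checked against brute-force oracles."""

import numpy as np
import pytest

from embryodyn.intervals import (
    GenomicInterval, GeneModel, Genome, IntervalError,
    assign_peak_to_gene, merge_intervals, overlap_pairs, read_bed,
    read_gff3, shuffle_intervals, subtract_intervals, write_bed, write_gff3,
)


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_overlap_pairs(a, b, min_bp=1):
    out = []
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if x.chrom == y.chrom and \
                    min(x.end, y.end) - max(x.start, y.start) >= min_bp:
                out.append((i, j))
    return sorted(out)


def brute_coverage(intervals, chrom, length):
    mask = np.zeros(length, dtype=bool)
    for x in intervals:
        if x.chrom == chrom:
            mask[x.start:x.end] = True
    return mask


def random_intervals(rng, n, chroms=("c1", "c2"), span=1000, max_len=80):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span - 1))
        length = int(rng.integers(1, max_len))
        out.append(iv(str(rng.choice(chroms)), start,
                      min(span, start + length)))
    return out


# ---------------------------------------------------------------------------
# GenomicInterval / BED
# ---------------------------------------------------------------------------

class TestBed:
    def test_parse_bed6_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1A\t0\t100\tp1\t5\t+\n")
        [x] = read_bed(p)
        assert (x.chrom, x.start, x.end, x.name, x.score, x.strand) == \
            ("chr1A", 0, 100, "p1", 5.0, "+")

    def test_round_trip_identity(self, tmp_path, rng):
        ivs = random_intervals(rng, 50)
        ivs = sorted(ivs, key=GenomicInterval.sort_key)
        p = tmp_path / "rt.bed"
        write_bed(ivs, p)
        back = read_bed(p)
        assert [(x.chrom, x.start, x.end) for x in back] == \
            [(x.chrom, x.start, x.end) for x in ivs]

    def test_zero_length_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1A\t100\t100\n")
        with pytest.raises(IntervalError, match="zero-length interval"):
            read_bed(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1A\t0\t100\nchr1A 5\n")
        with pytest.raises(IntervalError, match="line 2"):
            read_bed(p)

    def test_narrowpeak_extra_columns_preserved(self, tmp_path):
        p = tmp_path / "np.bed"
        p.write_text("c\t10\t60\tpk\t900\t.\t4.5\t3.2\t2.1\t25\n")
        [x] = read_bed(p)
        assert x.extra == ("4.5", "3.2", "2.1", "25")
        out = tmp_path / "out.bed"
        write_bed([x], out)
        assert read_bed(out)[0].extra == x.extra


class TestGff3:
    def write(self, tmp_path, body):
        p = tmp_path / "g.gff3"
        p.write_text("##gff-version 3\n" + body)
        return p

    def test_single_exon_plus_strand(self, tmp_path):
        body = (
            "c\t.\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "c\t.\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\t.\texon\t1001\t2000\t.\t+\t.\tParent=t1\n")
        [g] = read_gff3(self.write(tmp_path, body))
        assert (g.tss, g.tes) == (1000, 2000)
        kinds = [k for k, _ in g.feature_intervals]
        assert kinds == ["exon"]

    def test_minus_strand_tss_is_five_prime(self, tmp_path):
        body = (
            "c\t.\tgene\t1001\t2000\t.\t-\t.\tID=g1\n"
            "c\t.\tmRNA\t1001\t2000\t.\t-\t.\tID=t1;Parent=g1\n"
            "c\t.\texon\t1001\t2000\t.\t-\t.\tParent=t1\n")
        [g] = read_gff3(self.write(tmp_path, body))
        assert (g.tss, g.tes) == (2000, 1000)

    def test_intron_derived_from_exon_gap(self, tmp_path):
        body = (
            "c\t.\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "c\t.\tmRNA\t1001\t2000\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\t.\texon\t1001\t1200\t.\t+\t.\tParent=t1\n"
            "c\t.\texon\t1501\t2000\t.\t+\t.\tParent=t1\n")
        [g] = read_gff3(self.write(tmp_path, body))
        introns = [x for k, x in g.feature_intervals if k == "intron"]
        assert [(x.start, x.end) for x in introns] == [(1200, 1500)]

    def test_unknown_strand_rejected(self, tmp_path):
        body = "c\t.\tgene\t1001\t2000\t.\t?\t.\tID=g1\n"
        with pytest.raises(IntervalError, match="strand"):
            read_gff3(self.write(tmp_path, body))

    def test_write_read_round_trip(self, tmp_path, small_ds):
        p = tmp_path / "rt.gff3"
        genes = small_ds.genome.genes[:40]
        write_gff3(genes, p)
        back = {g.gene_id: g for g in read_gff3(p)}
        for g in genes:
            b = back[g.gene_id]
            assert (b.tss, b.tes, b.strand, b.subgenome, b.triad_id) == \
                (g.tss, g.tes, g.strand, g.subgenome, g.triad_id)


# ---------------------------------------------------------------------------
# overlap / merge / subtract
# ---------------------------------------------------------------------------

class TestAlgebra:
    def test_one_bp_overlap_counts(self):
        assert overlap_pairs([iv("c", 0, 100)], [iv("c", 99, 200)]) == [(0, 0)]

    def test_half_open_adjacency_is_not_overlap(self):
        assert overlap_pairs([iv("c", 0, 100)], [iv("c", 100, 200)]) == []

    def test_min_overlap_threshold(self):
        a, b = [iv("c", 0, 100)], [iv("c", 95, 200)]
        assert overlap_pairs(a, b, min_overlap_bp=5) == [(0, 0)]
        assert overlap_pairs(a, b, min_overlap_bp=6) == []

    @pytest.mark.parametrize("trial", range(5))
    def test_overlap_matches_brute_force(self, trial):
        rng = np.random.default_rng(100 + trial)
        a = random_intervals(rng, 50)
        b = random_intervals(rng, 50)
        assert overlap_pairs(a, b) == brute_overlap_pairs(a, b)

    @pytest.mark.parametrize("trial", range(5))
    def test_merge_subtract_match_coverage_masks(self, trial):
        rng = np.random.default_rng(200 + trial)
        a = random_intervals(rng, 60)
        b = random_intervals(rng, 60)
        for chrom in ("c1", "c2"):
            mask_m = brute_coverage(merge_intervals(a), chrom, 1000)
            assert (mask_m == brute_coverage(a, chrom, 1000)).all()
            sub = subtract_intervals(a, b)
            expect = brute_coverage(a, chrom, 1000) & \
                ~brute_coverage(b, chrom, 1000)
            assert (brute_coverage(sub, chrom, 1000) == expect).all()


# ---------------------------------------------------------------------------
# peak assignment
# ---------------------------------------------------------------------------

def toy_genome():
    g1 = GeneModel(
        "g1", "c", "+", tss=10_000, tes=12_000,
        feature_intervals=[("exon", iv("c", 10_000, 12_000, strand="+"))])
    g2 = GeneModel(
        "g2", "c", "+", tss=13_000, tes=16_000,
        feature_intervals=[
            ("exon", iv("c", 13_000, 14_000, strand="+")),
            ("intron", iv("c", 14_000, 15_500, strand="+")),
            ("exon", iv("c", 15_500, 16_000, strand="+"))])
    return Genome({"c": 100_000}, [g1, g2])


class TestAssignment:
    def test_peak_upstream_is_promoter(self):
        genome = toy_genome()
        assert assign_peak_to_gene(iv("c", 8_900, 9_100), genome) == \
            ("g1", "promoter")

    def test_promoter_beats_intron(self):
        # peak in g2's intron that also sits < 3 kb before g2's... use a
        # peak overlapping g1's downstream and inside g2's promoter window
        genome = toy_genome()
        peak = iv("c", 12_100, 12_300)   # g1 downstream + g2 promoter
        assert assign_peak_to_gene(peak, genome) == ("g2", "promoter")

    def test_exon_beats_intron_priority(self):
        genome = toy_genome()
        # overlaps g2 exon1 and intron; exon has priority, same gene
        peak = iv("c", 13_900, 14_100)
        assert assign_peak_to_gene(peak, genome) == ("g2", "exon")

    def test_far_peak_is_distal(self):
        genome = toy_genome()
        assert assign_peak_to_gene(iv("c", 50_000, 50_300), genome) == \
            (None, "distal")

    def test_unknown_chrom_errors(self):
        with pytest.raises(IntervalError, match="absent"):
            assign_peak_to_gene(iv("cX", 0, 10), toy_genome())

    def test_minus_strand_promoter_window(self):
        g = GeneModel("gm", "c", "-", tss=20_000, tes=18_000,
                      feature_intervals=[
                          ("exon", iv("c", 18_000, 20_000, strand="-"))])
        genome = Genome({"c": 100_000}, [g])
        assert assign_peak_to_gene(iv("c", 20_500, 20_700), genome) == \
            ("gm", "promoter")
        assert assign_peak_to_gene(iv("c", 17_000, 17_400), genome) == \
            ("gm", "downstream")

    def test_assignment_partitions_peaks(self, small_ds):
        genome = small_ds.genome
        stage = small_ds.config.stages[4]
        peaks = small_ds.peaks.peaks["ATAC"][stage][:200]
        for p in peaks:
            gene, cat = assign_peak_to_gene(p, genome)
            assert (cat == "distal") == (gene is None)


# ---------------------------------------------------------------------------
# shuffling
# ---------------------------------------------------------------------------

class TestShuffle:
    def test_length_multiset_preserved_inside_domain(self):
        dom = [iv("c", 0, 10_000)]
        src = [iv("c", 5, 105), iv("c", 50, 250)]
        for s in shuffle_intervals(src, dom, seed=1, n_shuffles=20):
            assert sorted(len(x) for x in s) == [100, 200]
            assert all(0 <= x.start and x.end <= 10_000 for x in s)

    def test_infeasible_length_errors(self):
        dom = [iv("c", 0, 100), iv("c", 500, 700)]
        with pytest.raises(IntervalError, match="length"):
            shuffle_intervals([iv("c", 0, 500)], dom, seed=1, n_shuffles=1)

    def test_equal_seeds_bitwise_reproducible(self):
        dom = [iv("c", 0, 5_000), iv("c", 8_000, 9_000)]
        src = [iv("c", 0, 120)] * 5
        a = shuffle_intervals(src, dom, seed=42, n_shuffles=10)
        b = shuffle_intervals(src, dom, seed=42, n_shuffles=10)
        assert a == b

    def test_different_seeds_diverge(self):
        dom = [iv("c", 0, 100_000)]
        src = [iv("c", 0, 100)] * 20
        [a] = shuffle_intervals(src, dom, seed=1, n_shuffles=1)
        [b] = shuffle_intervals(src, dom, seed=2, n_shuffles=1)
        inter = len({(x.start, x.end) for x in a} &
                    {(x.start, x.end) for x in b})
        union = len({(x.start, x.end) for x in a} |
                    {(x.start, x.end) for x in b})
        assert inter / union < 0.5

    def test_placement_probability_matches_closed_form(self):
        # a length-L interval placed uniformly in [0, D) overlaps a fixed
        # feature [f0, f1) iff start in (f0 - L, f1), clipped to [0, D - L]
        D, L = 2_000, 100
        f0, f1 = 700, 800
        feature = [iv("c", f0, f1)]
        dom = [iv("c", 0, D)]
        n = 10_000
        shuffles = shuffle_intervals([iv("c", 0, L)], dom, seed=3,
                                     n_shuffles=n)
        hits = sum(
            1 for [x] in shuffles
            if min(x.end, f1) - max(x.start, f0) >= 1)
        lo = max(0, f0 - L + 1)
        hi = min(D - L, f1 - 1)
        p = (hi - lo + 1) / (D - L + 1)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se
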