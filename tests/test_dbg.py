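import itertools

import numpy as np
import pytest

from haplec.dbg import DbgParams, build_dbg, correct_with_dbg, find_solid_regions
from haplec.io_formats import SeqRecord, reverse_complement

from conftest import random_seq


def brute_force_counts(reads, k):
    """Independent oracle: canonical k-mer counts by direct scanning."""
    counts = {}
    for r in reads:
        for i in range(len(r.seq) - k + 1):
            km = r.seq[i:i + k]
            if "N" in km:
                continue
            can = min(km, reverse_complement(km))
            counts[can] = counts.get(can, 0) + 1
    return counts


class TestBuildDbg:
    def test_single_read_distinct_kmers(self):
        seq = "AAAACAAAGAAATAAA"
        k = 5
        kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
        cans = {min(km, reverse_complement(km)) for km in kmers}
        assert len(cans) == len(kmers)  # setup: no repeats, no rc collisions
        dbg = build_dbg([SeqRecord("r", seq)], k=k, t_solid=1)
        assert len(dbg) == len(seq) - k + 1

    def test_reverse_complement_canonicalized(self):
        seq = "ACGTTGCAACG"
        dbg = build_dbg([SeqRecord("a", seq),
                         SeqRecord("b", reverse_complement(seq))], k=11, t_solid=1)
        assert len(dbg) == 1
        assert dbg.count(seq) == 2

    def test_counts_match_brute_force_oracle(self, rng):
        reads = [SeqRecord(f"r{i}", random_seq(rng, rng.integers(80, 300)))
                 for i in range(60)]
        k = 15
        dbg = build_dbg(reads, k=k, t_solid=2)
        assert dbg.to_dict() == brute_force_counts(reads, k)

    def test_kmers_with_n_skipped(self):
        dbg = build_dbg([SeqRecord("r", "ACGTNACGTACGTA")], k=11, t_solid=1)
        assert len(dbg) == 0 or all("N" not in k for k in dbg.to_dict())

    def test_k_larger_than_reads_rejected(self):
        with pytest.raises(ValueError):
            build_dbg([SeqRecord("r", "ACGT")], k=21)


class TestSolidRegions:
    def test_fully_solid_read_single_interval(self, rng):
        seq = random_seq(rng, 200)
        dbg = build_dbg([SeqRecord("s", seq)] * 3, k=21, t_solid=3)
        read = SeqRecord("r", seq)
        assert find_solid_regions(read, dbg) == [(0, 200)]

    def test_no_solid_kmers_empty(self, rng):
        dbg = build_dbg([SeqRecord("s", random_seq(rng, 100))], k=21, t_solid=3)
        read = SeqRecord("r", random_seq(rng, 100))
        assert find_solid_regions(read, dbg) == []

    def test_single_substitution_splits_into_flanking_intervals(self, rng):
        seq = random_seq(rng, 200)
        dbg = build_dbg([SeqRecord("s", seq)] * 3, k=21, t_solid=3)
        pos = 100
        mutated = seq[:pos] + ("A" if seq[pos] != "A" else "C") + seq[pos + 1:]
        regions = find_solid_regions(SeqRecord("r", mutated), dbg)
        assert len(regions) == 2
        (s1, e1), (s2, e2) = regions
        assert s1 == 0 and e1 <= pos + 21 - 1 and s2 >= pos + 1 and e2 == 200


class TestCorrectWithDbg:
    @pytest.fixture
    def genome_dbg(self, rng):
        genome = random_seq(rng, 5000)
        shorts = []
        for i in range(0, 5000 - 100, 10):  # 10x tiling coverage
            shorts.append(SeqRecord(f"s{i}", genome[i:i + 100]))
        dbg = build_dbg(shorts, k=21, t_solid=3)
        return genome, dbg

    def test_error_free_read_is_fixed_point(self, genome_dbg):
        genome, dbg = genome_dbg
        read = SeqRecord("r", genome[1000:2000])
        out = correct_with_dbg(read, dbg, DbgParams())
        assert out.seq == read.seq and out.id == read.id

    def test_planted_deletion_restored(self, genome_dbg):
        import edlib
        genome, dbg = genome_dbg
        true = genome[1000:2000]
        read = SeqRecord("r", true[:500] + true[501:])  # 1 bp deletion
        out = correct_with_dbg(read, dbg, DbgParams())
        assert out.seq == true
        assert edlib.align(out.seq, true, mode="NW", task="distance")["editDistance"] == 0

    def test_planted_substitution_restored(self, genome_dbg):
        genome, dbg = genome_dbg
        true = genome[2000:3000]
        bad = true[:400] + ("A" if true[400] != "A" else "C") + true[401:]
        out = correct_with_dbg(SeqRecord("r", bad), dbg, DbgParams())
        assert out.seq == true

    def test_ambiguous_equal_length_paths_left_unchanged(self, rng):
        # two haplotypes differing by one SNP inside the weak gap: both
        # paths are solid with identical length, so the unique-path rule
        # must refuse to correct
        left = random_seq(rng, 60)
        right = random_seq(rng, 60)
        mid_a, mid_b = "A", "G"
        hapA = left + mid_a + right
        hapB = left + mid_b + right
        shorts = [SeqRecord(f"a{i}", hapA) for i in range(5)] + \
                 [SeqRecord(f"b{i}", hapB) for i in range(5)]
        dbg = build_dbg(shorts, k=21, t_solid=3)
        # read from haplotype A with an error right at the SNP position
        bad = left + "C" + right
        assert "C" not in (mid_a, mid_b)
        out = correct_with_dbg(SeqRecord("r", bad), dbg, DbgParams())
        assert out.seq == bad

    def test_solid_regions_never_modified(self, genome_dbg, rng):
        genome, dbg = genome_dbg
        true = genome[3000:4000]
        # plant several errors
        bad = list(true)
        for pos in (100, 400, 700):
            bad[pos] = "A" if bad[pos] != "A" else "T"
        bad = "".join(bad)
        regions = find_solid_regions(SeqRecord("r", bad), dbg)
        out = correct_with_dbg(SeqRecord("r", bad), dbg, DbgParams())
        # verify every originally solid base interval is preserved verbatim
        # (solid regions can only grow; they are never rewritten)
        for s, e in regions:
            assert bad[s:e] in out.seq

    def test_iterated_correction_monotone_on_simulated_reads(self):
        import edlib
        from haplec.simulate import ReadSimParams, simulate_haplotypes, simulate_reads
        truth = simulate_haplotypes(30_000, 1, 0.0, seed=31)
        hap = truth.haplotypes[0].seq
        long_reads, short_reads, placements = simulate_reads(
            truth, ReadSimParams(long_mean_len=6000, long_err_rate=0.10,
                                 short_err_rate=0.003, seed=32))
        dbg = build_dbg(short_reads, k=21, t_solid=3)
        pls = {p.read_id: p for p in placements}

        def mean_ed(reads):
            tot = n = 0
            for r in reads:
                p = pls[r.id]
                frag = hap[p.start:p.end]
                if p.strand == "-":
                    frag = reverse_complement(frag)
                tot += edlib.align(r.seq, frag, mode="NW",
                                   task="distance")["editDistance"]
                n += len(r.seq)
            return tot / n

        params = DbgParams()
        e0 = mean_ed(long_reads)
        reads = [correct_with_dbg(r, dbg, params) for r in long_reads]
        e1 = mean_ed(reads)
        assert e1 < e0  # strictly decreases after one pass
        for _ in range(2):
            reads = [correct_with_dbg(r, dbg, params) for r in reads]
        e3 = mean_ed(reads)
        assert e3 <= e1  # further passes never make it worse
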