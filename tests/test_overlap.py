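import numpy as np
import pytest
from hypothesis import given, strategies as st

from haplec.io_formats import SeqRecord, reverse_complement
from haplec.overlap import (
    MapParams,
    alignments_from_paf,
    alignments_to_paf,
    banded_align,
    map_short_to_long,
)

from conftest import random_seq


def full_dp_edit_distance(a: str, b: str) -> int:
    """Unbanded Levenshtein oracle."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[m]


def replay_ops(aln, long_seq: str) -> None:
    """Check that the edit script reconstructs consistent substrings."""
    t = aln.long_start
    q = 0
    qseq = aln.query_seq
    for op, length in aln.ops:
        if op == "=":
            assert qseq[q:q + length] == long_seq[t:t + length]
            q += length
            t += length
        elif op == "X":
            assert all(qseq[q + i] != long_seq[t + i] for i in range(length))
            q += length
            t += length
        elif op == "I":
            q += length
        else:
            t += length
    assert t == aln.long_end
    assert q == len(qseq)


class TestBandedAlign:
    def test_identical_sequences(self):
        ops, ed = banded_align("ACGTACGT", "ACGTACGT")
        assert ed == 0 and ops == [("=", 8)]

    def test_single_substitution_matches_full_dp(self):
        a, b = "ACGTACGTAC", "ACGTTCGTAC"
        ops, ed = banded_align(a, b)
        assert ed == 1 == full_dp_edit_distance(a, b)
        assert sum(l for op, l in ops if op == "X") == 1

    def test_length_difference_beyond_band_rejected(self):
        assert banded_align("A" * 5, "A" * 40, band=10) is None

    def test_random_pairs_match_full_dp_oracle(self, rng):
        # 200 random trials; banded distance equals the unbanded DP
        # whenever the true distance fits in the band
        for _ in range(200):
            n1 = int(rng.integers(5, 51))
            n2 = int(rng.integers(max(1, n1 - 10), n1 + 10))
            a, b = random_seq(rng, n1), random_seq(rng, n2)
            truth = full_dp_edit_distance(a, b)
            res = banded_align(a, b, band=50)
            assert res is not None
            assert res[1] == truth

    @given(st.text(alphabet="ACGT", min_size=1, max_size=30),
           st.text(alphabet="ACGT", min_size=1, max_size=30))
    def test_ops_consume_both_sequences(self, a, b):
        res = banded_align(a, b, band=40)
        assert res is not None
        ops, ed = res
        q = sum(l for op, l in ops if op in "=XI")
        t = sum(l for op, l in ops if op in "=XD")
        assert q == len(a) and t == len(b)
        assert ed == full_dp_edit_distance(a, b)


class TestMapShortToLong:
    @pytest.fixture
    def long_read(self, rng):
        return SeqRecord("L", random_seq(rng, 6000))

    def test_exact_substring_maps_cleanly(self, long_read):
        sub = long_read.seq[1000:1250]
        (aln,) = map_short_to_long([SeqRecord("s", sub)], [long_read])
        assert (aln.long_start, aln.long_end, aln.strand, aln.n_edits) == \
            (1000, 1250, "+", 0)
        replay_ops(aln, long_read.seq)

    def test_reverse_complement_same_interval(self, long_read):
        sub = reverse_complement(long_read.seq[2000:2250])
        (aln,) = map_short_to_long([SeqRecord("s", sub)], [long_read])
        assert (aln.long_start, aln.long_end, aln.strand, aln.n_edits) == \
            (2000, 2250, "-", 0)
        replay_ops(aln, long_read.seq)

    def test_unrelated_read_unmapped(self, long_read, rng):
        alns = map_short_to_long([SeqRecord("s", random_seq(rng, 250))],
                                 [long_read])
        assert alns == []

    def test_noisy_read_coordinates_and_ops_consistent(self, long_read, rng):
        frag = list(long_read.seq[3000:3250])
        frag[50] = "A" if frag[50] != "A" else "C"
        del frag[120]
        (aln,) = map_short_to_long([SeqRecord("s", "".join(frag))], [long_read])
        assert abs(aln.long_start - 3000) <= 2
        assert aln.n_edits >= 2
        replay_ops(aln, long_read.seq)

    def test_read_overhanging_target_start_is_clipped(self, long_read):
        # 100 bases hang off the start of the target: only the overlapping
        # 150 bases should be aligned, with no forced garbage edits
        pre = random_seq(np.random.default_rng(9), 100)
        sread = SeqRecord("s", pre + long_read.seq[:150])
        (aln,) = map_short_to_long([sread], [long_read])
        assert aln.long_start == 0
        assert aln.n_edits <= 2
        assert len(aln.query_seq) <= 160


class TestPafInterop:
    def test_paf_round_trip_agrees_with_internal_mapping(self, rng):
        genome = random_seq(rng, 8000)
        long_reads = [SeqRecord("L", genome)]
        shorts = []
        for i in range(40):
            s = int(rng.integers(0, 8000 - 250))
            frag = genome[s:s + 250]
            if rng.random() < 0.5:
                frag = reverse_complement(frag)
            shorts.append(SeqRecord(f"s{i}", frag))
        alns = map_short_to_long(shorts, long_reads)
        paf = alignments_to_paf(alns, {s.id: len(s.seq) for s in shorts},
                                {"L": 8000})
        back = alignments_from_paf(paf, shorts, long_reads)
        agree = sum(
            1 for a, b in zip(sorted(alns, key=lambda x: x.short_id),
                              sorted(back, key=lambda x: x.short_id))
            if abs(a.long_start - b.long_start) <= 5
            and abs(a.long_end - b.long_end) <= 5)
        assert agree >= 0.95 * len(alns)
        for b in back:
            replay_ops(b, genome)

    def test_paf_without_cg_rejected(self, rng):
        from haplec.io_formats import PafRecord
        genome = random_seq(rng, 1000)
        rec = PafRecord("s", 250, 0, 250, "+", "L", 1000, 0, 250, 250, 250, 60)
        with pytest.raises(ValueError, match="cg"):
            alignments_from_paf([rec], [SeqRecord("s", genome[:250])],
                                [SeqRecord("L", genome)])
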