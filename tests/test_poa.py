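import itertools

import numpy as np
import pytest

from haplec.io_formats import SeqRecord
from haplec.overlap import map_short_to_long
from haplec.phasing import build_pile, phase_filter
from haplec.poa import (
    PoaGraph,
    PoaParams,
    Window,
    concatenate_subreads,
    correct_window,
    poa_align_and_consensus,
    segment_windows,
)

from conftest import random_seq


def msa_column_majority(segments):
    """Oracle for substitution-only, equal-length segment sets: the exact
    multiple alignment is the trivial stacking, and the consensus is the
    per-column majority (ties: first base in A<C<G<T order)."""
    L = len(segments[0])
    assert all(len(s) == L for s in segments)
    out = []
    for i in range(L):
        counts = {}
        for s in segments:
            counts[s[i]] = counts.get(s[i], 0) + 1
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


class TestPoaConsensus:
    def test_single_segment_is_identity(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        assert poa_align_and_consensus([("s", seq)]) == seq

    def test_five_identical_segments_weight_five(self):
        g = PoaGraph()
        for _ in range(5):
            g.add_sequence("ACGTTGCAGT")
        assert g.consensus() == "ACGTTGCAGT"
        assert {w for _, _, w in g.edges()} == {5}
        assert g.n_nodes == 10

    def test_majority_over_single_substitution(self, rng):
        base = random_seq(rng, 40)
        variant = "A" + base[1:] if base[0] != "A" else "C" + base[1:]
        segs = [("a", base)] * 4 + [("b", variant)]
        assert poa_align_and_consensus(segs) == base

    def test_substitution_only_windows_match_msa_majority(self, rng):
        # randomized small instances vs the exact-MSA column majority
        for trial in range(40):
            L = int(rng.integers(20, 61))
            n = int(rng.integers(3, 9))
            base = random_seq(rng, L)
            segs = [list(base) for _ in range(n)]
            # mutate a strict minority of segments so every column has a
            # unique majority and the oracle is unambiguous
            n_mut = int(rng.integers(0, (n - 1) // 2 + 1))
            for i in rng.choice(n, size=n_mut, replace=False):
                for _ in range(int(rng.integers(1, 4))):
                    p = int(rng.integers(0, L))
                    segs[i][p] = "ACGT"[int(rng.integers(0, 4))]
            segs = [(f"s{i}", "".join(s)) for i, s in enumerate(segs)]
            cons = poa_align_and_consensus(segs)
            oracle = msa_column_majority([s for _, s in segs])
            assert cons == oracle, f"trial {trial}"

    def test_exhaustive_tiny_instances_match_majority(self):
        # every substitution pattern of 3 segments over a 4-base window
        base = "ACGT"
        for alt in itertools.product("AG", repeat=4):
            seg2 = "".join(alt)
            segs = [("a", base), ("b", base), ("c", seg2)]
            assert poa_align_and_consensus(segs) == base

    def test_deterministic_across_runs(self, rng):
        segs = [(f"s{i}", random_seq(np.random.default_rng(100 + i), 60))
                for i in range(6)]
        a = poa_align_and_consensus(segs)
        b = poa_align_and_consensus(segs)
        assert a == b

    def test_staggered_anchored_segments_stitch(self, rng):
        full = random_seq(rng, 300)
        segs = [("a", full[:200]), ("b", full[50:250]), ("c", full[100:300])]
        out = poa_align_and_consensus(segs, PoaParams(), [0, 50, 100])
        assert out == full

    def test_empty_segment_list_rejected(self):
        with pytest.raises(ValueError):
            poa_align_and_consensus([])


class TestWindows:
    def _pile(self, rng, L=1500, cover_step=40, read_len=260):
        target = SeqRecord("T", random_seq(rng, L))
        shorts = [SeqRecord(f"s{i}", target.seq[p:p + read_len])
                  for i, p in enumerate(range(0, L - read_len + 1, cover_step))]
        alns = map_short_to_long(shorts, [target])
        return build_pile(target, alns)

    def test_window_boundaries(self, rng):
        pile = self._pile(rng, L=1500)
        wins = segment_windows(pile, 500)
        assert [(w.start, w.end) for w in wins] == [(0, 500), (500, 1000), (1000, 1500)]

    def test_remainder_window(self, rng):
        pile = self._pile(rng, L=1499)
        wins = segment_windows(pile, 500)
        assert wins[-1].end - wins[-1].start == 499

    def test_member_split_consistent_with_ops(self, rng):
        target = SeqRecord("T", random_seq(rng, 1000))
        (aln,) = map_short_to_long([SeqRecord("s", target.seq[450:620])], [target])
        wins = segment_windows(build_pile(target, [aln]), 500)
        (w0_seg,) = [s for _, s in wins[0].segments]
        (w1_seg,) = [s for _, s in wins[1].segments]
        assert w0_seg == target.seq[450:500] and len(w0_seg) == 50
        assert w1_seg == target.seq[500:620] and len(w1_seg) == 120
        assert wins[0].segment_cols == [450]
        assert wins[1].segment_cols == [0]

    def test_member_ending_exactly_on_boundary(self, rng):
        # an alignment whose end coincides with a window boundary emits a
        # slice for the boundary and nothing after it
        target = SeqRecord("T", random_seq(rng, 1500))
        (aln,) = map_short_to_long([SeqRecord("s", target.seq[250:500])], [target])
        assert (aln.long_start, aln.long_end) == (250, 500)
        wins = segment_windows(build_pile(target, [aln]), 500)
        assert len(wins[0].segments) == 1
        assert wins[0].segments[0][1] == target.seq[250:500]
        assert wins[1].segments == [] and wins[2].segments == []

    def test_many_boundary_aligned_members(self, rng):
        # stress the slice bookkeeping with many boundary-ending members
        target = SeqRecord("T", random_seq(rng, 2000))
        shorts = [SeqRecord(f"s{i}", target.seq[s:s + 250])
                  for i, s in enumerate(range(0, 1750, 250))]
        wins = segment_windows(
            build_pile(target, map_short_to_long(shorts, [target])), 500)
        got = sorted((w.start, sid) for w in wins for sid, _ in w.segments)
        assert len(got) == 7

    def test_short_clips_dropped(self, rng):
        target = SeqRecord("T", random_seq(rng, 1000))
        (aln,) = map_short_to_long([SeqRecord("s", target.seq[490:740])], [target])
        wins = segment_windows(build_pile(target, [aln]), 500)
        assert wins[0].segments == []  # 10 bp clip dropped
        assert len(wins[1].segments) == 1


class TestCorrectWindow:
    def test_no_segments_keeps_subread(self):
        w = Window("T", 0, 100, "ACGT" * 25, [], [])
        assert correct_window(w) == w.target_subread

    def test_below_min_cov_keeps_subread(self, rng):
        sub = random_seq(rng, 100)
        w = Window("T", 0, 100, sub, [("a", sub), ("b", sub)], [0, 0])
        assert correct_window(w, PoaParams(min_window_cov=3)) == sub

    def test_planted_indels_fixed_by_clean_segments(self, rng):
        true = random_seq(rng, 400)
        # target subread with 3 planted indels
        bad = true[:50] + true[51:200] + "GG" + true[200:330] + true[331:]
        segs = [(f"s{i}", true[o:o + 250]) for i, o in
                enumerate([0, 30, 60, 90, 120, 150])]
        cols = [0, 30, 60, 90, 120, 150]
        w = Window("T", 0, len(bad), bad, segs, cols)
        assert correct_window(w, PoaParams()) == true

    def test_interior_coverage_hole_keeps_subread(self, rng):
        sub = random_seq(rng, 500)
        segs = [("a", sub[:100])] * 3 + [("b", sub[400:])] * 3
        cols = [0, 0, 0, 400, 400, 400]
        w = Window("T", 0, 500, sub, segs, cols)
        assert correct_window(w, PoaParams()) == sub

    def test_uncovered_window_edges_keep_target_sequence(self, rng):
        sub = random_seq(rng, 500)
        segs = [(f"s{i}", sub[100:400]) for i in range(4)]
        w = Window("T", 0, 500, sub, segs, [100] * 4)
        assert correct_window(w, PoaParams()) == sub


class TestConcatenate:
    def test_identity_concatenation(self, rng):
        pile_target = SeqRecord("T", random_seq(rng, 1499))
        wins = segment_windows(build_pile(pile_target, []), 500)
        subs = [w.target_subread for w in wins]
        rec = concatenate_subreads(subs, wins, "T")
        assert rec.seq == pile_target.seq and rec.id == "T"

    def test_length_is_sum_of_subreads(self, rng):
        wins = segment_windows(build_pile(SeqRecord("T", random_seq(rng, 1499)), []), 500)
        subs = ["A" * 500, "C" * 500, "G" * 499]
        assert len(concatenate_subreads(subs, wins, "T").seq) == 1499

    def test_window_count_mismatch_rejected(self, rng):
        wins = segment_windows(build_pile(SeqRecord("T", random_seq(rng, 1000)), []), 500)
        with pytest.raises(ValueError):
            concatenate_subreads(["A"], wins, "T")


def test_window_order_independence(rng):
    """Windows share no state: correcting them in any order gives the
    same full-length read."""
    from haplec.simulate import ReadSimParams, simulate_haplotypes, simulate_reads
    truth = simulate_haplotypes(6000, 1, 0.0, seed=41)
    lr, sr, _ = simulate_reads(
        truth, ReadSimParams(long_mean_len=3000, long_err_rate=0.02,
                             short_err_rate=0.0, seed=42))
    target = lr[0]
    alns = [a for a in map_short_to_long(sr, [target])]
    filtered, _ = phase_filter(build_pile(target, alns))
    wins = segment_windows(filtered, 500)
    params = PoaParams()
    forward = [correct_window(w, params) for w in wins]
    backward = [correct_window(w, params) for w in reversed(wins)][::-1]
    assert forward == backward
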