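import numpy as np
import pytest
from hypothesis import given, strategies as st

from haplec.io_formats import SeqRecord
from haplec.overlap import map_short_to_long
from haplec.phasing import (
    HAP_SNP,
    MATCH,
    NGS_ERROR,
    TGS_ERROR,
    PhasingParams,
    build_pile,
    classify_column,
    phase_filter,
)

from conftest import random_seq


class TestClassifyColumn:
    """The three support scenarios, decided purely from counts."""

    def test_all_reads_disagree_means_target_error(self):
        c = classify_column("G", {"A": 6})
        assert c.label == TGS_ERROR and c.corrected_base == "A"

    def test_both_alleles_strong_means_haplotype_snp(self):
        assert classify_column("A", {"A": 7, "C": 6}).label == HAP_SNP

    def test_single_disagreeing_read_is_short_read_error(self):
        assert classify_column("G", {"G": 9, "T": 1}).label == NGS_ERROR

    def test_four_read_boundary_is_still_short_read_error(self):
        # "at most four" disagreeing reads are attributed to errors
        assert classify_column("A", {"A": 8, "C": 4}).label == NGS_ERROR

    def test_no_disagreement_is_match(self):
        assert classify_column("A", {"A": 12}).label == MATCH

    def test_gap_allele_follows_same_rules(self):
        assert classify_column("A", {"-": 9, "A": 1}).label == TGS_ERROR
        assert classify_column("A", {"-": 9, "A": 9}).label == HAP_SNP
        assert classify_column("A", {"-": 3, "A": 9}).label == NGS_ERROR

    def test_tie_between_alternatives_prefers_lexicographic(self):
        c = classify_column("T", {"C": 6, "A": 6})
        assert c.label == TGS_ERROR and c.corrected_base == "A"

    @given(st.dictionaries(st.sampled_from("ACGT-"),
                           st.integers(min_value=0, max_value=30), max_size=5),
           st.sampled_from("ACGT"))
    def test_pure_function_of_counts(self, support, target):
        a = classify_column(target, support)
        b = classify_column(target, dict(reversed(list(support.items()))))
        assert (a.label, a.corrected_base) == (b.label, b.corrected_base)

    @given(st.sampled_from("ACGT"),
           st.dictionaries(st.sampled_from("ACGT-"),
                           st.integers(min_value=0, max_value=30), max_size=5))
    def test_min_support_monotonicity(self, target, support):
        # raising min_support can only move labels toward NGS_ERROR/MATCH
        strength = {TGS_ERROR: 2, HAP_SNP: 2, NGS_ERROR: 1, MATCH: 0}
        labels = [classify_column(target, support, PhasingParams(ms)).label
                  for ms in (2, 4, 6, 9)]
        ranks = [strength[l] for l in labels]
        assert ranks == sorted(ranks, reverse=True)


class TestPile:
    def test_empty_pile(self, rng):
        target = SeqRecord("T", random_seq(rng, 100))
        pile = build_pile(target, [])
        assert len(pile) == 0
        assert all(v == [] for v in pile.column_index.values())

    def test_exact_alignment_columns(self, rng):
        target = SeqRecord("T", random_seq(rng, 600))
        (aln,) = map_short_to_long([SeqRecord("s", target.seq[100:350])], [target])
        pile = build_pile(target, [aln])
        idx = pile.column_index
        assert idx[99] == [] and idx[350] == []
        for pos in range(100, 350):
            assert idx[pos] == [("s", target.seq[pos])]

    def test_mismatch_columns_hand_computed(self, rng):
        target = SeqRecord("T", random_seq(rng, 600))
        f1 = list(target.seq[100:350])
        f1[50] = "A" if f1[50] != "A" else "C"
        f2 = list(target.seq[200:450])
        f2[100] = "G" if f2[100] != "G" else "T"
        alns = map_short_to_long(
            [SeqRecord("s1", "".join(f1)), SeqRecord("s2", "".join(f2))], [target])
        pile = build_pile(target, alns)
        counts = pile.counts()
        # column 150: s1 shows its substituted base, s2 absent
        assert counts[150].sum() == 1
        assert counts[150, "ACGT".index(f1[50])] == 1
        # column 300: s1 shows target base, s2 shows its substitution
        assert counts[300].sum() == 2
        assert counts[300, "ACGT".index(target.seq[300])] == 1
        assert counts[300, "ACGT".index(f2[100])] == 1

    def test_member_targeting_other_read_rejected(self, rng):
        target = SeqRecord("T", random_seq(rng, 400))
        (aln,) = map_short_to_long([SeqRecord("s", target.seq[50:300])], [target])
        with pytest.raises(ValueError):
            build_pile(SeqRecord("T2", target.seq), [aln])


class TestPhaseFilter:
    def _two_hap_pile(self, rng, n_a=6, n_b=6):
        hapA = random_seq(rng, 1200)
        pos = 600
        alt = "A" if hapA[pos] != "A" else "C"
        hapB = hapA[:pos] + alt + hapA[pos + 1:]
        target = SeqRecord("T", hapA)
        shorts = [SeqRecord(f"a{i}", hapA[450:850]) for i in range(n_a)] + \
                 [SeqRecord(f"b{i}", hapB[450:850]) for i in range(n_b)]
        alns = map_short_to_long(shorts, [target])
        return build_pile(target, alns)

    def test_no_disagreement_is_identity(self, rng):
        target = SeqRecord("T", random_seq(rng, 800))
        shorts = [SeqRecord(f"s{i}", target.seq[i * 50:i * 50 + 300])
                  for i in range(8)]
        pile = build_pile(target, map_short_to_long(shorts, [target]))
        filtered, classifications = phase_filter(pile)
        assert [m.short_id for m in filtered.members] == \
               [m.short_id for m in pile.members]
        assert all(c.label != HAP_SNP for c in classifications)

    def test_out_of_phase_reads_removed(self, rng):
        pile = self._two_hap_pile(rng)
        filtered, classifications = phase_filter(pile)
        kept = {m.short_id for m in filtered.members}
        assert kept == {f"a{i}" for i in range(6)}
        snps = [c for c in classifications if c.label == HAP_SNP]
        assert len(snps) == 1 and snps[0].pos == 600

    def test_reads_agreeing_at_snp_never_removed(self, rng):
        pile = self._two_hap_pile(rng)
        filtered, _ = phase_filter(pile)
        assert all(m.short_id.startswith("a") for m in filtered.members)

    def test_weak_alternative_keeps_everyone(self, rng):
        pile = self._two_hap_pile(rng, n_a=8, n_b=4)  # 4 = below the bar
        filtered, classifications = phase_filter(pile)
        assert len(filtered.members) == 12
        labels = {c.pos: c.label for c in classifications}
        assert labels[600] == NGS_ERROR

    def test_phasing_precision_on_simulated_two_strain_mix(self, two_strain_community):
        # phase filtering operates on de-Bruijn pre-corrected targets (the
        # stage-1 pass exists precisely to make these alignments reliable)
        from haplec.dbg import DbgParams, build_dbg, correct_with_dbg
        truth, long_reads_raw, short_reads, placements = two_strain_community
        dbg = build_dbg(short_reads, 21, 3)
        long_reads = long_reads_raw[:12]
        for _ in range(3):
            long_reads = [correct_with_dbg(r, dbg, DbgParams()) for r in long_reads]
        pls = {p.read_id: p for p in placements}
        alns = map_short_to_long(short_reads, long_reads)
        by = {}
        for a in alns:
            by.setdefault(a.long_id, []).append(a)
        kept_same = kept_total = 0
        for target in long_reads:
            pile = build_pile(target, by.get(target.id, []))
            filtered, _ = phase_filter(pile)
            t_hap = pls[target.id].hap_id
            for m in filtered.members:
                kept_total += 1
                kept_same += pls[m.short_id].hap_id == t_hap
        assert kept_total > 200
        assert kept_same / kept_total >= 0.95
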