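"""Pile construction, column classification and phase filtering.

For one target long read, all short-read alignments form a *pile* indexed
by target coordinates.  Each column where at least one short read
disagrees with the target falls into one of three scenarios, decided
purely from allele support counts (the target itself is never counted):

* the alternative allele is strongly supported while the target base is
  not — the target carries a sequencing error (``TGS_ERROR``);
* both the target base and an alternative are strongly supported — the
  column is a haplotype-specific SNP (``HAP_SNP``): the disagreeing short
  reads come from another strain, not from errors;
* the alternative is weakly supported — the disagreeing short reads carry
  their own sequencing errors (``NGS_ERROR``) and are kept.

"Strong" support means at least ``min_support`` reads (default 5), which
tolerates the occasional short-read error that coincides with a long-read
error.  Phase filtering removes every short read that carries a
strongly-supported alternative allele at one or more ``HAP_SNP`` columns;
what remains is a phase-consistent pile.  Target errors spotted here are
*not* edited in place — they are resolved by the window consensus, which
sees the whole phase-consistent pile at once.

The same support logic is applied to deletion ("gap") observations, so
indel-type strain variants are classified like SNPs; a read whose
alignment shows a gap at a base-SNP column is neither evidence for nor
against the variant and is never removed for that column alone.

In regions where the target still carries clustered indel errors, the
per-read placement of bases around the gaps is not unique and a few
adjacent columns can show strong but artifactual allele splits whose
removal sets jointly cover the whole pile.  Phase filtering stays at full
strength nevertheless — the pipeline handles the fallout at the window
level, by falling back to the unfiltered pile for a window whose
filtered coverage collapses (see the consensus stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from haplec import _kernels as K
from haplec.io_formats import SeqRecord
from haplec.overlap import PileAlignment

MATCH = "MATCH"
TGS_ERROR = "TGS_ERROR"
HAP_SNP = "HAP_SNP"
NGS_ERROR = "NGS_ERROR"

_SYMBOLS = "ACGT-"


@dataclass
class PhasingParams:
    """``min_support``: reads required to call support "strong" (>= 2)."""

    min_support: int = 5

    def __post_init__(self) -> None:
        if self.min_support < 2:
            raise ValueError("min_support must be >= 2")


@dataclass
class ColumnClass:
    """Classification of one pile column.

    ``support`` maps symbol ('A'/'C'/'G'/'T'/'-') to the number of short
    reads showing it; the target read itself is excluded.
    ``corrected_base`` is set for ``TGS_ERROR`` columns ('-' when the
    evidence says the target base is an insertion artifact).
    """

    pos: int
    target_base: str
    support: Dict[str, int]
    label: str
    corrected_base: Optional[str] = None


class AlignmentPile:
    """A target long read plus all short-read alignments onto it."""

    def __init__(self, target: SeqRecord, members: Sequence[PileAlignment]):
        for m in members:
            if m.long_id != target.id:
                raise ValueError(
                    f"alignment of {m.short_id} targets {m.long_id}, "
                    f"not {target.id}"
                )
        self.target = target
        self.members = sorted(members, key=lambda m: (m.long_start, m.short_id))
        self._tcodes = K.encode(target.seq)

    def __len__(self) -> int:
        return len(self.members)

    def _member_arrays(self):
        ms = self.members
        tstart = np.asarray([m.long_start for m in ms], dtype=np.int64)
        opoff = np.zeros(len(ms) + 1, dtype=np.int64)
        np.cumsum([m.op_codes.size for m in ms], out=opoff[1:])
        qoff = np.zeros(len(ms) + 1, dtype=np.int64)
        np.cumsum([m.query_codes.size for m in ms], out=qoff[1:])
        if ms:
            op_codes = np.concatenate([m.op_codes for m in ms])
            op_lens = np.concatenate([m.op_lens for m in ms])
            qflat = np.concatenate([m.query_codes for m in ms])
            # the compiled pile kernels index by these spans unchecked, so
            # enforce ops consistency before handing the arrays over
            lens64 = op_lens.astype(np.int64)
            red = np.minimum(opoff[:-1], max(op_codes.size - 1, 0))
            tspan = np.add.reduceat(np.where(op_codes == 2, 0, lens64), red)
            qspan = np.add.reduceat(np.where(op_codes == 3, 0, lens64), red)
            want_t = np.asarray([m.long_end - m.long_start for m in ms])
            want_q = np.asarray([m.query_codes.size for m in ms])
            empty = opoff[:-1] == opoff[1:]
            tspan[empty] = 0
            qspan[empty] = 0
            if (tspan != want_t).any() or (qspan != want_q).any():
                bad = int(np.flatnonzero((tspan != want_t) | (qspan != want_q))[0])
                raise ValueError(
                    f"alignment of {ms[bad].short_id} on {ms[bad].long_id}: "
                    f"edit operations inconsistent with its coordinates"
                )
        else:
            op_codes = np.empty(0, dtype=np.uint8)
            op_lens = np.empty(0, dtype=np.int32)
            qflat = np.empty(0, dtype=np.uint8)
        return tstart, opoff, op_codes, op_lens, qoff[:-1], qflat

    def counts(self) -> np.ndarray:
        """Per-column support counts, shape (len(target), 6).

        Columns: A, C, G, T, gap, insertion-before-position (the last is
        bookkeeping for artifact-zone detection, not an allele).
        """
        tstart, opoff, op_codes, op_lens, qoff, qflat = self._member_arrays()
        return K.pile_counts(len(self.target.seq), tstart, opoff,
                             op_codes, op_lens, qoff, qflat)

    @cached_property
    def column_index(self) -> Dict[int, List[Tuple[str, str]]]:
        """Explicit per-column observations [(short_id, symbol), ...].

        Convenience view for inspection and small fixtures; the pipeline
        works from :meth:`counts` instead.
        """
        index: Dict[int, List[Tuple[str, str]]] = {
            i: [] for i in range(len(self.target.seq))
        }
        for m in self.members:
            t = m.long_start
            q = 0
            for c, l in zip(m.op_codes, m.op_lens):
                if c <= K.OP_X:
                    for x in range(l):
                        index[t + x].append((m.short_id, _SYMBOLS[m.query_codes[q + x]]))
                    t += l
                    q += l
                elif c == K.OP_I:
                    q += l
                else:
                    for x in range(l):
                        index[t + x].append((m.short_id, "-"))
                    t += l
        return index


def build_pile(target: SeqRecord, alignments: Sequence[PileAlignment]) -> AlignmentPile:
    """Assemble the pile of a target read from its alignments."""
    return AlignmentPile(target, alignments)


def classify_column(target_base: str, support: Dict[str, int],
                    params: Optional[PhasingParams] = None) -> ColumnClass:
    """Classify one column from its support counts (target excluded).

    With ``a`` the count supporting the target base, ``b`` the largest
    alternative count and ``B`` its symbol, the rules are applied in
    order: alternative strong while target weak -> TGS_ERROR (corrected to
    B); both strong -> HAP_SNP; any weak disagreement -> NGS_ERROR;
    no disagreement -> MATCH.  Ties among alternatives prefer the higher
    count, then A < C < G < T < '-'.
    """
    params = params or PhasingParams()
    ms = params.min_support
    a = support.get(target_base, 0)
    best_alt = None
    b = 0
    for sym in _SYMBOLS:
        if sym == target_base:
            continue
        cnt = support.get(sym, 0)
        if cnt > b:
            b = cnt
            best_alt = sym
    if b >= ms and a < ms:
        return ColumnClass(-1, target_base, dict(support), TGS_ERROR, best_alt)
    if a >= ms and b >= ms:
        return ColumnClass(-1, target_base, dict(support), HAP_SNP)
    if b >= 1:
        return ColumnClass(-1, target_base, dict(support), NGS_ERROR)
    return ColumnClass(-1, target_base, dict(support), MATCH)


def _classify_arrays(tcodes: np.ndarray, counts: np.ndarray, min_support: int):
    """Vectorized column classification.

    Returns (labels, alt_code, a, b, filtered_mask) where labels use
    0 MATCH, 1 TGS_ERROR, 2 HAP_SNP, 3 NGS_ERROR; ``filtered_mask[l, s]``
    marks symbol ``s`` as a strongly-supported out-of-phase allele at
    column ``l``.
    """
    L = tcodes.size
    cols = np.arange(L)
    counts = counts[:, :5]
    a = counts[cols, tcodes]
    alt = counts.copy()
    alt[cols, tcodes] = -1
    b = alt.max(axis=1)
    alt_code = alt.argmax(axis=1)  # first max: A<C<G<T<'-' preference
    labels = np.zeros(L, dtype=np.uint8)
    strong_alt = b >= min_support
    labels[strong_alt & (a < min_support)] = 1
    labels[strong_alt & (a >= min_support)] = 2
    labels[~strong_alt & (b >= 1)] = 3
    filtered_mask = (alt >= min_support)
    filtered_mask[labels != 2] = False
    return labels, alt_code, a, b, filtered_mask


def phase_filter(pile: AlignmentPile, params: Optional[PhasingParams] = None
                 ) -> Tuple[AlignmentPile, List[ColumnClass]]:
    """Remove out-of-phase short reads from the pile.

    Every column with at least one disagreeing observation is classified;
    a member is removed when it shows a strongly-supported alternative
    allele at one or more HAP_SNP columns.  Returns the phase-consistent
    pile and the classifications of all non-MATCH columns.
    """
    params = params or PhasingParams()
    kept_idx, labels, alt_code, a_arr, counts = _phase_filter_core(pile, params)
    filtered = AlignmentPile(pile.target, [pile.members[i] for i in kept_idx])
    classifications: List[ColumnClass] = []
    tseq = pile.target.seq
    for pos in np.flatnonzero(labels != 0):
        support = {
            _SYMBOLS[s]: int(counts[pos, s])
            for s in range(5) if counts[pos, s] > 0
        }
        label = (MATCH, TGS_ERROR, HAP_SNP, NGS_ERROR)[labels[pos]]
        corrected = _SYMBOLS[alt_code[pos]] if labels[pos] == 1 else None
        classifications.append(
            ColumnClass(int(pos), tseq[pos], support, label, corrected)
        )
    return filtered, classifications


def classifications_to_tsv(classifications: Sequence[ColumnClass]) -> str:
    """Render column classifications as a debug TSV
    (pos, target_base, counts, label, corrected_base)."""
    lines = ["pos\ttarget_base\tsupport\tlabel\tcorrected_base"]
    for c in classifications:
        support = ",".join(f"{b}:{n}" for b, n in sorted(c.support.items()))
        lines.append(
            f"{c.pos}\t{c.target_base}\t{support}\t{c.label}\t{c.corrected_base or ''}")
    return "\n".join(lines) + "\n"


def _phase_filter_core(pile: AlignmentPile, params: PhasingParams):
    """Array-level phase filter shared by the public op and the pipeline.

    Returns (kept member indices, labels, alt_code, a, counts).
    """
    if not pile.members:
        return [], np.zeros(len(pile.target.seq), dtype=np.uint8), None, None, \
            np.zeros((len(pile.target.seq), 6), dtype=np.int32)
    tstart, opoff, op_codes, op_lens, qoff, qflat = pile._member_arrays()
    counts = K.pile_counts(len(pile.target.seq), tstart, opoff,
                           op_codes, op_lens, qoff, qflat)
    labels, alt_code, a_arr, b_arr, filtered_mask = _classify_arrays(
        pile._tcodes, counts, params.min_support)
    snp_cols = np.flatnonzero(labels == 2)
    if snp_cols.size == 0:
        kept = list(range(len(pile.members)))
        return kept, labels, alt_code, a_arr, counts
    flag_index = np.full(len(pile.target.seq), -1, dtype=np.int64)
    flag_index[snp_cols] = np.arange(snp_cols.size)
    alleles = K.member_alleles(flag_index, snp_cols.size, tstart, opoff,
                               op_codes, op_lens, qoff, qflat)
    fm = filtered_mask[snp_cols]  # (n_snp, 5)
    removed = np.zeros(len(pile.members), dtype=bool)
    for ci in range(snp_cols.size):
        obs = alleles[:, ci]
        seen = obs < 5
        removed |= seen & fm[ci][np.clip(obs, 0, 4)]
    kept = np.flatnonzero(~removed).tolist()
    return kept, labels, alt_code, a_arr, counts
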