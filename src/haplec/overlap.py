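"""Short-to-long read mapping.

A minimizer index of the long reads is queried with the minimizers of each
short read; diagonal-clustered seed hits with enough support are extended
with a banded edit-distance alignment (Myers bit-vector via edlib) and
kept when the edit fraction is acceptable.  A short read may align to many
long reads — in a mixed community the same region legitimately occurs on
several long reads and several haplotypes — but only the best alignment
per (short, long) pair is kept.

Indel placement is normalized by left-shifting gaps within homopolymers so
that pile columns over different short reads are comparable.

Alignments may instead be ingested from a PAF file with cg:Z: tags (see
:func:`alignments_from_paf`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from haplec import _kernels as K
from haplec.io_formats import PafRecord, SeqRecord, reverse_complement

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class MapParams:
    """Minimizer-seeding and extension parameters.

    ``band`` is the half-width (bp) allowed around the seeded diagonal;
    ``max_edit_frac`` rejects alignments with more than that fraction of
    edits per aligned base.  Defaults are tuned for ~250 bp short reads
    against pre-corrected long reads.
    """

    minimizer_k: int = 15
    minimizer_w: int = 10
    min_chain_seeds: int = 3
    band: int = 50
    max_edit_frac: float = 0.30
    max_occ: int = 512  # minimizers seen more often than this are skipped

    def __post_init__(self) -> None:
        if self.minimizer_k > 15:
            raise ValueError("minimizer_k must be <= 15 (2-bit packed)")
        if self.band < 8:
            raise ValueError("band must be >= 8")


@dataclass
class PileAlignment:
    """One short read placed on one long read.

    ``ops`` run in forward long-read coordinates and span exactly
    [long_start, long_end); for reverse-strand hits the stored aligned
    query (``query_codes``) is the reverse complement of the short read,
    so ops always read forward on both sequences.
    """

    short_id: str
    long_id: str
    long_start: int
    long_end: int
    strand: str
    n_edits: int
    op_codes: np.ndarray  # uint8, 0 '=' 1 'X' 2 'I' 3 'D'
    op_lens: np.ndarray   # int32
    query_codes: np.ndarray  # uint8 codes of the oriented aligned query part
    query_start: int = 0  # offset of the aligned part on the oriented read

    @property
    def ops(self) -> List[Tuple[str, int]]:
        return [(K._OP_CHARS[c], int(l)) for c, l in zip(self.op_codes, self.op_lens)]

    @property
    def query_seq(self) -> str:
        return K.decode(self.query_codes)

    def validate(self) -> None:
        tspan, qspan, edits = K.ops_spans(self.op_codes, self.op_lens)
        if tspan != self.long_end - self.long_start:
            raise ValueError(
                f"{self.short_id}->{self.long_id}: ops span {tspan} != "
                f"interval {self.long_end - self.long_start}"
            )
        if qspan != self.query_codes.size:
            raise ValueError(
                f"{self.short_id}->{self.long_id}: ops consume {qspan} query "
                f"bases of {self.query_codes.size}"
            )
        if edits != self.n_edits:
            raise ValueError(
                f"{self.short_id}->{self.long_id}: n_edits {self.n_edits} != "
                f"ops edits {edits}"
            )


def _parse_cigar(cigar: str, qcodes: np.ndarray, tcodes: np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """CIGAR string -> op arrays; 'M' runs are resolved into '='/'X' by
    comparing the sequences."""
    codes: List[int] = []
    lens: List[int] = []
    q = 0
    t = 0
    for num, op in _CIG_RE.findall(cigar):
        n = int(num)
        if op == "M":
            for i in range(n):
                c = K.OP_EQ if qcodes[q + i] == tcodes[t + i] else K.OP_X
                if codes and codes[-1] == c:
                    lens[-1] += 1
                else:
                    codes.append(c)
                    lens.append(1)
            q += n
            t += n
            continue
        c = K._OP_CODE[op]
        if codes and codes[-1] == c:
            lens[-1] += n
        else:
            codes.append(c)
            lens.append(n)
        if c in (K.OP_EQ, K.OP_X):
            q += n
            t += n
        elif c == K.OP_I:
            q += n
        else:
            t += n
    return np.asarray(codes, dtype=np.uint8), np.asarray(lens, dtype=np.int32)


def normalize_indels(op_codes: np.ndarray, op_lens: np.ndarray,
                     qcodes: np.ndarray, tcodes: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Left-shift gaps within homopolymers (canonical indel placement)."""
    if not (op_codes == K.OP_I).any() and not (op_codes == K.OP_D).any():
        return op_codes, op_lens
    cols = K.expand_ops(op_codes, op_lens)
    cols = K.left_shift_gaps(cols, qcodes, tcodes)
    return K.compress_ops(cols)


def banded_align(query: str, target: str, band: int = 50
                 ) -> Optional[Tuple[List[Tuple[str, int]], int]]:
    """Global banded edit-distance alignment with a deterministic edit script.

    Dynamic programming restricted to |i - j| <= band; returns (ops,
    n_edits) or None when no alignment stays within the band (in
    particular when the length difference alone exceeds it).  Ties prefer
    match > mismatch > deletion-from-target > insertion.
    """
    q = K.encode(query)
    t = K.encode(target)
    n, m = len(q), len(t)
    if abs(n - m) > band:
        return None
    BIG = 1 << 30
    # D[i][j]: edits aligning q[:i] to t[:j]; band on j - i
    width = 2 * band + 1
    D = np.full((n + 1, width), BIG, dtype=np.int64)

    def col(i: int, j: int) -> int:
        return j - i + band

    D[0, col(0, 0)] = 0
    for j in range(1, min(m, band) + 1):
        D[0, col(0, j)] = j
    for i in range(1, n + 1):
        jlo = max(0, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            c = col(i, j)
            best = BIG
            if j > 0 and c - 1 >= 0:
                sub = D[i - 1, c] + (0 if q[i - 1] == t[j - 1] else 1)
                best = min(best, sub)
            if c + 1 < width:  # deletion from target: consume t[j-1]... (gap in q)
                pass
            # insertion of q[i-1] (consume query only): j same
            ins = D[i - 1, c + 1] + 1 if c + 1 < width else BIG
            # deletion (consume target only): from D[i, j-1]
            dele = D[i, c - 1] + 1 if j > 0 and c - 1 >= 0 else BIG
            best = min(best, ins, dele)
            D[i, c] = best
    dist = int(D[n, col(n, m)])
    if dist >= BIG:
        return None
    # traceback with the stated preference order
    ops: List[Tuple[str, int]] = []
    i, j = n, m

    def push(op: str) -> None:
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))

    while i > 0 or j > 0:
        c = col(i, j)
        here = D[i, c]
        if i > 0 and j > 0 and q[i - 1] == t[j - 1] and D[i - 1, c] == here:
            push("=")
            i -= 1
            j -= 1
            continue
        if i > 0 and j > 0 and D[i - 1, c] + 1 == here and q[i - 1] != t[j - 1]:
            push("X")
            i -= 1
            j -= 1
            continue
        if j > 0 and c - 1 >= 0 and D[i, c - 1] + 1 == here:
            push("D")
            j -= 1
            continue
        if i > 0 and c + 1 < width and D[i - 1, c + 1] + 1 == here:
            push("I")
            i -= 1
            continue
        raise AssertionError("banded_align traceback failed")
    ops.reverse()
    return ops, dist


class _MinimizerIndex:
    """Sorted-array minimizer index over a set of target sequences."""

    def __init__(self, targets: Sequence[SeqRecord], k: int, w: int) -> None:
        self.k = k
        self.w = w
        self.targets = targets
        self.encoded = [K.encode(t.seq) for t in targets]
        self.seqs = [t.seq for t in targets]
        all_codes = []
        all_packed = []
        for ti, codes in enumerate(self.encoded):
            if codes.size < k:
                continue
            pos, code, strand = K.minimizers(codes, k, w)
            packed = (np.int64(ti) << 33) | (pos.astype(np.int64) << 1) | strand
            all_codes.append(code)
            all_packed.append(packed)
        if all_codes:
            codes = np.concatenate(all_codes)
            packed = np.concatenate(all_packed)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.packed = packed[order]
        else:
            self.codes = np.empty(0, dtype=np.int64)
            self.packed = np.empty(0, dtype=np.int64)

    def lookup(self, code_arr: np.ndarray, max_occ: int
               ) -> Tuple[np.ndarray, np.ndarray]:
        """For each query code, matching packed entries (concatenated) and
        the query index each match came from."""
        left = np.searchsorted(self.codes, code_arr, side="left")
        right = np.searchsorted(self.codes, code_arr, side="right")
        n_hits = right - left
        keep = (n_hits > 0) & (n_hits <= max_occ)
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        chunks = [self.packed[left[i]:right[i]] for i in idx]
        qidx = np.repeat(idx, n_hits[idx])
        return np.concatenate(chunks), qidx


def _extend_candidate(q_str: str, qcodes: np.ndarray,
                      t_str: str, tcodes: np.ndarray, tstart_est: int,
                      params: MapParams) -> Optional[Tuple[int, int, int, np.ndarray, np.ndarray, np.ndarray]]:
    """Banded extension of one seeded candidate (oriented query given).

    Returns (long_start, long_end, n_edits, op_codes, op_lens, oriented
    query codes), or None on rejection.
    """
    full_len = qcodes.size
    # clip the query where it overhangs the target ends: the remaining part
    # must fit inside the target for the infix alignment to be meaningful
    q_lo = max(0, -tstart_est)
    q_hi = full_len - max(0, tstart_est + full_len - tcodes.size)
    if q_hi - q_lo < 30:
        return None
    qc = qcodes[q_lo:q_hi]
    qlen = qc.size
    tstart_est = tstart_est + q_lo
    pad = params.band
    lo = max(0, tstart_est - pad)
    hi = min(tcodes.size, tstart_est + qlen + pad)
    if hi - lo < qlen - pad:
        return None
    k_lim = max(8, int(round(params.max_edit_frac * qlen)))
    res = edlib.align(q_str[q_lo:q_hi], t_str[lo:hi], mode="HW", task="path", k=k_lim)
    if res["editDistance"] < 0:
        return None
    t0, t1 = res["locations"][0]
    t1 += 1  # edlib end is inclusive
    cig = np.frombuffer(res["cigar"].encode("ascii"), dtype=np.uint8)
    op_codes, op_lens, edits = K.parse_cigar_normalize(
        cig, qc, tcodes[lo + t0:lo + t1])
    return lo + t0, lo + t1, int(edits), op_codes, op_lens, qc, q_lo


def map_short_to_long(short_reads: Sequence[SeqRecord],
                      long_reads: Sequence[SeqRecord],
                      params: Optional[MapParams] = None,
                      index: Optional[_MinimizerIndex] = None,
                      ) -> List[PileAlignment]:
    """Map every short read onto the long reads.

    Minimizer seeds are clustered by diagonal per (long read, strand);
    clusters with at least ``min_chain_seeds`` colinear seeds are extended
    by banded alignment.  Only the best alignment per (short, long) pair
    is kept; reverse-strand hits are reported on the forward long-read
    frame with the short read reverse-complemented.
    """
    if not short_reads or not long_reads:
        raise ValueError("read sets must be non-empty")
    params = params or MapParams()
    if index is None:
        index = _MinimizerIndex(long_reads, params.minimizer_k, params.minimizer_w)
    k = params.minimizer_k
    out: List[PileAlignment] = []
    for sr in short_reads:
        qcodes = K.encode(sr.seq)
        if qcodes.size < k:
            continue
        qpos, qcode, qstrand = K.minimizers(qcodes, k, params.minimizer_w)
        if qpos.size == 0:
            continue
        packed, qidx = index.lookup(qcode, params.max_occ)
        if packed.size == 0:
            continue
        tidx = packed >> 33
        tpos = (packed >> 1) & ((1 << 32) - 1)
        tstrand = packed & 1
        rel = (tstrand ^ qstrand[qidx]).astype(np.int64)
        qp = qpos[qidx].astype(np.int64)
        diag = np.where(rel == 0, tpos - qp, tpos + qp)
        cti, crl, cns, cmed = K.cluster_seed_hits(
            tidx, rel, diag, qp, params.band, params.min_chain_seeds)
        if cti.size == 0:
            continue
        qlen = qcodes.size
        q_fwd = sr.seq
        qcodes_rev = None
        q_rev = None
        best_per_pair: Dict[int, Tuple[int, PileAlignment]] = {}
        for ci in range(cti.size):
            ti = int(cti[ci])
            rl = int(crl[ci])
            med = int(cmed[ci])
            tstart_est = med if rl == 0 else med - qlen + k
            if rl:
                if qcodes_rev is None:
                    qcodes_rev = K.revcomp_codes(qcodes)
                    q_rev = reverse_complement(sr.seq)
                qs, qc = q_rev, qcodes_rev
            else:
                qs, qc = q_fwd, qcodes
            ext = _extend_candidate(qs, qc, index.seqs[ti], index.encoded[ti],
                                    tstart_est, params)
            if ext is None:
                continue
            t0, t1, ed, opc, opl, qcc, q_lo = ext
            old = best_per_pair.get(ti)
            if old is None or ed < old[0]:
                best_per_pair[ti] = (ed, PileAlignment(
                    short_id=sr.id,
                    long_id=long_reads[ti].id,
                    long_start=t0,
                    long_end=t1,
                    strand="-" if rl else "+",
                    n_edits=ed,
                    op_codes=opc,
                    op_lens=opl,
                    query_codes=qcc,
                    query_start=q_lo,
                ))
        out.extend(aln for _, aln in best_per_pair.values())
    return out


def alignments_from_paf(paf_records: Sequence[PafRecord],
                        short_reads: Sequence[SeqRecord],
                        long_reads: Sequence[SeqRecord]) -> List[PileAlignment]:
    """Convert PAF records (cg:Z: tags required) into pile alignments.

    The cg CIGAR is used verbatim apart from resolving 'M' runs into
    '='/'X' and normalizing indel placement.  Query-end clipping implied
    by query_start/query_end is honoured.
    """
    shorts = {r.id: r for r in short_reads}
    longs = {r.id: r for r in long_reads}
    out: List[PileAlignment] = []
    for rec in paf_records:
        if rec.cg is None:
            raise ValueError(
                f"PAF record {rec.query_id}->{rec.target_id} lacks a cg:Z: tag"
            )
        sr = shorts.get(rec.query_id)
        lr = longs.get(rec.target_id)
        if sr is None or lr is None:
            continue
        tcodes = K.encode(lr.seq)[rec.target_start:rec.target_end]
        if rec.strand == "+":
            qc = K.encode(sr.seq)[rec.query_start:rec.query_end]
            q_start = rec.query_start
        else:
            # PAF query coordinates are on the forward query; the aligned
            # segment on the target-forward frame is the reverse complement
            qc = K.revcomp_codes(K.encode(sr.seq))[
                len(sr.seq) - rec.query_end: len(sr.seq) - rec.query_start]
            q_start = len(sr.seq) - rec.query_end
        cg_span_t = sum(int(n) for n, op in _CIG_RE.findall(rec.cg) if op in "=XMD")
        cg_span_q = sum(int(n) for n, op in _CIG_RE.findall(rec.cg) if op in "=XMI")
        if cg_span_t != rec.target_end - rec.target_start or cg_span_q != qc.size:
            raise ValueError(
                f"PAF cg tag of {rec.query_id}->{rec.target_id} is inconsistent "
                f"with its coordinates"
            )
        cig = np.frombuffer(rec.cg.encode("ascii"), dtype=np.uint8)
        op_codes, op_lens, edits = K.parse_cigar_normalize(cig, qc, tcodes)
        out.append(PileAlignment(
            short_id=rec.query_id,
            long_id=rec.target_id,
            long_start=rec.target_start,
            long_end=rec.target_end,
            strand=rec.strand,
            n_edits=edits,
            op_codes=op_codes,
            op_lens=op_lens,
            query_codes=qc,
            query_start=q_start,
        ))
    return out


def alignments_to_paf(alignments: Sequence[PileAlignment],
                      short_lens: Dict[str, int],
                      long_lens: Dict[str, int]) -> List[PafRecord]:
    """Render internal alignments as PAF records with cg:Z: tags."""
    out = []
    for a in alignments:
        tspan, qspan, edits = K.ops_spans(a.op_codes, a.op_lens)
        qlen = short_lens[a.short_id]
        cg = "".join(f"{l}{K._OP_CHARS[c]}" for c, l in zip(a.op_codes, a.op_lens))
        n_match = sum(int(l) for c, l in zip(a.op_codes, a.op_lens) if c == K.OP_EQ)
        aln_len = sum(int(l) for l in a.op_lens)
        if a.strand == "+":
            qs, qe = a.query_start, a.query_start + qspan
        else:
            qs, qe = qlen - a.query_start - qspan, qlen - a.query_start
        out.append(PafRecord(
            query_id=a.short_id, query_len=qlen, query_start=qs, query_end=qe,
            strand=a.strand, target_id=a.long_id, target_len=long_lens[a.long_id],
            target_start=a.long_start, target_end=a.long_end,
            n_matches=n_match, aln_len=aln_len, mapq=60, cg=cg,
        ))
    return out
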