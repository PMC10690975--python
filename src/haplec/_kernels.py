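"""Compiled numeric kernels.

Sequences are handled as ``uint8`` code arrays (A=0, C=1, G=2, T=3, N/other=4);
alignment edit operations as parallel ``(op_code, length)`` arrays with
op codes 0 '=' match, 1 'X' mismatch, 2 'I' insertion (consumes query only),
3 'D' deletion (consumes target only).  Pile columns use symbol 4 for a gap
observation and 5 for "no observation".

Everything here is deterministic: no randomness, no threading, no
order-dependent floating point.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.typed import Dict
from numba.core import types

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGT-", dtype=np.uint8)

OP_EQ, OP_X, OP_I, OP_D = 0, 1, 2, 3
_OP_CHARS = "=XID"
_OP_CODE = {c: i for i, c in enumerate(_OP_CHARS)}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a code array back to a string (4 -> '-')."""
    return _DEC[codes].tobytes().decode("ascii")


@njit(cache=True)
def revcomp_codes(codes):
    n = codes.size
    out = np.empty(n, dtype=np.uint8)
    for i in range(n):
        b = codes[n - 1 - i]
        out[i] = 3 - b if b < 4 else 4
    return out


# ---------------------------------------------------------------------------
# k-mer machinery
# ---------------------------------------------------------------------------


@njit(cache=True)
def kmer_codes(codes, k):
    """Forward / reverse-complement 2-bit codes of every k-mer.

    Returns (fwd, rc, valid); k-mers containing non-ACGT bases are invalid.
    """
    n = codes.size
    m = n - k + 1
    if m < 0:
        m = 0
    fwd = np.zeros(m, dtype=np.int64)
    rc = np.zeros(m, dtype=np.int64)
    valid = np.zeros(m, dtype=np.bool_)
    if m == 0:
        return fwd, rc, valid
    mask = (np.int64(1) << np.int64(2 * k)) - np.int64(1)
    shift = np.int64(2 * (k - 1))
    f = np.int64(0)
    r = np.int64(0)
    run = 0
    for i in range(n):
        b = codes[i]
        if b > 3:
            run = 0
            f = np.int64(0)
            r = np.int64(0)
        else:
            f = ((f << np.int64(2)) | np.int64(b)) & mask
            r = (r >> np.int64(2)) | (np.int64(3 - b) << shift)
            run += 1
        j = i - k + 1
        if j >= 0 and run >= k:
            fwd[j] = f
            rc[j] = r
            valid[j] = True
    return fwd, rc, valid


@njit(cache=True, inline="always")
def _mix64(x):
    # invertible scramble so that low-complexity k-mers do not dominate
    # minimizer selection
    h = (x + np.int64(0x9E3779B9)) * np.int64(-7046029254386353131)
    h = h ^ ((h >> np.int64(31)) & np.int64(0x1FFFFFFFF))
    h = h * np.int64(-4417276706812531889)
    return h & np.int64(0x7FFFFFFFFFFFFFFF)


@njit(cache=True)
def minimizers(codes, k, w):
    """(w,k)-minimizers of a sequence on canonical k-mer codes.

    Returns (pos, code, strand): k-mer start positions, canonical codes and
    a flag that is 1 when the canonical code is the reverse complement of
    the forward k-mer.
    """
    fwd, rc, valid = kmer_codes(codes, k)
    m = fwd.size
    pos = np.empty(m, dtype=np.int32)
    code = np.empty(m, dtype=np.int64)
    strand = np.empty(m, dtype=np.uint8)
    if m == 0:
        return pos[:0], code[:0], strand[:0]
    can = np.empty(m, dtype=np.int64)
    st = np.empty(m, dtype=np.uint8)
    h = np.empty(m, dtype=np.int64)
    BIG = np.int64(0x7FFFFFFFFFFFFFFF)
    for i in range(m):
        if valid[i]:
            if fwd[i] <= rc[i]:
                can[i] = fwd[i]
                st[i] = 0
            else:
                can[i] = rc[i]
                st[i] = 1
            h[i] = _mix64(can[i])
        else:
            can[i] = -1
            h[i] = BIG
    nw = m - w + 1
    cnt = 0
    last = -1
    if nw < 1:
        # sequence shorter than one full window: take the single best k-mer
        best = 0
        for i in range(1, m):
            if h[i] < h[best]:
                best = i
        if can[best] >= 0:
            pos[0] = best
            code[0] = can[best]
            strand[0] = st[best]
            cnt = 1
    else:
        for s in range(nw):
            best = s
            for t in range(s + 1, s + w):
                if h[t] < h[best]:
                    best = t
            if best != last and can[best] >= 0:
                pos[cnt] = best
                code[cnt] = can[best]
                strand[cnt] = st[best]
                cnt += 1
                last = best
    return pos[:cnt].copy(), code[:cnt].copy(), strand[:cnt].copy()


# ---------------------------------------------------------------------------
# de Bruijn graph: counting and path search
# ---------------------------------------------------------------------------


@njit(cache=True)
def count_kmers(flat, offsets, k):
    """Canonical k-mer counts over a set of reads packed into one array."""
    d = Dict.empty(types.int64, types.int64)
    for ri in range(offsets.size - 1):
        seg = flat[offsets[ri]:offsets[ri + 1]]
        fwd, rc, valid = kmer_codes(seg, k)
        for i in range(fwd.size):
            if valid[i]:
                c = fwd[i] if fwd[i] <= rc[i] else rc[i]
                if c in d:
                    d[c] += 1
                else:
                    d[c] = 1
    return d


@njit(cache=True)
def solid_flags(codes, k, counts, t_solid):
    """Per-k-mer flag: canonical count in the index >= t_solid."""
    fwd, rc, valid = kmer_codes(codes, k)
    out = np.zeros(fwd.size, dtype=np.bool_)
    for i in range(fwd.size):
        if valid[i]:
            c = fwd[i] if fwd[i] <= rc[i] else rc[i]
            if c in counts and counts[c] >= t_solid:
                out[i] = True
    return out


@njit(cache=True)
def dbg_enumerate_paths(src_fwd, src_rc, dst_fwd, k, counts, t_solid,
                        dmin, dmax, max_branch, max_paths):
    """Enumerate solid paths from src k-mer to dst k-mer in the implicit DBG.

    A path is admissible if it reaches dst after d extension steps with
    dmin <= d <= dmax and every intermediate k-mer is solid.  Collects up
    to ``max_paths`` admissible paths; returns (n_found, paths_flat,
    path_lens) where n_found exceeds ``max_paths`` (or the search aborted
    on the expansion budget) when the gap is too ambiguous to use.
    """
    mask = (np.int64(1) << np.int64(2 * k)) - np.int64(1)
    shift = np.int64(2 * (k - 1))
    cap = dmax + 1
    st_fwd = np.zeros(cap, dtype=np.int64)
    st_rc = np.zeros(cap, dtype=np.int64)
    tried = np.zeros(cap, dtype=np.int8)
    bases = np.zeros(cap, dtype=np.uint8)
    paths = np.zeros(max_paths * dmax, dtype=np.uint8)
    lens = np.zeros(max_paths, dtype=np.int64)
    found = 0
    st_fwd[0] = src_fwd
    st_rc[0] = src_rc
    depth = 0
    expansions = 0
    while depth >= 0:
        if tried[depth] >= 4:
            depth -= 1
            continue
        b = tried[depth]
        tried[depth] += 1
        nf = ((st_fwd[depth] << np.int64(2)) | np.int64(b)) & mask
        nr = (st_rc[depth] >> np.int64(2)) | (np.int64(3 - b) << shift)
        c = nf if nf <= nr else nr
        if not (c in counts and counts[c] >= t_solid):
            continue
        expansions += 1
        if expansions > max_branch:
            return max_paths + 1, paths, lens
        nd = depth + 1
        bases[depth] = b
        if nf == dst_fwd and nd >= dmin:
            if found < max_paths:
                for i in range(nd):
                    paths[found * dmax + i] = bases[i]
                lens[found] = nd
            found += 1
            if found > max_paths:
                return found, paths, lens
            continue
        if nd < dmax:
            depth = nd
            st_fwd[nd] = nf
            st_rc[nd] = nr
            tried[nd] = 0
    return found, paths, lens


# ---------------------------------------------------------------------------
# alignment-op utilities
# ---------------------------------------------------------------------------


@njit(cache=True)
def ops_spans(op_codes, op_lens):
    """(target_span, query_span, n_edits) of an op run list."""
    t = 0
    q = 0
    e = 0
    for i in range(op_codes.size):
        l = op_lens[i]
        c = op_codes[i]
        if c == 0:
            t += l
            q += l
        elif c == 1:
            t += l
            q += l
            e += l
        elif c == 2:
            q += l
            e += l
        else:
            t += l
            e += l
    return t, q, e


@njit(cache=True)
def expand_ops(op_codes, op_lens):
    n = 0
    for i in range(op_lens.size):
        n += op_lens[i]
    out = np.empty(n, dtype=np.uint8)
    p = 0
    for i in range(op_codes.size):
        for _ in range(op_lens[i]):
            out[p] = op_codes[i]
            p += 1
    return out


@njit(cache=True)
def compress_ops(cols):
    n = cols.size
    codes = np.empty(n, dtype=np.uint8)
    lens = np.empty(n, dtype=np.int32)
    cnt = 0
    i = 0
    while i < n:
        j = i + 1
        while j < n and cols[j] == cols[i]:
            j += 1
        codes[cnt] = cols[i]
        lens[cnt] = j - i
        cnt += 1
        i = j
    return codes[:cnt].copy(), lens[:cnt].copy()


@njit(cache=True)
def left_shift_gaps(cols, qcodes, tcodes):
    """Left-align indels within homopolymers on expanded alignment columns.

    ``cols`` holds one op code per alignment column; ``qcodes``/``tcodes``
    are the aligned query and target sub-sequences.  The alignment is
    rewritten as per-column symbol pairs (4 = gap): a deletion column may
    bubble left past a match/mismatch when the two target bases are equal,
    an insertion column when the two query bases are equal, and deletions
    pass insertions unconditionally (canonical order: D before I).  The
    consumed base order and the edit count are unchanged.  Returns the new
    column op codes.
    """
    n = cols.size
    qs = np.empty(n, dtype=np.uint8)
    ts = np.empty(n, dtype=np.uint8)
    t = 0
    q = 0
    for i in range(n):
        c = cols[i]
        if c <= 1:
            qs[i] = qcodes[q]
            ts[i] = tcodes[t]
            t += 1
            q += 1
        elif c == 2:
            qs[i] = qcodes[q]
            ts[i] = 4
            q += 1
        else:
            qs[i] = 4
            ts[i] = tcodes[t]
            t += 1
    for i in range(1, n):
        is_del = qs[i] == 4
        is_ins = ts[i] == 4 and qs[i] != 4
        if not (is_del or is_ins):
            continue
        p = i
        while p > 0:
            pq = qs[p - 1]
            pt = ts[p - 1]
            if is_del:
                if pq == 4:
                    break  # reached another deletion: runs merge
                if pt == 4:
                    # D passes I: swap both symbol streams
                    qs[p - 1], qs[p] = qs[p], qs[p - 1]
                    ts[p - 1], ts[p] = ts[p], ts[p - 1]
                elif pt == ts[p]:
                    qs[p - 1], qs[p] = qs[p], qs[p - 1]
                else:
                    break
            else:
                if pt == 4 or pq == 4:
                    break
                if pq == qs[p]:
                    ts[p - 1], ts[p] = ts[p], ts[p - 1]
                else:
                    break
            p -= 1
    out = np.empty(n, dtype=np.uint8)
    for i in range(n):
        if qs[i] == 4:
            out[i] = 3
        elif ts[i] == 4:
            out[i] = 2
        elif qs[i] == ts[i]:
            out[i] = 0
        else:
            out[i] = 1
    return out


# ---------------------------------------------------------------------------
# pile kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def pile_counts(target_len, m_tstart, m_opoff, op_codes, op_lens,
                m_qoff, qcodes_flat):
    """Per-column support counts over a pile of alignments.

    Columns 0-3 count A/C/G/T observations, column 4 gap (deletion)
    observations, column 5 reads with an insertion immediately before the
    target position (not an allele — used to spot indel-artifact zones).
    """
    counts = np.zeros((target_len, 6), dtype=np.int32)
    for mi in range(m_tstart.size):
        t = m_tstart[mi]
        q = m_qoff[mi]
        for oi in range(m_opoff[mi], m_opoff[mi + 1]):
            c = op_codes[oi]
            l = op_lens[oi]
            if c <= 1:
                for x in range(l):
                    b = qcodes_flat[q + x]
                    if b < 4:
                        counts[t + x, b] += 1
                t += l
                q += l
            elif c == 2:
                q += l
                if t < target_len:
                    counts[t, 5] += 1
            else:
                for x in range(l):
                    counts[t + x, 4] += 1
                t += l
    return counts


@njit(cache=True)
def member_alleles(flag_index, n_flag, m_tstart, m_opoff, op_codes, op_lens,
                   m_qoff, qcodes_flat):
    """Observed symbol of every member at flagged columns (5 = not covered).

    ``flag_index`` maps target position -> flagged-column ordinal or -1.
    """
    n = m_tstart.size
    out = np.full((n, n_flag), 5, dtype=np.int8)
    for mi in range(n):
        t = m_tstart[mi]
        q = m_qoff[mi]
        for oi in range(m_opoff[mi], m_opoff[mi + 1]):
            c = op_codes[oi]
            l = op_lens[oi]
            if c <= 1:
                for x in range(l):
                    fi = flag_index[t + x]
                    if fi >= 0:
                        b = qcodes_flat[q + x]
                        out[mi, fi] = b if b < 4 else 5
                t += l
                q += l
            elif c == 2:
                q += l
            else:
                for x in range(l):
                    fi = flag_index[t + x]
                    if fi >= 0:
                        out[mi, fi] = 4
                t += l
    return out


@njit(cache=True)
def window_slices(window_len, target_len, m_tstart, m_opoff, op_codes, op_lens):
    """Slice each member's aligned query at window boundaries.

    Returns flat arrays (member, window, q_lo, q_hi, col0) where q_lo/q_hi
    are offsets into the member's own aligned query sequence and col0 is the
    segment's start column within its window.
    """
    n = m_tstart.size
    total = 0
    for mi in range(n):
        tspan = 0
        for oi in range(m_opoff[mi], m_opoff[mi + 1]):
            if op_codes[oi] != 2:
                tspan += op_lens[oi]
        tstart = m_tstart[mi]
        tend = tstart + tspan
        # one slice per window boundary crossed (a boundary at tend itself
        # still triggers an emission, except at the very end of the target)
        cross = tend // window_len - tstart // window_len
        if cross > 0 and tend == target_len and target_len % window_len == 0:
            cross -= 1
        total += cross + 1
    out_member = np.empty(total, dtype=np.int32)
    out_win = np.empty(total, dtype=np.int32)
    out_qlo = np.empty(total, dtype=np.int32)
    out_qhi = np.empty(total, dtype=np.int32)
    out_col0 = np.empty(total, dtype=np.int32)
    r = 0
    for mi in range(n):
        t = m_tstart[mi]
        q = 0
        w = t // window_len
        wend = (w + 1) * window_len
        if wend > target_len:
            wend = target_len
        seg_qlo = 0
        seg_tlo = t
        for oi in range(m_opoff[mi], m_opoff[mi + 1]):
            c = op_codes[oi]
            l = op_lens[oi]
            if c == 2:
                q += l
                continue
            consumes_q = c <= 1
            while l > 0:
                room = wend - t
                step = l if l < room else room
                t += step
                if consumes_q:
                    q += step
                l -= step
                if t == wend and t < target_len:
                    out_member[r] = mi
                    out_win[r] = w
                    out_qlo[r] = seg_qlo
                    out_qhi[r] = q
                    out_col0[r] = seg_tlo - w * window_len
                    r += 1
                    w += 1
                    wend = (w + 1) * window_len
                    if wend > target_len:
                        wend = target_len
                    seg_qlo = q
                    seg_tlo = t
        out_member[r] = mi
        out_win[r] = w
        out_qlo[r] = seg_qlo
        out_qhi[r] = q
        out_col0[r] = seg_tlo - w * window_len
        r += 1
    return out_member[:r], out_win[:r], out_qlo[:r], out_qhi[:r], out_col0[:r]


# ---------------------------------------------------------------------------
# partial order alignment
# ---------------------------------------------------------------------------

_NEG = -1_000_000_000


@njit(cache=True)
def _poa_topo(n_nodes, eu, ev, n_edges):
    indeg = np.zeros(n_nodes, dtype=np.int32)
    succ_off = np.zeros(n_nodes + 1, dtype=np.int32)
    for e in range(n_edges):
        indeg[ev[e]] += 1
        succ_off[eu[e] + 1] += 1
    for i in range(n_nodes):
        succ_off[i + 1] += succ_off[i]
    succ = np.empty(n_edges, dtype=np.int32)
    ptr = succ_off[:-1].copy()
    for e in range(n_edges):
        succ[ptr[eu[e]]] = ev[e]
        ptr[eu[e]] += 1
    order = np.empty(n_nodes, dtype=np.int32)
    head = 0
    tail = 0
    deg = indeg.copy()
    for v in range(n_nodes):
        if deg[v] == 0:
            order[tail] = v
            tail += 1
    while head < tail:
        u = order[head]
        head += 1
        for si in range(succ_off[u], succ_off[u + 1]):
            v = succ[si]
            deg[v] -= 1
            if deg[v] == 0:
                order[tail] = v
                tail += 1
    return order


@njit(cache=True)
def _poa_preds(n_nodes, eu, ev, n_edges):
    poff = np.zeros(n_nodes + 1, dtype=np.int32)
    for e in range(n_edges):
        poff[ev[e] + 1] += 1
    for i in range(n_nodes):
        poff[i + 1] += poff[i]
    plist = np.empty(n_edges, dtype=np.int32)
    ptr = poff[:-1].copy()
    for e in range(n_edges):
        plist[ptr[ev[e]]] = eu[e]
        ptr[ev[e]] += 1
    return poff, plist


@njit(cache=True)
def _poa_dp(base, col, poff, plist, order, n_nodes, q, col0,
            match, mismatch, gap, band, H, ptyp, pnod, outdeg, jmin_end):
    """Banded semi-global DP of one segment against the graph.

    ``jmin_end`` bounds the ends-free rule: an alignment may stop at a
    graph sink with the segment tail unaligned only for j >= jmin_end
    (the tail must not exceed the segment's genuine overhang past the
    graph).  Returns (best_v, best_j, best_s); best_v < 0 when the band
    never reached an admissible end state.
    """
    m = q.size
    lo = np.empty(n_nodes, dtype=np.int32)
    hi = np.empty(n_nodes, dtype=np.int32)
    for v in range(n_nodes):
        c = col[v] - col0 + 1  # expected segment position matching node v
        l = c - band
        if l < 0:
            l = 0
        h = c + band
        if h > m:
            h = m
        lo[v] = l
        hi[v] = h
        if l <= h:
            for jc in range(h - l + 1):
                H[v, jc] = _NEG
                ptyp[v, jc] = 0
    Hv = np.empty(m + 1, dtype=np.int32)
    for j in range(m + 1):
        Hv[j] = gap * j
    for idx in range(n_nodes):
        v = order[idx]
        if lo[v] > hi[v]:
            continue
        if lo[v] == 0:
            H[v, 0] = 0
            ptyp[v, 0] = 0
        jstart = lo[v] if lo[v] > 0 else 1
        for j in range(jstart, hi[v] + 1):
            jc = j - lo[v]
            best = _NEG
            bt = np.uint8(0)
            bn = -1
            if j - 1 >= lo[v]:
                h_ins = H[v, jc - 1]
                if h_ins > _NEG:
                    best = h_ins + gap
                    bt = np.uint8(3)
                    bn = v
            s = match if base[v] == q[j - 1] else mismatch
            npred = poff[v + 1] - poff[v]
            if npred == 0:
                d = Hv[j - 1] + s
                if d > best:
                    best = d
                    bt = np.uint8(1)
                    bn = n_nodes  # virtual row sentinel
            else:
                for pi in range(poff[v], poff[v + 1]):
                    p = plist[pi]
                    if lo[p] <= j - 1 <= hi[p]:
                        hp = H[p, j - 1 - lo[p]]
                        if hp > _NEG:
                            d = hp + s
                            if d > best:
                                best = d
                                bt = np.uint8(1)
                                bn = p
                    if lo[p] <= j <= hi[p]:
                        hp = H[p, j - lo[p]]
                        if hp > _NEG:
                            d = hp + gap
                            if d > best:
                                best = d
                                bt = np.uint8(2)
                                bn = p
            H[v, jc] = best
            ptyp[v, jc] = bt
            pnod[v, jc] = bn
    best_v = -1
    best_j = m
    best_s = _NEG
    for idx in range(n_nodes):
        v = order[idx]
        if lo[v] <= m <= hi[v]:
            s = H[v, m - lo[v]]
            if s > best_s:
                best_s = s
                best_v = v
                best_j = m
        if outdeg[v] == 0:
            jfrom = lo[v] if lo[v] > jmin_end else jmin_end
            if jfrom < 1:
                jfrom = 1
            for j in range(jfrom, hi[v] + 1):
                if j >= m:
                    break  # j == m handled above
                s = H[v, j - lo[v]]
                if s > best_s:
                    best_s = s
                    best_v = v
                    best_j = j
    return best_v, best_j, best_s, lo, hi


@njit(cache=True)
def poa_add_segment(base, ring, col, eu, ev, ew, out_head, out_next,
                    n_nodes, n_edges, q, col0,
                    match, mismatch, gap, band,
                    H, ptyp, pnod):
    """Align one segment to the graph and thread it in.

    The dynamic program is semi-global (leading/trailing graph nodes are
    free; the segment is aligned end to end) and banded: node ``v`` with
    estimated window column ``col[v]`` is only scored against segment
    positions within ``band`` of ``col[v] - col0``.  Matched bases fuse into
    existing nodes (or aligned-ring siblings of the same base); edge weights
    count threaded sequences.  ``H``/``ptyp``/``pnod`` are caller-provided
    scratch matrices with at least ``n_nodes`` rows and ``2*band + 2``
    columns.  Returns updated (n_nodes, n_edges).
    """
    m = q.size
    if n_nodes == 0:
        for j in range(m):
            base[j] = q[j]
            ring[j] = j
            col[j] = col0 + j
        for j in range(m - 1):
            eu[j] = j
            ev[j] = j + 1
            ew[j] = 1
            out_next[j] = out_head[j]
            out_head[j] = j
        return m, m - 1
    order = _poa_topo(n_nodes, eu, ev, n_edges)
    poff, plist = _poa_preds(n_nodes, eu, ev, n_edges)
    outdeg = np.zeros(n_nodes, dtype=np.int32)
    for e in range(n_edges):
        outdeg[eu[e]] += 1
    # adaptive banding: anchored segments rarely drift more than a few
    # bases off their expected diagonal, so a narrow band almost always
    # suffices; fall back to the full band when the score disagrees
    narrow = band // 3
    if narrow < 8:
        narrow = 8
    # columns of the graph the segment can overlap (for the score bar)
    maxcol = col[0]
    mincol = col[0]
    for v in range(1, n_nodes):
        if col[v] > maxcol:
            maxcol = col[v]
        if col[v] < mincol:
            mincol = col[v]
    ov_lo = col0 if col0 > mincol else mincol
    ov_hi = (col0 + m) if (col0 + m) < (maxcol + 1) else (maxcol + 1)
    m_ov = ov_hi - ov_lo
    if m_ov < 0:
        m_ov = 0
    thr = (match * m_ov) // 2
    overhang = (col0 + m) - (maxcol + 1)
    if overhang < 0:
        overhang = 0
    best_v, best_j, best_s, lo, hi = _poa_dp(
        base, col, poff, plist, order, n_nodes, q, col0,
        match, mismatch, gap, narrow, H, ptyp, pnod, outdeg,
        m - overhang)
    if narrow < band and (best_v < 0 or best_s < thr):
        best_v, best_j, best_s, lo, hi = _poa_dp(
            base, col, poff, plist, order, n_nodes, q, col0,
            match, mismatch, gap, band, H, ptyp, pnod, outdeg,
            m - overhang)
    # best end (computed in _poa_dp): either the segment is fully consumed
    # inside the graph (trailing graph nodes free), or the alignment ends
    # at a graph sink and the segment's remaining tail extends the graph
    # for free (overlap-style ends-free scoring; a penalized overhang
    # would bias the DP toward chimeric in-graph alignments)
    matched = np.full(m, -1, dtype=np.int32)
    if best_v < 0 or best_s <= _NEG:
        # band never reached the end of the segment (degenerate window);
        # thread the segment as an unaligned chain
        pass
    else:
        v = best_v
        j = best_j
        while j > 0:
            if v == n_nodes:
                # inside the virtual row: remaining bases are leading inserts
                j -= 1
                continue
            t = ptyp[v, j - lo[v]]
            if t == 1:
                matched[j - 1] = v
                pv = pnod[v, j - lo[v]]
                v = pv
                j -= 1
            elif t == 2:
                v = pnod[v, j - lo[v]]
            elif t == 3:
                j -= 1
            else:
                break
    # fuse
    prev = -1
    for j in range(m):
        u = matched[j]
        if u >= 0:
            if base[u] == q[j]:
                node = u
            else:
                node = -1
                r = ring[u]
                while r != u:
                    if base[r] == q[j]:
                        node = r
                        break
                    r = ring[r]
                if node < 0:
                    node = n_nodes
                    n_nodes += 1
                    base[node] = q[j]
                    col[node] = col[u]
                    out_head[node] = -1
                    ring[node] = ring[u]
                    ring[u] = node
        else:
            node = n_nodes
            n_nodes += 1
            base[node] = q[j]
            col[node] = col[prev] + 1 if prev >= 0 else col0 + j
            ring[node] = node
            out_head[node] = -1
        if prev >= 0 and prev != node:
            e = out_head[prev]
            found = False
            while e != -1:
                if ev[e] == node:
                    ew[e] += 1
                    found = True
                    break
                e = out_next[e]
            if not found:
                eu[n_edges] = prev
                ev[n_edges] = node
                ew[n_edges] = 1
                out_next[n_edges] = out_head[prev]
                out_head[prev] = n_edges
                n_edges += 1
        prev = node
    return n_nodes, n_edges


@njit(cache=True)
def poa_heaviest_path(base, eu, ev, ew, n_nodes, n_edges):
    """Heaviest source-to-sink consensus path.

    Edges score (weight - 1), i.e. support above the single-sequence
    baseline: with raw weight sums, a stray error branch of several
    weight-1 edges could outweigh one well-supported edge purely by being
    longer.  Ties prefer the earlier node in topological order.  Short
    terminal runs of weight-1 edges (error tails of a single segment) are
    trimmed from the returned path; long weight-1 runs are genuine
    single-coverage sequence and are kept.
    """
    order = _poa_topo(n_nodes, eu, ev, n_edges)
    rank = np.empty(n_nodes, dtype=np.int32)
    for i in range(n_nodes):
        rank[order[i]] = i
    poff, plist = _poa_preds(n_nodes, eu, ev, n_edges)
    # weights looked up per (pred, node) via the pred list and edge scan
    # build weight lookup parallel to plist
    pw = np.empty(n_edges, dtype=np.int64)
    ptr = poff[:-1].copy()
    for e in range(n_edges):
        v = ev[e]
        # find position: fill in edge order (matches _poa_preds fill order)
        pw[ptr[v]] = ew[e]
        ptr[v] += 1
    NEGL = np.int64(-1) << 60
    score = np.full(n_nodes, NEGL, dtype=np.int64)
    bp = np.full(n_nodes, -1, dtype=np.int32)
    outdeg = np.zeros(n_nodes, dtype=np.int32)
    for e in range(n_edges):
        outdeg[eu[e]] += 1
    for idx in range(n_nodes):
        v = order[idx]
        if poff[v + 1] == poff[v]:
            score[v] = 0
            continue
        best = NEGL
        bprev = -1
        for pi in range(poff[v], poff[v + 1]):
            p = plist[pi]
            if score[p] == NEGL:
                continue
            # score edges by (support - 1): a path gains nothing from
            # detours through singly-supported branches, so spurious long
            # parallel branches cannot outweigh a well-supported edge
            cand = score[p] + pw[pi] - 1
            if cand > best or (cand == best and bprev >= 0 and rank[p] < rank[bprev]):
                best = cand
                bprev = p
        score[v] = best
        bp[v] = bprev
    best_v = -1
    best_s = NEGL
    for idx in range(n_nodes):
        v = order[idx]
        if outdeg[v] == 0 and score[v] > best_s:
            best_s = score[v]
            best_v = v
    nodes = np.empty(n_nodes, dtype=np.int32)
    cnt = 0
    v = best_v
    while v >= 0:
        nodes[cnt] = v
        cnt += 1
        v = bp[v]
    # nodes are in reverse order; recover per-step edge weights
    wts = np.empty(cnt, dtype=np.int64)  # wts[i] = weight of edge into nodes[i]
    for i in range(cnt - 1):
        u = nodes[i + 1]
        vv = nodes[i]
        w = np.int64(0)
        for pi in range(poff[vv], poff[vv + 1]):
            if plist[pi] == u and pw[pi] > w:
                w = pw[pi]
        wts[i] = w
    # a sum-of-weights path happily absorbs weight-1 junk at its ends
    # (stray error tails of single segments); trim short terminal runs of
    # weight-1 edges when the path contains any better-supported edge.
    # Long weight-1 runs are genuine single-coverage regions and are kept.
    TRIM_CAP = 8
    has_strong = False
    for i in range(cnt - 1):
        if wts[i] >= 2:
            has_strong = True
            break
    first = 0       # index (from the back) of last kept node
    last = cnt - 1  # index of first kept node
    if has_strong and cnt > 1:
        r = 0
        while r < cnt - 1 and wts[r] < 2:
            r += 1
        if r <= TRIM_CAP:
            first = r
        r = 0
        while last - 1 - r >= first and wts[last - 1 - r] < 2:
            r += 1
        if r <= TRIM_CAP:
            last -= r
    res = np.empty(last - first + 1, dtype=np.uint8)
    for i in range(last - first + 1):
        res[i] = base[nodes[last - i]]
    return res


@njit(cache=True)
def poa_consensus_kernel(seg_flat, seg_off, seg_col0,
                         match, mismatch, gap, band):
    """Build a POA over all segments of a window and return the heaviest-path
    consensus codes."""
    total = seg_flat.size
    cap_n = total + 8
    cap_e = 2 * total + 16
    base = np.zeros(cap_n, dtype=np.uint8)
    ring = np.zeros(cap_n, dtype=np.int32)
    colv = np.zeros(cap_n, dtype=np.int32)
    eu = np.zeros(cap_e, dtype=np.int32)
    ev = np.zeros(cap_e, dtype=np.int32)
    ew = np.zeros(cap_e, dtype=np.int64)
    out_head = np.full(cap_n, -1, dtype=np.int32)
    out_next = np.full(cap_e, -1, dtype=np.int32)
    W = 2 * band + 2
    H = np.empty((cap_n, W), dtype=np.int32)
    ptyp = np.empty((cap_n, W), dtype=np.uint8)
    pnod = np.empty((cap_n, W), dtype=np.int32)
    n_nodes = 0
    n_edges = 0
    for si in range(seg_off.size - 1):
        q = seg_flat[seg_off[si]:seg_off[si + 1]]
        if q.size == 0:
            continue
        n_nodes, n_edges = poa_add_segment(
            base, ring, colv, eu, ev, ew, out_head, out_next,
            n_nodes, n_edges, q, seg_col0[si],
            match, mismatch, gap, band, H, ptyp, pnod)
    if n_nodes == 0:
        return np.empty(0, dtype=np.uint8)
    return poa_heaviest_path(base, eu, ev, ew, n_nodes, n_edges)


# ---------------------------------------------------------------------------
# misc helpers
# ---------------------------------------------------------------------------


@njit(cache=True)
def parse_cigar_normalize(cig, qcodes, tcodes):
    """Parse a CIGAR byte string, resolve 'M' runs, left-align indels.

    ``cig`` is the ASCII CIGAR as a uint8 array over digits and =XIDM.
    Returns (op_codes, op_lens, n_edits) with indels left-shifted within
    homopolymers (see :func:`left_shift_gaps`).
    """
    n = cig.size
    # first pass: total column count
    total = 0
    num = 0
    for i in range(n):
        c = cig[i]
        if 48 <= c <= 57:
            num = num * 10 + (c - 48)
        else:
            total += num
            num = 0
    cols = np.empty(total, dtype=np.uint8)
    p = 0
    q = 0
    t = 0
    num = 0
    has_indel = False
    for i in range(n):
        c = cig[i]
        if 48 <= c <= 57:
            num = num * 10 + (c - 48)
            continue
        if c == 61 or c == 88 or c == 77:  # '=' 'X' 'M'
            for x in range(num):
                cols[p] = 0 if qcodes[q] == tcodes[t] else 1
                p += 1
                q += 1
                t += 1
        elif c == 73:  # 'I'
            for x in range(num):
                cols[p] = 2
                p += 1
                q += 1
            has_indel = True
        else:  # 'D'
            for x in range(num):
                cols[p] = 3
                p += 1
                t += 1
            has_indel = True
        num = 0
    if has_indel:
        cols = left_shift_gaps(cols, qcodes, tcodes)
    op_codes, op_lens = compress_ops(cols)
    edits = 0
    for i in range(op_codes.size):
        if op_codes[i] != 0:
            edits += op_lens[i]
    return op_codes, op_lens, edits


@njit(cache=True)
def cluster_seed_hits(tidx, rel, diag, qp, band, min_seeds):
    """Diagonal clustering of minimizer seed hits for one query read.

    Hits are grouped by (target index, relative strand) and split where
    consecutive sorted diagonals jump by more than ``band``.  For every
    (target, strand) pair only the cluster with the most distinct query
    positions is kept, and only if it has at least ``min_seeds`` of them.
    Returns (ti, rl, n_seeds, med_diag) arrays.
    """
    n = tidx.size
    out_ti = np.empty(n, dtype=np.int64)
    out_rl = np.empty(n, dtype=np.int64)
    out_ns = np.empty(n, dtype=np.int64)
    out_md = np.empty(n, dtype=np.int64)
    cnt = 0
    if n == 0:
        return out_ti[:0], out_rl[:0], out_ns[:0], out_md[:0]
    key = (tidx << np.int64(34)) | (rel << np.int64(33)) | (diag + (np.int64(1) << np.int64(31)))
    order = np.argsort(key)
    grp_ti = np.int64(-1)
    grp_rl = np.int64(-1)
    grp_best = -1
    grp_med = np.int64(0)
    i = 0
    while i < n:
        a = order[i]
        j = i + 1
        while j < n:
            b = order[j]
            if tidx[b] != tidx[a] or rel[b] != rel[a]:
                break
            if diag[order[j]] - diag[order[j - 1]] > band:
                break
            j += 1
        # distinct query positions in cluster [i, j)
        size = j - i
        qps = np.empty(size, dtype=np.int64)
        for x in range(size):
            qps[x] = qp[order[i + x]]
        qps.sort()
        ns = 1
        for x in range(1, size):
            if qps[x] != qps[x - 1]:
                ns += 1
        med = diag[order[i + size // 2]]
        if tidx[a] != grp_ti or rel[a] != grp_rl:
            if grp_best >= min_seeds:
                out_ti[cnt] = grp_ti
                out_rl[cnt] = grp_rl
                out_ns[cnt] = grp_best
                out_md[cnt] = grp_med
                cnt += 1
            grp_ti = tidx[a]
            grp_rl = rel[a]
            grp_best = -1
        if ns > grp_best:
            grp_best = ns
            grp_med = med
        i = j
    if grp_best >= min_seeds:
        out_ti[cnt] = grp_ti
        out_rl[cnt] = grp_rl
        out_ns[cnt] = grp_best
        out_md[cnt] = grp_med
        cnt += 1
    return out_ti[:cnt].copy(), out_rl[:cnt].copy(), out_ns[:cnt].copy(), out_md[:cnt].copy()


@njit(cache=True)
def runs_of_true(flags):
    """Maximal runs of True as (start, end) half-open index pairs."""
    n = flags.size
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    cnt = 0
    i = 0
    while i < n:
        if flags[i]:
            j = i + 1
            while j < n and flags[j]:
                j += 1
            starts[cnt] = i
            ends[cnt] = j
            cnt += 1
            i = j
        else:
            i += 1
    return starts[:cnt].copy(), ends[:cnt].copy()
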