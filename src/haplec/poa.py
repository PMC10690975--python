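"""Windowed partial-order-alignment consensus.

The phase-filtered pile is cut into consecutive non-overlapping windows on
the target read.  Within a window, the clipped short-read segments are
threaded one after another into a base-labelled DAG: matched bases fuse
into existing vertices (or "aligned-ring" siblings carrying the same
base), unmatched bases add vertices, and every traversed edge counts the
sequences supporting it.  The consensus of the window is the
maximum-total-weight source-to-sink path of the DAG, which replaces the
target subread; the corrected subreads are finally concatenated back into
the full-length read.

The target subread itself takes no part in the consensus — the short
reads alone decide the sequence, which is what removes the long-read
errors.  Windows are independent (no shared state), so they may be
processed in any order or concurrently with identical results; segment
threading order within a window is fixed (target start, then read id) so
the greedy graph construction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from haplec import _kernels as K
from haplec.io_formats import SeqRecord
from haplec.phasing import AlignmentPile

_MIN_SEGMENT = 20  # segments shorter than this after clipping are dropped


@dataclass
class PoaParams:
    """Scoring and windowing parameters.

    Linear gap penalties; ``band`` restricts the alignment of a segment to
    the graph to a diagonal band around the segment's target-anchored
    position (plenty for <1% error segments) — pass ``band=None`` for an
    unbanded alignment.  ``min_window_cov`` is the minimum number of
    segments required before a window is corrected at all.
    """

    match: int = 3
    mismatch: int = -5
    gap: int = -4
    window_len: int = 500
    min_window_cov: int = 3
    band: Optional[int] = 30

    def __post_init__(self) -> None:
        if not (self.match > 0 >= self.mismatch and 0 >= self.gap):
            raise ValueError("require match > 0 >= mismatch and 0 >= gap")
        if self.window_len < 2 * _MIN_SEGMENT:
            raise ValueError("window_len unreasonably small")


@dataclass
class Window:
    """One target window and the short-read segments clipped into it.

    ``segments`` hold (short_id, sequence); ``segment_cols`` gives each
    segment's start column relative to ``start`` (segments from reads that
    begin mid-window are anchored accordingly).
    """

    target_id: str
    start: int
    end: int
    target_subread: str
    segments: List[Tuple[str, str]]
    segment_cols: List[int]


class PoaGraph:
    """Base-labelled partial-order graph with support-weighted edges."""

    def __init__(self, capacity: int = 1024):
        cap_e = 2 * capacity + 16
        self._base = np.zeros(capacity, dtype=np.uint8)
        self._ring = np.zeros(capacity, dtype=np.int32)
        self._col = np.zeros(capacity, dtype=np.int32)
        self._eu = np.zeros(cap_e, dtype=np.int32)
        self._ev = np.zeros(cap_e, dtype=np.int32)
        self._ew = np.zeros(cap_e, dtype=np.int64)
        self._out_head = np.full(capacity, -1, dtype=np.int32)
        self._out_next = np.full(cap_e, -1, dtype=np.int32)
        self.n_nodes = 0
        self.n_edges = 0

    def _grow(self, need: int) -> None:
        if self.n_nodes + need <= self._base.size:
            return
        new = max(2 * self._base.size, self.n_nodes + need + 16)
        g = PoaGraph(new)
        for name in ("_base", "_ring", "_col", "_out_head"):
            getattr(g, name)[: self.n_nodes] = getattr(self, name)[: self.n_nodes]
        for name in ("_eu", "_ev", "_ew", "_out_next"):
            getattr(g, name)[: self.n_edges] = getattr(self, name)[: self.n_edges]
        self.__dict__.update({k: g.__dict__[k] for k in
                              ("_base", "_ring", "_col", "_eu", "_ev", "_ew",
                               "_out_head", "_out_next")})

    def add_sequence(self, seq: str, col0: int = 0,
                     match: int = 3, mismatch: int = -5, gap: int = -4,
                     band: Optional[int] = None) -> None:
        """Align a sequence to the graph and thread it in."""
        q = K.encode(seq)
        if q.size == 0:
            return
        self._grow(q.size)
        eff_band = band if band is not None else q.size + int(self._col[:self.n_nodes].max(initial=0)) + 2
        W = 2 * eff_band + 2
        cap = self.n_nodes + q.size + 2
        H = np.empty((cap, W), dtype=np.int32)
        ptyp = np.empty((cap, W), dtype=np.uint8)
        pnod = np.empty((cap, W), dtype=np.int32)
        self.n_nodes, self.n_edges = K.poa_add_segment(
            self._base, self._ring, self._col, self._eu, self._ev, self._ew,
            self._out_head, self._out_next, self.n_nodes, self.n_edges,
            q, col0, match, mismatch, gap, eff_band, H, ptyp, pnod)

    def consensus(self) -> str:
        """Heaviest source-to-sink path (ties: earlier topological order)."""
        if self.n_nodes == 0:
            return ""
        codes = K.poa_heaviest_path(self._base, self._eu, self._ev, self._ew,
                                    self.n_nodes, self.n_edges)
        return K.decode(codes)

    def edges(self) -> List[Tuple[int, int, int]]:
        """Edge list as (from_node, to_node, weight)."""
        return [(int(self._eu[e]), int(self._ev[e]), int(self._ew[e]))
                for e in range(self.n_edges)]

    def node_base(self, v: int) -> str:
        return "ACGT"[self._base[v]]


def segment_windows(pile: AlignmentPile, window_len: int = 500) -> List[Window]:
    """Cut the (phase-filtered) pile into consecutive windows.

    Windows are [i*L, min((i+1)*L, len)) on the target; each member
    contributes at most one segment per window, sliced from its aligned
    query by replaying the edit operations.  Segments shorter than 20 bp
    after clipping are dropped.
    """
    L = len(pile.target.seq)
    if L == 0:
        return []
    n_win = (L + window_len - 1) // window_len
    windows = [
        Window(
            target_id=pile.target.id,
            start=i * window_len,
            end=min((i + 1) * window_len, L),
            target_subread=pile.target.seq[i * window_len: min((i + 1) * window_len, L)],
            segments=[],
            segment_cols=[],
        )
        for i in range(n_win)
    ]
    if not pile.members:
        return windows
    tstart, opoff, op_codes, op_lens, qoff, qflat = pile._member_arrays()
    mi, wi, qlo, qhi, col0 = K.window_slices(
        window_len, L, tstart, opoff, op_codes, op_lens)
    order = np.lexsort((mi, wi))  # by window, then member (members pre-sorted)
    for r in order:
        if qhi[r] - qlo[r] < _MIN_SEGMENT:
            continue
        m = pile.members[mi[r]]
        seq = K.decode(m.query_codes[qlo[r]:qhi[r]])
        w = windows[wi[r]]
        w.segments.append((m.short_id, seq))
        w.segment_cols.append(int(col0[r]))
    return windows


def poa_align_and_consensus(segments: Sequence[Tuple[str, str]],
                            params: Optional[PoaParams] = None,
                            segment_cols: Optional[Sequence[int]] = None) -> str:
    """POA consensus of a set of segments.

    The graph is initialized from the first segment and each subsequent
    segment is aligned and fused; the consensus is the heaviest path.
    Segment order must already be fixed by the caller (window machinery
    sorts by target start, then id).  When ``segment_cols`` is omitted the
    alignment is unbanded.
    """
    if not segments:
        raise ValueError("poa_align_and_consensus requires at least one segment")
    params = params or PoaParams()
    if segment_cols is None:
        cols = [0] * len(segments)
        band = None
    else:
        cols = list(segment_cols)
        band = params.band
    seg_codes = [K.encode(s) for _, s in segments]
    flat = np.concatenate(seg_codes) if seg_codes else np.empty(0, dtype=np.uint8)
    off = np.zeros(len(seg_codes) + 1, dtype=np.int64)
    np.cumsum([c.size for c in seg_codes], out=off[1:])
    eff_band = band
    if eff_band is None:
        eff_band = int(flat.size + max(cols, default=0) + 2)
    codes = K.poa_consensus_kernel(
        flat, off, np.asarray(cols, dtype=np.int64),
        params.match, params.mismatch, params.gap, eff_band)
    return K.decode(codes)


def window_coverage(window: Window) -> np.ndarray:
    """Per-column segment coverage of a window."""
    cover = np.zeros(len(window.target_subread), dtype=np.int32)
    for (_, seq), c0 in zip(window.segments, window.segment_cols):
        cover[c0:c0 + len(seq)] += 1
    return cover


def has_interior_hole(window: Window) -> bool:
    """True when a zero-coverage column separates covered columns."""
    cover = window_coverage(window)
    covered = np.flatnonzero(cover > 0)
    if covered.size == 0:
        return False
    return bool((cover[covered[0]:covered[-1] + 1] == 0).any())


def correct_window(window: Window, params: Optional[PoaParams] = None) -> str:
    """Corrected subread for one window.

    Windows with fewer than ``min_window_cov`` segments keep the original
    target subread (too little evidence to rewrite anything).  Columns
    before the first / after the last covered position also keep the
    target's own sequence — the consensus path cannot speak for them — and
    a window whose interior contains a zero-coverage column is left
    entirely unchanged: its POA graph falls apart into disconnected
    components and the heaviest path would silently drop the gap.
    """
    params = params or PoaParams()
    if len(window.segments) < params.min_window_cov:
        return window.target_subread
    wlen = len(window.target_subread)
    cover = window_coverage(window)
    covered = np.flatnonzero(cover > 0)
    if covered.size == 0:
        return window.target_subread
    lead, trail = int(covered[0]), int(covered[-1]) + 1
    if (cover[lead:trail] == 0).any():  # interior coverage hole
        return window.target_subread
    cons = poa_align_and_consensus(window.segments, params, window.segment_cols)
    span = max(trail - lead, 1)
    if not 0.5 <= len(cons) / span <= 2.0:
        return window.target_subread
    return window.target_subread[:lead] + cons + window.target_subread[trail:]


def concatenate_subreads(subreads: Sequence[str], windows: Sequence[Window],
                         read_id: str) -> SeqRecord:
    """Splice corrected subreads back into a full-length read."""
    if len(subreads) != len(windows):
        raise ValueError(
            f"{read_id}: {len(subreads)} subreads for {len(windows)} windows"
        )
    return SeqRecord(read_id, "".join(subreads), None)
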