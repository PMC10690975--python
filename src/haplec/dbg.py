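"""Solid-k-mer de Bruijn graph pre-correction of long reads.

Short reads are decomposed into canonical k-mers; a k-mer whose count
reaches ``t_solid`` is *solid* and assumed to come from a real genome
rather than from a sequencing error.  On a long read, maximal stretches
whose k-mers are all solid act as anchors; for every weak gap between two
anchors the implicit graph of solid k-mers is searched for paths joining
the anchor k-mers whose length is compatible with the gap.

When several near-identical haplotypes are present, the graph contains
bubbles, and an admissible path exists per haplotype.  The corrector then
keeps the path closest (by edit distance) to the read's own gap sequence,
and only if that winner is strict — at a haplotype bubble the read's own
base at the divergent site is the deciding evidence, so the read is
corrected toward its own haplotype; when the read is uninformative there
(an error at the divergent site itself, or too many candidate paths) the
gap is left unchanged rather than guessed.  Residual ambiguity of this
kind is resolved later by the phased overlap stage.

This pass removes the bulk of the artificial indels, which is what makes
subsequent short-to-long alignment well-behaved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from haplec import _kernels as K
from haplec.io_formats import SeqRecord

logger = logging.getLogger(__name__)

# gaps longer than this are never searched: the DFS budget would be spent
# without a realistic chance of a unique path
_MAX_GAP = 500


@dataclass
class DbgParams:
    """Parameters of the de Bruijn correction pass.

    ``max_branch`` caps DFS expansions per gap; ``max_path_slack`` is the
    allowed difference (bp) between a candidate path length and the
    observed gap length.
    """

    k: int = 21
    t_solid: int = 3
    max_branch: int = 5000
    max_path_slack: int = 10
    max_paths: int = 16  # gaps with more candidate paths are left alone

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or not 11 <= self.k <= 31:
            raise ValueError(f"k must be odd and in [11, 31], got {self.k}")
        for name in ("t_solid", "max_branch", "max_path_slack", "max_paths"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class DbgIndex:
    """Canonical k-mer counts of a short-read set."""

    def __init__(self, k: int, t_solid: int, counts) -> None:
        self.k = k
        self.t_solid = t_solid
        self._counts = counts  # numba typed Dict: int64 code -> count

    def __len__(self) -> int:
        return len(self._counts)

    def count(self, kmer: str) -> int:
        """Count of one k-mer (canonicalized)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {len(kmer)} bases")
        fwd, rc, valid = K.kmer_codes(K.encode(kmer), self.k)
        if not valid[0]:
            return 0
        code = int(min(fwd[0], rc[0]))
        return int(self._counts.get(code, 0))

    def is_solid(self, kmer: str) -> bool:
        return self.count(kmer) >= self.t_solid

    def to_dict(self) -> Dict[str, int]:
        """Counts as a plain {kmer-string: count} dict (small inputs only)."""
        out = {}
        for code, cnt in self._counts.items():
            codes = np.empty(self.k, dtype=np.uint8)
            c = int(code)
            for i in range(self.k - 1, -1, -1):
                codes[i] = c & 3
                c >>= 2
            out[K.decode(codes)] = int(cnt)
        return out


def build_dbg(short_reads: Sequence[SeqRecord], k: int = 21, t_solid: int = 3) -> DbgIndex:
    """Count canonical k-mers of the short reads.

    k-mers containing N are skipped.  Raises if no read is long enough to
    contain a single k-mer.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if not short_reads:
        raise ValueError("short read set is empty")
    if all(len(r.seq) < k for r in short_reads):
        raise ValueError(f"k={k} exceeds the length of every short read")
    flat = np.concatenate([K.encode(r.seq) for r in short_reads])
    offsets = np.zeros(len(short_reads) + 1, dtype=np.int64)
    np.cumsum([len(r.seq) for r in short_reads], out=offsets[1:])
    counts = K.count_kmers(flat, offsets, k)
    return DbgIndex(k, t_solid, counts)


def find_solid_regions(read: SeqRecord, dbg: DbgIndex) -> List[Tuple[int, int]]:
    """Maximal base intervals of the read whose k-mers are all solid.

    Intervals are 0-based half-open, sorted and non-overlapping; a read
    without any solid k-mer yields an empty list.
    """
    codes = K.encode(read.seq)
    if codes.size < dbg.k:
        return []
    flags = K.solid_flags(codes, dbg.k, dbg._counts, dbg.t_solid)
    starts, ends = K.runs_of_true(flags)
    return [(int(s), int(e) + dbg.k - 1) for s, e in zip(starts, ends)]


def _choose_path(found: int, paths: "np.ndarray", lens: "np.ndarray",
                 gap_seq: str, max_paths: int) -> Optional[str]:
    """Pick the candidate path for a gap, or None to leave it unchanged.

    A single admissible path wins outright; among several, the one with
    the smallest edit distance to the read's own gap sequence wins only
    if it is strictly better than every other.
    """
    import edlib

    if found == 0 or found > max_paths:
        return None
    dmax = paths.size // max(lens.size, 1)
    spells = [K.decode(paths[i * dmax: i * dmax + lens[i]]) for i in range(found)]
    if found == 1:
        return spells[0]
    dists = [edlib.align(s, gap_seq, mode="NW", task="distance")["editDistance"]
             for s in spells]
    order = sorted(range(found), key=lambda i: dists[i])
    if dists[order[0]] < dists[order[1]]:
        return spells[order[0]]
    return None


def correct_with_dbg(read: SeqRecord, dbg: DbgIndex, params: DbgParams) -> SeqRecord:
    """One de Bruijn correction pass over a single long read.

    Every weak gap flanked by two solid anchors is replaced by the
    winning admissible solid path (see :func:`_choose_path`); ambiguous,
    unreachable or oversized gaps, and weak head/tail regions, pass
    through unchanged.  Bases inside solid regions are never modified.
    """
    k = dbg.k
    codes = K.encode(read.seq)
    if codes.size < k:
        return SeqRecord(read.id, read.seq, None)
    flags = K.solid_flags(codes, k, dbg._counts, dbg.t_solid)
    starts, ends = K.runs_of_true(flags)
    if starts.size == 0:
        return SeqRecord(read.id, read.seq, None)
    fwd, rc, valid = K.kmer_codes(codes, k)
    seq = read.seq
    pieces = [seq[: int(ends[0]) - 1 + k]]
    n_fixed = 0
    for i in range(1, starts.size):
        p1 = int(ends[i - 1]) - 1  # last solid k-mer of the previous anchor
        p2 = int(starts[i])        # first solid k-mer of the next anchor
        run_end = int(ends[i]) - 1
        gap = p2 - p1
        replaced = False
        if 0 < gap <= _MAX_GAP:
            dmin = max(1, gap - params.max_path_slack)
            dmax = gap + params.max_path_slack
            found, paths, lens = K.dbg_enumerate_paths(
                fwd[p1], rc[p1], fwd[p2], k, dbg._counts, dbg.t_solid,
                dmin, dmax, params.max_branch, params.max_paths,
            )
            chosen = _choose_path(found, paths, lens, seq[p1 + k:p2 + k],
                                  params.max_paths)
            if chosen is not None:
                pieces.append(chosen)
                replaced = True
                n_fixed += 1
        if not replaced:
            pieces.append(seq[p1 + k:p2 + k])
        pieces.append(seq[p2 + k:run_end + k])
    pieces.append(seq[int(ends[-1]) - 1 + k:])
    if n_fixed:
        logger.debug("%s: %d gap(s) corrected, %d anchor run(s)",
                     read.id, n_fixed, starts.size)
    return SeqRecord(read.id, "".join(pieces), None)
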