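"""Error-rate evaluation of (corrected) reads against truth haplotypes.

Metrics follow the usual read-level conventions for mixed communities:

* ``indels/100 kbp`` — insertion or deletion *errors* per 100,000 aligned
  read bases (an event of several bases counts once by default; a
  ``count_bases`` switch counts bases instead);
* ``mismatches/100 kbp`` — mismatching bases per 100,000 aligned bases;
* ``genome fraction`` — percent of each haplotype covered by at least one
  read alignment.

Each read is assigned to its single best-scoring haplotype and strand
(minimizer seeding plus banded extension with a relaxed band); reads with
no acceptable alignment are counted as unaligned and contribute to no
rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from haplec import _kernels as K
from haplec.io_formats import SeqRecord
from haplec.overlap import MapParams, _MinimizerIndex, _parse_cigar

# evaluation alignments tolerate raw uncorrected reads
_EVAL_MAX_EDIT_FRAC = 0.35


@dataclass
class TruthAlignment:
    """Best placement of one read on the truth haplotypes."""

    read_id: str
    hap_id: str
    hap_start: int
    hap_end: int
    strand: str
    aligned_bases: int       # read bases in the alignment
    n_mismatches: int
    n_indel_events: int
    n_indel_bases: int


@dataclass
class ErrorReport:
    """Error rates and coverage of a read set versus its truth genomes."""

    indels_per_100kbp: float
    mismatches_per_100kbp: float
    genome_fraction_percent: Dict[str, float]  # per haplotype + "overall"
    aligned_bases: int
    unaligned_read_count: int

    def to_tsv(self) -> str:
        lines = ["metric\thaplotype\tvalue"]
        lines.append(f"indels_per_100kbp\tall\t{self.indels_per_100kbp:.2f}")
        lines.append(f"mismatches_per_100kbp\tall\t{self.mismatches_per_100kbp:.2f}")
        for hap, gf in self.genome_fraction_percent.items():
            lines.append(f"genome_fraction_percent\t{hap}\t{gf:.3f}")
        lines.append(f"aligned_bases\tall\t{self.aligned_bases}")
        lines.append(f"unaligned_read_count\tall\t{self.unaligned_read_count}")
        return "\n".join(lines) + "\n"


def align_reads_to_truth(reads: Sequence[SeqRecord],
                         haplotypes: Sequence[SeqRecord],
                         ) -> List[TruthAlignment]:
    """Align each read to its best haplotype and strand.

    Reads whose best alignment exceeds the evaluation edit-fraction
    threshold (or that share no minimizers with any haplotype) are
    omitted; callers count them via the difference in lengths.
    """
    if not haplotypes:
        raise ValueError("haplotype set must be non-empty")
    k, w = 15, 10
    index = _MinimizerIndex(haplotypes, k, w)
    out: List[TruthAlignment] = []
    for read in reads:
        qcodes = K.encode(read.seq)
        if qcodes.size < k:
            continue
        qpos, qcode, qstrand = K.minimizers(qcodes, k, w)
        if qpos.size == 0:
            continue
        packed, qidx = index.lookup(qcode, max_occ=1024)
        if packed.size == 0:
            continue
        tidx = packed >> 33
        tpos = (packed >> 1) & ((1 << 32) - 1)
        tstrand = packed & 1
        rel = (tstrand ^ qstrand[qidx]).astype(np.int64)
        qp = qpos[qidx].astype(np.int64)
        diag = np.where(rel == 0, tpos - qp, tpos + qp)
        qlen = qcodes.size
        qrev = None
        # vote for (hap, strand, coarse diagonal) and extend the best few
        coarse = diag // max(200, qlen // 8)
        keys = (tidx << 22) ^ (rel << 21) ^ (coarse & ((1 << 20) - 1))
        uniq, cnt = np.unique(keys, return_counts=True)
        best = None
        for key in uniq[np.argsort(cnt)][-3:][::-1]:
            sel = keys == key
            ti = int(tidx[sel][0])
            rl = int(rel[sel][0])
            med = int(np.median(diag[sel]))
            tstart_est = med if rl == 0 else med - qlen + k
            tc = index.encoded[ti]
            pad = max(100, qlen // 10)
            lo = max(0, tstart_est - pad)
            hi = min(tc.size, tstart_est + qlen + pad)
            if hi <= lo:
                continue
            if rl:
                if qrev is None:
                    qrev = K.revcomp_codes(qcodes)
                qc = qrev
            else:
                qc = qcodes
            # progressive distance cap: corrected reads align within a
            # small k, so the expensive wide-band pass runs only for raw
            # or badly corrected reads
            q_str = K.decode(qc)
            t_str = index.seqs[ti][lo:hi]
            res = {"editDistance": -1}
            for frac in (0.02, 0.06, _EVAL_MAX_EDIT_FRAC):
                k_lim = max(16, int(frac * qlen))
                res = edlib.align(q_str, t_str, mode="HW", task="path", k=k_lim)
                if res["editDistance"] >= 0:
                    break
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                t0, t1 = res["locations"][0]
                best = (res["editDistance"], ti, rl, lo + t0, lo + t1 + 1,
                        res["cigar"], qc)
        if best is None:
            continue
        ed, ti, rl, t0, t1, cigar, qc = best
        opc, opl = _parse_cigar(cigar, qc, index.encoded[ti][t0:t1])
        n_mm = 0
        n_ev = 0
        n_ib = 0
        for c, l in zip(opc, opl):
            if c == K.OP_X:
                n_mm += int(l)
            elif c in (K.OP_I, K.OP_D):
                n_ev += 1
                n_ib += int(l)
        out.append(TruthAlignment(
            read_id=read.id,
            hap_id=haplotypes[ti].id,
            hap_start=t0,
            hap_end=t1,
            strand="-" if rl else "+",
            aligned_bases=qlen,
            n_mismatches=n_mm,
            n_indel_events=n_ev,
            n_indel_bases=n_ib,
        ))
    return out


def compute_metrics(alignments: Sequence[TruthAlignment],
                    haplotypes: Sequence[SeqRecord],
                    n_reads: Optional[int] = None,
                    count_bases: bool = False) -> ErrorReport:
    """Aggregate alignments into per-100-kbp rates and genome fraction.

    ``count_bases=True`` counts indel bases instead of indel events.
    Raises when no bases aligned (the rates would be undefined).
    """
    total = sum(a.aligned_bases for a in alignments)
    if total == 0:
        raise ValueError("no aligned bases: error rates are undefined")
    indels = sum((a.n_indel_bases if count_bases else a.n_indel_events)
                 for a in alignments)
    mism = sum(a.n_mismatches for a in alignments)
    cover = {h.id: np.zeros(len(h.seq), dtype=bool) for h in haplotypes}
    for a in alignments:
        cover[a.hap_id][a.hap_start:a.hap_end] = True
    gf = {hid: 100.0 * c.sum() / c.size for hid, c in cover.items()}
    gf["overall"] = (
        100.0 * sum(int(c.sum()) for c in cover.values())
        / sum(c.size for c in cover.values())
    )
    unaligned = (n_reads - len(alignments)) if n_reads is not None else 0
    return ErrorReport(
        indels_per_100kbp=1e5 * indels / total,
        mismatches_per_100kbp=1e5 * mism / total,
        genome_fraction_percent=gf,
        aligned_bases=total,
        unaligned_read_count=unaligned,
    )


def evaluate_reads(reads: Sequence[SeqRecord], haplotypes: Sequence[SeqRecord],
                   count_bases: bool = False) -> ErrorReport:
    """Convenience wrapper: align then compute metrics."""
    alns = align_reads_to_truth(reads, haplotypes)
    return compute_metrics(alns, haplotypes, n_reads=len(reads),
                           count_bases=count_bases)
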