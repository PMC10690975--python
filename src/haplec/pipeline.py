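"""Protocol orchestration: de Bruijn passes, then phased-overlap passes.

The standard protocol applies the de Bruijn corrector several times
(indel removal stabilizes after about three passes), then several
overlap-stage passes, each of which remaps the short reads onto the
current long reads, phases and filters every pile, and rebuilds every
read from window consensi.  Pre-computed alignments (PAF) may seed the
first overlap pass only — after one pass the long reads have changed, so
later passes always remap internally.

Every pass starts again from the full short-read set: phase filtering is
relative to one target read and is not carried across passes.  The whole
protocol is deterministic for a fixed configuration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from haplec import _kernels as K
from haplec.dbg import DbgParams, build_dbg, correct_with_dbg
from haplec.evaluate import evaluate_reads
from haplec.io_formats import SeqRecord
from haplec.overlap import MapParams, PileAlignment, map_short_to_long
from haplec.phasing import AlignmentPile, PhasingParams, _phase_filter_core
from haplec.poa import (PoaParams, Window, concatenate_subreads,
                        correct_window, has_interior_hole, segment_windows)

logger = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ProtocolConfig:
    """Full protocol configuration.

    ``og_iters`` overlap passes are run per outer round (one "iteration"
    of the overlap stage is conventionally a small number of repeated
    passes); ``og_outer_rounds`` repeats the whole overlap stage.
    ``threads`` is accepted for interface stability; windows are
    order-independent by construction and the current implementation
    processes them serially, which keeps results bit-identical trivially.
    """

    dbg: DbgParams = field(default_factory=DbgParams)
    mapping: MapParams = field(default_factory=MapParams)
    phasing: PhasingParams = field(default_factory=PhasingParams)
    poa: PoaParams = field(default_factory=PoaParams)
    dbg_iters: int = 3
    og_iters: int = 3
    og_outer_rounds: int = 1
    threads: int = 1
    seed: int = 0
    filter_short_reads: bool = False
    # window rescue (correcting filter-collapsed windows from the
    # unfiltered pile) runs during the first N overlap passes; afterwards
    # such windows pass through unchanged, which guarantees convergence —
    # rescued regions are alignment-ambiguous and would otherwise be
    # rewritten slightly differently forever
    rescue_passes: int = 2

    def __post_init__(self) -> None:
        for name in ("dbg_iters", "og_iters", "og_outer_rounds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PassStats:
    """Per-pass accounting (exposed through the structured log)."""

    reads_touched: int = 0
    columns_tgs_error: int = 0
    columns_hap_snp: int = 0
    columns_ngs_error: int = 0
    members_filtered: int = 0
    windows_corrected: int = 0
    windows_rescued: int = 0
    windows_total: int = 0


def _restore_protected(consensus: str, subread: str, positions: List[int]) -> str:
    """Restore the target's own base at protected (HAP_SNP) columns.

    At a haplotype-SNP column the target base is, by construction of the
    classification, correct — strongly supported by in-phase reads — so a
    consensus that changed it (out-of-phase contamination surviving the
    filter) is overridden.  Positions whose base was deleted by the
    consensus are left alone (no unambiguous restore exists).
    """
    import edlib

    res = edlib.align(consensus, subread, mode="NW", task="path")
    out = list(consensus)
    qi = ti = 0
    pos_set = set(positions)
    changed = False
    for num, op in _CIG_RE.findall(res["cigar"]):
        n = int(num)
        if op in "=XM":
            if op != "=":
                for x in range(n):
                    if ti + x in pos_set and out[qi + x] != subread[ti + x]:
                        out[qi + x] = subread[ti + x]
                        changed = True
            qi += n
            ti += n
        elif op == "I":
            qi += n
        else:
            ti += n
    return "".join(out) if changed else consensus


def _correct_one_read(target: SeqRecord, alignments: List[PileAlignment],
                      config: ProtocolConfig, stats: PassStats,
                      allow_rescue: bool = True) -> SeqRecord:
    pile = AlignmentPile(target, alignments)
    kept_idx, labels, _alt, _a, counts = _phase_filter_core(pile, config.phasing)
    stats.columns_tgs_error += int((labels == 1).sum())
    stats.columns_hap_snp += int((labels == 2).sum())
    stats.columns_ngs_error += int((labels == 3).sum())
    stats.members_filtered += len(pile.members) - len(kept_idx)
    filtered = AlignmentPile(target, [pile.members[i] for i in kept_idx])
    windows = segment_windows(filtered, config.poa.window_len)
    # a window is rewritten only when it shows evidence of a target error:
    # a TGS_ERROR column (strong alternative base or gap, weak target
    # support) or strong insertion evidence (target is missing bases);
    # where every short read agrees with the target, no action is taken
    snp_cols = np.flatnonzero(labels == 2)
    err_cols = np.flatnonzero(
        (labels == 1) | (counts[:, 5] >= config.phasing.min_support))
    dirty = set((err_cols // config.poa.window_len).tolist())
    # in regions where the target still carries clustered indel errors,
    # artifactual "SNP" columns can make phase filtering strip the pile of
    # every haplotype at once; such windows fall back to the unfiltered
    # pile so that target errors remain correctable there
    unfiltered_windows = None
    subreads = []
    for wi, w in enumerate(windows):
        if wi not in dirty:
            subreads.append(w.target_subread)
            continue
        use = w
        if allow_rescue and has_interior_hole(w):
            if unfiltered_windows is None:
                unfiltered_windows = segment_windows(pile, config.poa.window_len)
            wu = unfiltered_windows[wi]
            if not has_interior_hole(wu):
                # the unfiltered pile mixes haplotypes; threading the
                # target subread in first makes it the backbone, so exact
                # allele ties resolve toward the target's own haplotype
                # while its clustered errors are still outvoted
                use = Window(
                    target_id=wu.target_id, start=wu.start, end=wu.end,
                    target_subread=wu.target_subread,
                    segments=[(target.id, wu.target_subread)] + wu.segments,
                    segment_cols=[0] + wu.segment_cols,
                )
                stats.windows_rescued += 1
        sub = correct_window(use, config.poa)
        if sub != use.target_subread:
            protect = [int(c) - w.start for c in snp_cols
                       if w.start <= c < w.end]
            if protect:
                sub = _restore_protected(sub, use.target_subread, protect)
        if sub != use.target_subread:
            stats.windows_corrected += 1
        subreads.append(sub)
    stats.windows_total += len(windows)
    return concatenate_subreads(subreads, windows, target.id)


def run_og_pass(long_reads: Sequence[SeqRecord], short_reads: Sequence[SeqRecord],
                config: Optional[ProtocolConfig] = None,
                alignments: Optional[Sequence[PileAlignment]] = None,
                allow_rescue: bool = True,
                ) -> List[SeqRecord]:
    """One overlap-stage pass over all long reads.

    Maps the short reads (unless ``alignments`` are supplied), then builds,
    phases, filters, windows and rewrites every long read.  Reads with an
    empty pile pass through unchanged.
    """
    if not long_reads or not short_reads:
        raise ValueError("read sets must be non-empty")
    config = config or ProtocolConfig()
    if alignments is None:
        alignments = map_short_to_long(short_reads, long_reads, config.mapping)
    by_target: Dict[str, List[PileAlignment]] = {}
    for a in alignments:
        by_target.setdefault(a.long_id, []).append(a)
    stats = PassStats()
    out: List[SeqRecord] = []
    for read in long_reads:
        alns = by_target.get(read.id)
        if not alns:
            out.append(SeqRecord(read.id, read.seq, None))
            continue
        stats.reads_touched += 1
        out.append(_correct_one_read(read, alns, config, stats, allow_rescue))
    logger.info(
        "OG pass: %d/%d reads touched; columns TGS_ERROR=%d HAP_SNP=%d "
        "NGS_ERROR=%d; %d members filtered; %d/%d windows corrected (%d rescued)",
        stats.reads_touched, len(long_reads), stats.columns_tgs_error,
        stats.columns_hap_snp, stats.columns_ngs_error,
        stats.members_filtered, stats.windows_corrected, stats.windows_total,
        stats.windows_rescued,
    )
    return out


def _kmer_prefilter(short_reads: Sequence[SeqRecord], config: ProtocolConfig
                    ) -> List[SeqRecord]:
    """Discard short reads containing any k-mer below the solidity bar.

    A lightweight spectrum cleaner for unusually noisy short-read sets.
    """
    dbg = build_dbg(short_reads, config.dbg.k, config.dbg.t_solid)
    kept = []
    for r in short_reads:
        codes = K.encode(r.seq)
        if codes.size < dbg.k:
            continue
        flags = K.solid_flags(codes, dbg.k, dbg._counts, dbg.t_solid)
        if flags.all():
            kept.append(r)
    logger.info("short-read k-mer filter kept %d/%d reads", len(kept), len(short_reads))
    return kept


def run_protocol(long_reads: Sequence[SeqRecord], short_reads: Sequence[SeqRecord],
                 config: Optional[ProtocolConfig] = None,
                 truth: Optional[Sequence[SeqRecord]] = None,
                 alignments: Optional[Sequence[PileAlignment]] = None,
                 ) -> List[SeqRecord]:
    """The full two-stage protocol.

    ``dbg_iters`` de Bruijn passes, then ``og_outer_rounds`` x ``og_iters``
    overlap passes.  Supplied ``alignments`` (from PAF) are used for the
    first overlap pass only.  When ``truth`` haplotypes are given, error
    rates are logged after each stage.
    """
    if not long_reads:
        raise ValueError("no long reads to correct")
    config = config or ProtocolConfig()
    reads = [SeqRecord(r.id, r.seq, None) for r in long_reads]

    def _log_stage(stage: str) -> None:
        if truth is not None:
            rep = evaluate_reads(reads, truth)
            logger.info(
                "%s: indels/100kbp=%.2f mismatches/100kbp=%.2f GF=%.2f%%",
                stage, rep.indels_per_100kbp, rep.mismatches_per_100kbp,
                rep.genome_fraction_percent["overall"],
            )

    _log_stage("raw")
    shorts = list(short_reads)
    if config.filter_short_reads and shorts:
        shorts = _kmer_prefilter(shorts, config)
    if config.dbg_iters > 0 and shorts:
        dbg = build_dbg(shorts, config.dbg.k, config.dbg.t_solid)
        for i in range(config.dbg_iters):
            reads = [correct_with_dbg(r, dbg, config.dbg) for r in reads]
            logger.info("DBG pass %d/%d done", i + 1, config.dbg_iters)
        _log_stage("after DBG stage")
    total_og = config.og_outer_rounds * config.og_iters
    if total_og > 0 and shorts:
        # a pass is a deterministic function of (read sequence, short
        # reads): a read that a pass leaves unchanged is at a fixed point
        # and can be dropped from all later passes
        active = list(range(len(reads)))
        first = True
        n_pass = 0
        for rnd in range(config.og_outer_rounds):
            for i in range(config.og_iters):
                if not active:
                    break
                sub = [reads[j] for j in active]
                sub_out = run_og_pass(
                    sub, shorts, config,
                    alignments=alignments if first else None,
                    allow_rescue=n_pass < config.rescue_passes,
                )
                n_pass += 1
                first = False
                still = []
                for j, r_new in zip(active, sub_out):
                    if r_new.seq != reads[j].seq:
                        still.append(j)
                    reads[j] = r_new
                active = still
                logger.info("OG pass %d/%d (round %d) done; %d read(s) still changing",
                            i + 1, config.og_iters, rnd + 1, len(active))
        _log_stage("after OG stage")
    return reads
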