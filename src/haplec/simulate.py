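"""Synthetic strain mixtures and hybrid read sets.

The generator emulates the structure of mixed-strain sequencing studies: a
random ancestor genome is mutated into several near-identical haplotypes
("strains"), and from each haplotype both long, error-prone reads and
short, accurate reads are drawn.  Defaults mirror common mixed-community
designs: 10x coverage of each read type per strain, long reads averaging
10 kbp with 10% indel-dominated errors, short reads of 250 bp with 0.3%
substitution-dominated errors.

Every read is labelled with its source haplotype and interval, so
downstream phasing and correction accuracy can be measured exactly.
Seeded runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import edlib
import numpy as np

from haplec.io_formats import SeqRecord, reverse_complement

_BASES = "ACGT"


@dataclass
class Variant:
    """One mutation of the ancestor carried by one haplotype.

    ``pos`` is on the haplotype's own coordinates.  For SNPs, ``ref`` and
    ``alt`` are single bases; for insertions ``alt`` holds the inserted
    bases (``ref`` empty); for deletions ``ref`` holds the deleted bases
    (``alt`` empty).
    """

    hap_id: str
    pos: int
    ref: str
    alt: str
    kind: str  # snp | ins | del


@dataclass
class CommunityTruth:
    """Ground truth of a simulated community."""

    haplotypes: List[SeqRecord]
    pairwise_divergence: np.ndarray
    per_haplotype_coverage: Dict[str, Tuple[float, float]]  # id -> (long, short)
    variant_table: List[Variant]


@dataclass
class ReadSimParams:
    """Read-level simulation parameters.

    Error mixes are (insertion, deletion, substitution) fractions summing
    to 1.  Long reads default to an indel-dominated profile, short reads to
    a substitution-dominated one.
    """

    long_mean_len: int = 10_000
    long_err_rate: float = 0.10
    long_err_mix: Tuple[float, float, float] = (0.35, 0.40, 0.25)
    short_read_len: int = 250
    short_err_rate: float = 0.003
    short_err_mix: Tuple[float, float, float] = (0.05, 0.05, 0.90)
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.long_err_rate, self.short_err_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"error rate {rate} outside [0, 1)")
        for mix in (self.long_err_mix, self.short_err_mix):
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"error mix {mix} does not sum to 1")


@dataclass
class TruthPlacement:
    """Source haplotype and interval of one simulated read."""

    read_id: str
    hap_id: str
    start: int
    end: int
    strand: str


class TruthPlacements(list):
    """Placement list with aggregate injected-error tallies.

    ``injected["long"]`` / ``injected["short"]`` map error kind
    ("ins"/"del"/"sub") to the number of injected events.
    """

    def __init__(self, records=(), injected=None):
        super().__init__(records)
        self.injected: Dict[str, Dict[str, int]] = injected or {
            "long": {"ins": 0, "del": 0, "sub": 0},
            "short": {"ins": 0, "del": 0, "sub": 0},
        }


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(
    rng: np.random.Generator,
    ancestor: str,
    hap_id: str,
    divergence: float,
    indel_fraction: float,
) -> Tuple[str, List[Variant]]:
    """Mutate the ancestor at per-base rate ``divergence``.

    A fraction ``indel_fraction`` of events are 1-3 bp indels (ins/del with
    equal probability); the rest are substitutions.
    """
    n = len(ancestor)
    hits = np.flatnonzero(rng.random(n) < divergence)
    pieces: List[str] = []
    variants: List[Variant] = []
    cursor = 0
    out_len = 0
    for pos in hits:
        if pos < cursor:  # swallowed by a previous deletion
            continue
        pieces.append(ancestor[cursor:pos])
        out_len += pos - cursor
        cursor = pos
        if rng.random() < indel_fraction:
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:  # insertion before ancestor[pos]
                ins = "".join(_BASES[i] for i in rng.integers(0, 4, size=size))
                pieces.append(ins)
                variants.append(Variant(hap_id, out_len, "", ins, "ins"))
                out_len += size
            else:  # deletion of ancestor[pos:pos+size]
                size = min(size, n - pos)
                variants.append(Variant(hap_id, out_len, ancestor[pos:pos + size], "", "del"))
                cursor = pos + size
        else:
            ref = ancestor[pos]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            pieces.append(alt)
            variants.append(Variant(hap_id, out_len, ref, alt, "snp"))
            out_len += 1
            cursor = pos + 1
    pieces.append(ancestor[cursor:])
    return "".join(pieces), variants


def simulate_haplotypes(
    ancestor_len: int,
    n_haplotypes: int,
    divergence: float,
    indel_fraction: float = 0.1,
    seed: int = 0,
    long_cov: float = 10.0,
    short_cov: float = 10.0,
    abundance: str = "uniform",
    abundance_sigma: float = 0.5,
) -> CommunityTruth:
    """Generate a community of near-identical haplotypes.

    Each haplotype is the random ancestor mutated independently at per-base
    rate ``divergence`` (so the realized pairwise divergence is roughly
    twice that).  ``abundance="lognormal"`` draws per-haplotype coverage
    multipliers from a log-normal distribution (mean-normalized), emulating
    uneven strain abundances; the default is uniform coverage.
    """
    if ancestor_len < 1000:
        raise ValueError("ancestor_len must be >= 1000")
    if not 0.0 <= divergence < 0.2:
        raise ValueError(
            f"divergence {divergence} outside [0, 0.2): beyond this the "
            "haplotypes are no longer near-identical strains"
        )
    rng = np.random.default_rng(seed)
    ancestor = _random_genome(rng, ancestor_len)
    haplotypes: List[SeqRecord] = []
    variant_table: List[Variant] = []
    for h in range(n_haplotypes):
        hap_id = f"hap{h}"
        seq, variants = _mutate(rng, ancestor, hap_id, divergence, indel_fraction)
        haplotypes.append(SeqRecord(hap_id, seq))
        variant_table.extend(variants)
    div = np.zeros((n_haplotypes, n_haplotypes))
    for i in range(n_haplotypes):
        for j in range(i + 1, n_haplotypes):
            a, b = haplotypes[i].seq, haplotypes[j].seq
            d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            div[i, j] = div[j, i] = d / ((len(a) + len(b)) / 2)
    if abundance == "lognormal":
        mult = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_haplotypes)
        mult /= mult.mean()
    elif abundance == "uniform":
        mult = np.ones(n_haplotypes)
    else:
        raise ValueError(f"unknown abundance mode {abundance!r}")
    coverage = {
        rec.id: (long_cov * m, short_cov * m) for rec, m in zip(haplotypes, mult)
    }
    return CommunityTruth(haplotypes, div, coverage, variant_table)


def _inject_errors(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    mix: Tuple[float, float, float],
    tally: Dict[str, int],
) -> str:
    """Inject per-base errors; 1 bp insertions/deletions, random substitutions."""
    if rate <= 0.0:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return seq
    kinds = rng.choice(3, size=hits.size, p=list(mix))  # 0 ins, 1 del, 2 sub
    extra = rng.integers(0, 4, size=hits.size)
    pieces: List[str] = []
    cursor = 0
    for pos, kind, x in zip(hits, kinds, extra):
        pieces.append(seq[cursor:pos])
        if kind == 0:
            pieces.append(_BASES[x] + seq[pos])
            tally["ins"] += 1
            cursor = pos + 1
        elif kind == 1:
            tally["del"] += 1
            cursor = pos + 1
        else:
            ref = seq[pos]
            pieces.append(_BASES[(_BASES.index(ref) + 1 + x % 3) % 4])
            tally["sub"] += 1
            cursor = pos + 1
    pieces.append(seq[cursor:])
    return "".join(pieces)


def _draw_reads(
    rng: np.random.Generator,
    hap: SeqRecord,
    coverage: float,
    mean_len: int,
    len_sd_frac: float,
    min_len: int,
    fixed_len: bool,
    err_rate: float,
    err_mix: Tuple[float, float, float],
    prefix: str,
    tally: Dict[str, int],
) -> Tuple[List[SeqRecord], List[TruthPlacement]]:
    L = len(hap.seq)
    target_bases = coverage * L
    reads: List[SeqRecord] = []
    placements: List[TruthPlacement] = []
    total = 0
    i = 0
    qual = max(2, int(round(-10 * math.log10(max(err_rate, 1e-4)))))
    while total < target_bases:
        if fixed_len:
            rlen = min(mean_len, L)
        else:
            rlen = int(rng.normal(mean_len, len_sd_frac * mean_len))
            rlen = max(min_len, min(rlen, L))
        start = int(rng.integers(0, L - rlen + 1))
        end = start + rlen
        strand = "+" if rng.random() < 0.5 else "-"
        frag = hap.seq[start:end]
        if strand == "-":
            frag = reverse_complement(frag)
        seq = _inject_errors(rng, frag, err_rate, err_mix, tally)
        rid = f"{prefix}_{hap.id}_{i}"
        reads.append(SeqRecord(rid, seq, [qual] * len(seq)))
        placements.append(TruthPlacement(rid, hap.id, start, end, strand))
        total += rlen
        i += 1
    return reads, placements


def simulate_reads(
    truth: CommunityTruth,
    params: ReadSimParams,
) -> Tuple[List[SeqRecord], List[SeqRecord], TruthPlacements]:
    """Draw long and short reads from every haplotype.

    Long-read lengths are Normal(mean, 0.2*mean) truncated at 1 kbp; short
    reads have fixed length.  Reads are drawn until the requested coverage
    is reached, from uniformly random positions and strands.  Returns
    (long_reads, short_reads, placements); placements carry source labels
    and aggregate injected-error tallies.
    """
    rng = np.random.default_rng(params.seed)
    long_reads: List[SeqRecord] = []
    short_reads: List[SeqRecord] = []
    placements = TruthPlacements()
    for hap in truth.haplotypes:
        long_cov, short_cov = truth.per_haplotype_coverage[hap.id]
        if long_cov <= 0 or short_cov <= 0:
            raise ValueError(f"non-positive coverage for {hap.id}")
        if long_cov * len(hap.seq) < 1000 or short_cov * len(hap.seq) < params.short_read_len:
            raise ValueError(
                f"coverage for {hap.id} too low to produce any read"
            )
        lr, lp = _draw_reads(
            rng, hap, long_cov, params.long_mean_len, 0.2, 1000, False,
            params.long_err_rate, params.long_err_mix, "long",
            placements.injected["long"],
        )
        sr, sp = _draw_reads(
            rng, hap, short_cov, params.short_read_len, 0.0, params.short_read_len,
            True, params.short_err_rate, params.short_err_mix, "short",
            placements.injected["short"],
        )
        long_reads.extend(lr)
        short_reads.extend(sr)
        placements.extend(lp)
        placements.extend(sp)
    return long_reads, short_reads, placements


def write_truth_tables(truth: CommunityTruth, placements: TruthPlacements,
                       placements_path: str, variants_path: str) -> None:
    """Dump placements and variants as TSV."""
    with open(placements_path, "wt") as out:
        out.write("read_id\thap_id\tstart\tend\tstrand\n")
        for p in placements:
            out.write(f"{p.read_id}\t{p.hap_id}\t{p.start}\t{p.end}\t{p.strand}\n")
    with open(variants_path, "wt") as out:
        out.write("hap_id\tpos\tref\talt\tkind\n")
        for v in truth.variant_table:
            out.write(f"{v.hap_id}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.kind}\n")
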