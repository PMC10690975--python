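"""Sequence and alignment file I/O.

Conventions used throughout the package:

* all coordinates are 0-based, half-open;
* sequences are upper-cased on ingest and ``U`` is mapped to ``T``;
* FASTQ qualities are phred+33;
* corrected reads are written as FASTA (qualities are not propagated
  through correction).
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from Bio import SeqIO


class ParseError(ValueError):
    """Raised when a sequence or alignment file cannot be parsed."""


_ALLOWED = set("ACGTN")
_TRANS = str.maketrans("acgtunU", "ACGTTNT")


@dataclass
class SeqRecord:
    """One read or haplotype sequence.

    Attributes
    ----------
    id : str
        Identifier, unique within a file.
    seq : str
        Sequence over the alphabet ``{A, C, G, T, N}``.
    quals : list of int, optional
        Per-base phred scores, same length as ``seq``.
    """

    id: str
    seq: str
    quals: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: {len(self.quals)} quality values for "
                f"{len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class PafRecord:
    """One line of a PAF (pairwise mapping) file.

    Coordinates are 0-based half-open on both query and target; for
    reverse-strand hits they are still given on the forward strand of both
    sequences, per the PAF convention.  The optional ``cg`` field carries
    the cg:Z: CIGAR tag when present.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    aln_len: int
    mapq: int
    cg: Optional[str] = None

    def __post_init__(self) -> None:
        for label, start, end, length in (
            ("query", self.query_start, self.query_end, self.query_len),
            ("target", self.target_start, self.target_end, self.target_len),
        ):
            if not (0 <= start < end <= length):
                raise ValueError(
                    f"PAF {label} interval [{start}, {end}) out of bounds "
                    f"for length {length}"
                )
        if self.strand not in "+-":
            raise ValueError(f"invalid PAF strand {self.strand!r}")
        if self.n_matches > self.aln_len:
            raise ValueError("n_matches exceeds alignment length")


def _open_maybe_gzip(path: str, mode: str = "rt"):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def _sniff_format(handle) -> Optional[str]:
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            return None
        if line.strip():
            handle.seek(pos)
            break
    first = line.lstrip()[0]
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"unrecognized sequence format (first record starts with {first!r})")


def _clean_seq(record_id: str, seq: str) -> str:
    seq = seq.translate(_TRANS)
    bad = set(seq) - _ALLOWED
    if bad:
        raise ParseError(
            f"record {record_id!r} contains invalid characters: {sorted(bad)}"
        )
    return seq


def read_seq_file(path: str) -> List[SeqRecord]:
    """Read a FASTA or FASTQ file (optionally gzip-compressed).

    The format is auto-detected from the first record.  Sequences are
    upper-cased and ``U`` is mapped to ``T``.  Duplicate identifiers and
    malformed records raise :class:`ParseError`.
    """
    handle = _open_maybe_gzip(path)
    try:
        fmt = _sniff_format(handle)
        if fmt is None:
            return []
        records: List[SeqRecord] = []
        seen = set()
        try:
            for i, rec in enumerate(SeqIO.parse(handle, fmt)):
                if rec.id in seen:
                    raise ParseError(
                        f"{path}: duplicate record id {rec.id!r} (record {i + 1})"
                    )
                seen.add(rec.id)
                quals = None
                if fmt == "fastq":
                    quals = list(rec.letter_annotations["phred_quality"])
                records.append(SeqRecord(rec.id, _clean_seq(rec.id, str(rec.seq)), quals))
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(
                f"{path}: malformed {fmt} near record {len(records) + 1}: {exc}"
            ) from exc
        return records
    finally:
        handle.close()


def write_seq_file(records: Sequence[SeqRecord], path: str, fmt: Optional[str] = None) -> None:
    """Write records as FASTA or FASTQ (gzip if the path ends in ``.gz``).

    When ``fmt`` is None it is inferred from the file name; FASTQ output
    requires qualities on every record.
    """
    if fmt is None:
        stem = path[:-3] if path.endswith(".gz") else path
        ext = os.path.splitext(stem)[1].lower()
        fmt = "fastq" if ext in (".fastq", ".fq") else "fasta"
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as out:
        for rec in records:
            if fmt == "fasta":
                out.write(f">{rec.id}\n{rec.seq}\n")
            else:
                if rec.quals is None:
                    raise ValueError(f"record {rec.id!r} has no qualities for FASTQ output")
                qual = "".join(chr(min(q, 93) + 33) for q in rec.quals)
                out.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def parse_paf(path: str) -> List[PafRecord]:
    """Parse a PAF file into :class:`PafRecord` objects.

    Requires the 12 mandatory columns; the cg:Z: tag is retained when
    present.  Non-numeric coordinates raise :class:`ParseError` with the
    offending line number.
    """
    records: List[PafRecord] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 PAF columns, got {len(fields)}")
            cg = None
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cg = tag[5:]
            try:
                rec = PafRecord(
                    query_id=fields[0],
                    query_len=int(fields[1]),
                    query_start=int(fields[2]),
                    query_end=int(fields[3]),
                    strand=fields[4],
                    target_id=fields[5],
                    target_len=int(fields[6]),
                    target_start=int(fields[7]),
                    target_end=int(fields[8]),
                    n_matches=int(fields[9]),
                    aln_len=int(fields[10]),
                    mapq=int(fields[11]),
                    cg=cg,
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_paf(records: Sequence[PafRecord], path: str) -> None:
    """Write PAF records, appending a cg:Z: tag where one is present."""
    with open(path, "wt") as out:
        for r in records:
            fields = [
                r.query_id,
                str(r.query_len),
                str(r.query_start),
                str(r.query_end),
                r.strand,
                r.target_id,
                str(r.target_len),
                str(r.target_start),
                str(r.target_end),
                str(r.n_matches),
                str(r.aln_len),
                str(r.mapq),
            ]
            if r.cg is not None:
                fields.append(f"cg:Z:{r.cg}")
            out.write("\t".join(fields) + "\n")


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A, C, G, T, N}``."""
    return seq.translate(_COMP)[::-1]
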