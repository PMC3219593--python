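"""Sequence model: reads, reverse complement, numeric k-mer coding, read I/O.

All coordinates are 0-based, end-exclusive.  The nucleotide alphabet is
{A, C, G, T, N}; N marks ambiguous bases and is excluded from every numeric
k-mer, so N positions can only ever be stored as plaintext letters.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Literal

from Bio import SeqIO

#: Fixed letter -> radix-4 digit map, recorded in the archive header.
LETTER_MAP = "ACGT"
_DIGITS = {c: i for i, c in enumerate(LETTER_MAP)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class SequenceError(ValueError):
    """Raised for malformed sequences or records."""


@dataclass(frozen=True)
class Read:
    """One DNA read with its original dataset ordinal."""

    id: int
    seq: str
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", len(self.seq))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    bad = set(seq) - _VALID
    if bad:
        raise SequenceError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_value(seq: str, pos: int, k: int) -> int | None:
    """Radix-4 value of seq[pos:pos+k] under A=0, C=1, G=2, T=3.

    Returns None when the window contains N (such windows produce no seed).
    Raises for out-of-bounds windows.
    """
    if pos < 0 or pos + k > len(seq):
        raise SequenceError(f"k-mer window [{pos}, {pos + k}) out of bounds for length {len(seq)}")
    value = 0
    for c in seq[pos : pos + k]:
        d = _DIGITS.get(c)
        if d is None:
            if c == "N":
                return None
            raise SequenceError(f"invalid character {c!r} in sequence")
        value = (value << 2) | d
    return value


def kmer_scan(seq: str, k: int) -> Iterator[tuple[int, int]]:
    """Yield (offset, value) for every N-free k-mer window, via a rolling hash."""
    n = len(seq)
    if k < 1 or n < k:
        return
    mask = (1 << (2 * k)) - 1
    value = 0
    valid = 0  # number of consecutive non-N digits ending at the current position
    for i, c in enumerate(seq):
        d = _DIGITS.get(c)
        if d is None:
            if c != "N":
                raise SequenceError(f"invalid character {c!r} in sequence")
            value = 0
            valid = 0
            continue
        value = ((value << 2) | d) & mask
        valid += 1
        if valid >= k:
            yield i - k + 1, value


def _open_text(path: str | Path) -> IO[str]:
    # Accept plain or gzip-compressed containers, sniffed from the magic bytes.
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle: IO[str]) -> Literal["fasta", "fastq"]:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SequenceError("cannot determine file format: expected '>' (FASTA) or '@' (FASTQ)")


def read_sequences(
    path: str | Path,
    format: Literal["fasta", "fastq"] | None = None,
    invalid: Literal["error", "mask"] = "error",
) -> Iterator[Read]:
    """Stream reads from a FASTA/FASTQ file (optionally gzip-compressed).

    Reads are yielded in file order with ids 0, 1, 2, ...; FASTQ quality
    values are discarded.  Characters outside {A,C,G,T,N} (after uppercasing)
    either raise a :class:`SequenceError` naming the record, or are replaced
    by N when ``invalid="mask"``.
    """
    handle = _open_text(path)
    try:
        if format is None:
            format = _sniff_format(handle)
        for idx, rec in enumerate(SeqIO.parse(handle, format)):
            seq = str(rec.seq).upper()
            bad = set(seq) - _VALID
            if bad:
                if invalid == "mask":
                    seq = "".join(c if c in _VALID else "N" for c in seq)
                else:
                    raise SequenceError(
                        f"record {idx} ({rec.id}): invalid characters {sorted(bad)}"
                    )
            yield Read(id=idx, seq=seq)
    except ValueError as exc:  # biopython parse failure
        if isinstance(exc, SequenceError):
            raise
        raise SequenceError(f"malformed {format} input: {exc}") from exc
    finally:
        handle.close()


def write_fasta(reads: Iterator[Read] | list[Read], path: str | Path, width: int = 0) -> int:
    """Write reads as multi-FASTA with headers ``>read_<original id>``.

    ``width`` = 0 writes each sequence on one line.  Returns the read count.
    """
    n = 0
    with open(path, "w") as out:
        for read in reads:
            out.write(f">read_{read.id}\n")
            if width > 0:
                for i in range(0, len(read.seq), width):
                    out.write(read.seq[i : i + width] + "\n")
            else:
                out.write(read.seq + "\n")
            n += 1
    return n
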