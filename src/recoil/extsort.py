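"""Bounded-memory external merge sort over record streams.

Records accumulate in an in-memory chunk of at most ``chunk_limit`` records;
full chunks are sorted and spilled to temporary files, which are then k-way
merged with ``heapq.merge``.  The output is identical for every chunk_limit
(ties are broken by the full record, so the order is total as long as records
are comparable tuples).

Spill files hold flat binary records: fixed-width little-endian structs for
integer tuples (seeds, anchors, edges) and length-prefixed payloads for
variable-length records such as reads.
"""

from __future__ import annotations

import heapq
import os
import pickle
import struct
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any, Callable, Iterable, Iterator


class Serializer:
    """Writes/reads one record to/from a binary spill file."""

    def dump(self, record: Any, fh: IO[bytes]) -> None:
        raise NotImplementedError

    def load_all(self, fh: IO[bytes]) -> Iterator[Any]:
        raise NotImplementedError


class StructSerializer(Serializer):
    """Fixed-width little-endian tuples of unsigned integers."""

    def __init__(self, fmt: str):
        if not fmt.startswith("<"):
            fmt = "<" + fmt
        self._struct = struct.Struct(fmt)

    @property
    def record_size(self) -> int:
        return self._struct.size

    def dump(self, record: tuple, fh: IO[bytes]) -> None:
        fh.write(self._struct.pack(*record))

    def load_all(self, fh: IO[bytes]) -> Iterator[tuple]:
        size = self._struct.size
        unpack = self._struct.unpack
        while True:
            buf = fh.read(size)
            if not buf:
                return
            if len(buf) != size:
                raise IOError("truncated spill file")
            yield unpack(buf)


class PickleSerializer(Serializer):
    """Length-prefixed pickled records; handles arbitrary variable-size tuples."""

    def dump(self, record: Any, fh: IO[bytes]) -> None:
        blob = pickle.dumps(record, protocol=pickle.HIGHEST_PROTOCOL)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)

    def load_all(self, fh: IO[bytes]) -> Iterator[Any]:
        while True:
            head = fh.read(4)
            if not head:
                return
            (n,) = struct.unpack("<I", head)
            blob = fh.read(n)
            if len(blob) != n:
                raise IOError("truncated spill file")
            yield pickle.loads(blob)


@dataclass
class SortStats:
    """Instrumentation for the bounded-memory contract."""

    peak_resident_records: int = 0
    chunks_spilled: int = 0
    records_in: int = 0
    spill_bytes: int = 0

    def observe(self, resident: int) -> None:
        if resident > self.peak_resident_records:
            self.peak_resident_records = resident


def external_sort(
    records: Iterable[Any],
    chunk_limit: int,
    key: Callable[[Any], Any] | None = None,
    serializer: Serializer | None = None,
    tmpdir: str | Path | None = None,
    stats: SortStats | None = None,
) -> Iterator[Any]:
    """Yield ``records`` in sorted order using at most ``chunk_limit`` resident records.

    Ties under ``key`` are broken by the full record so the total order (and
    therefore the output stream) is independent of chunk_limit.
    """
    if chunk_limit < 2:
        raise ValueError("chunk_limit must be >= 2")
    serializer = serializer or PickleSerializer()
    stats = stats if stats is not None else SortStats()
    full_key = key if key is not None else lambda r: r
    sort_key = (lambda r: (full_key(r), r)) if key is not None else None

    spills: list[str] = []
    chunk: list[Any] = []

    def spill(chunk: list[Any]) -> None:
        chunk.sort(key=sort_key)
        fd, name = tempfile.mkstemp(prefix="recoil-sort-", suffix=".spill", dir=tmpdir and str(tmpdir))
        try:
            with os.fdopen(fd, "wb", buffering=1 << 16) as fh:
                for rec in chunk:
                    serializer.dump(rec, fh)
                stats.spill_bytes += fh.tell()
        except OSError:
            os.unlink(name)
            raise
        spills.append(name)
        stats.chunks_spilled += 1

    try:
        for rec in records:
            chunk.append(rec)
            stats.records_in += 1
            stats.observe(len(chunk))
            if len(chunk) >= chunk_limit:
                spill(chunk)
                chunk = []

        if not spills:
            chunk.sort(key=sort_key)
            yield from chunk
            return
        if chunk:
            spill(chunk)
            chunk = []

        handles = [open(name, "rb", buffering=1 << 16) for name in spills]
        try:
            streams = [serializer.load_all(fh) for fh in handles]
            yield from heapq.merge(*streams, key=sort_key)
        finally:
            for fh in handles:
                fh.close()
    finally:
        for name in spills:
            try:
                os.unlink(name)
            except OSError:
                pass
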