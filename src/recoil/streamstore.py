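"""Append-only on-disk sequence store with a forward-only reader.

Encoder and decoder both walk the BFS-ordered reads with two cursors — the
current read and its parent — whose positions are non-decreasing.  The store
backs the parent cursor with a spill file read strictly forward in batches of
``buffer_records``, so the resident set is one buffer regardless of dataset
size, and backward seeks are structurally impossible (instrumented).
"""

from __future__ import annotations

import os
import struct
import tempfile
from pathlib import Path


class SequentialStore:
    def __init__(self, tmpdir: str | Path | None = None, buffer_records: int = 1024):
        if buffer_records < 1:
            raise ValueError("buffer_records must be >= 1")
        fd, self._path = tempfile.mkstemp(prefix="recoil-store-", suffix=".seq", dir=tmpdir and str(tmpdir))
        self._writer = os.fdopen(fd, "wb", buffering=1 << 16)
        self._reader = open(self._path, "rb", buffering=1 << 16)
        self._buffer_records = buffer_records
        self._buffer: dict[int, str] = {}
        self._next_unread = 0  # first record index not yet loaded
        self.n_appended = 0
        self.max_reader_position = -1  # instrumentation: strictly forward access

    def append(self, seq: str) -> int:
        data = seq.encode("ascii")
        self._writer.write(struct.pack("<I", len(data)))
        self._writer.write(data)
        self.n_appended += 1
        return self.n_appended - 1

    def _load_batch(self) -> None:
        """Buffer the next ``buffer_records`` records from disk, dropping the old batch."""
        self._writer.flush()
        self._buffer.clear()
        for _ in range(self._buffer_records):
            if self._next_unread >= self.n_appended:
                break
            head = self._reader.read(4)
            (n,) = struct.unpack("<I", head)
            self._buffer[self._next_unread] = self._reader.read(n).decode("ascii")
            self._next_unread += 1

    def get(self, position: int) -> str:
        """Record at ``position``; positions must be non-decreasing across calls."""
        if position >= self.n_appended:
            raise IndexError(f"record {position} not yet appended")
        if position < self.max_reader_position:
            raise AssertionError(
                f"backward read: position {position} after {self.max_reader_position}"
            )
        self.max_reader_position = position
        while position not in self._buffer:
            if position < self._next_unread:
                # still wanted but already evicted with the previous batch
                raise AssertionError(f"record {position} evicted before use")
            self._load_batch()
        return self._buffer[position]

    def close(self) -> None:
        try:
            self._writer.close()
            self._reader.close()
        finally:
            try:
                os.unlink(self._path)
            except OSError:
                pass

    def __enter__(self) -> "SequentialStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
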