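"""The .recoil archive container.

Layout (all integers little-endian or LEB128 varints):

    magic          4 bytes  b"RCL1"
    version        u8       (currently 1)
    codec          u8       0=none 1=zlib 2=bz2 3=lzma
    k_graph        u8
    k_encode       u8
    letter map     4 bytes  ASCII, digit order (default b"ACGT")
    n_reads        varint
    top_seeds      varint   (t)
    anchor_cap     varint
    letter_cost    varint   bits per plaintext nucleotide
    mem_record_cost varint  bits charged per MEM record in the gain model
    flags          u8       bit0: original-order permutation stored
    n_streams      varint
    per stream:    u8 name length, name bytes, varint raw length,
                   varint compressed length
    stream blobs, concatenated in table order

Each stream is compressed independently by the chosen codec, so the decoder
can open them concurrently and scan each strictly forward.
"""

from __future__ import annotations

import bz2
import lzma
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

from recoil.varint import encode_uvarint

MAGIC = b"RCL1"
VERSION = 1

CODEC_IDS = {"none": 0, "zlib": 1, "bz2": 2, "lzma": 3}
CODEC_NAMES = {v: k for k, v in CODEC_IDS.items()}
CODECS = tuple(CODEC_IDS)

FLAG_HAS_PERMUTATION = 1


class ArchiveError(ValueError):
    """Malformed, truncated, or unsupported archive."""


def _compress(blob: bytes, codec: str) -> bytes:
    if codec == "none":
        return blob
    if codec == "zlib":
        return zlib.compress(blob, 9)
    if codec == "bz2":
        return bz2.compress(blob, 9)
    if codec == "lzma":
        return lzma.compress(blob, preset=6)
    raise ArchiveError(f"unknown codec {codec!r}")


def _decompress(blob: bytes, codec: str) -> bytes:
    try:
        if codec == "none":
            return blob
        if codec == "zlib":
            return zlib.decompress(blob)
        if codec == "bz2":
            return bz2.decompress(blob)
        if codec == "lzma":
            return lzma.decompress(blob)
    except Exception as exc:
        raise ArchiveError(f"corrupt {codec} stream: {exc}") from exc
    raise ArchiveError(f"unknown codec {codec!r}")


@dataclass
class ArchiveMeta:
    n_reads: int
    k_graph: int = 15
    k_encode: int = 10
    letter_map: str = "ACGT"
    codec: str = "lzma"
    top_seeds: int = 8
    anchor_cap: int = 80
    letter_cost: int = 2
    mem_record_cost: int = 20
    has_permutation: bool = True


@dataclass
class Archive:
    meta: ArchiveMeta
    streams: dict[str, bytes] = field(default_factory=dict)

    def stream_sizes(self) -> dict[str, int]:
        return {name: len(blob) for name, blob in self.streams.items()}


def write_archive(archive: Archive, path: str | Path) -> dict[str, int]:
    """Serialize to ``path``; returns per-stream compressed sizes."""
    meta = archive.meta
    if meta.codec not in CODEC_IDS:
        raise ArchiveError(f"unknown codec {meta.codec!r}")
    if len(meta.letter_map) != 4:
        raise ArchiveError("letter map must name exactly 4 nucleotides")
    header = bytearray()
    header += MAGIC
    header += struct.pack("<BBBB", VERSION, CODEC_IDS[meta.codec], meta.k_graph, meta.k_encode)
    header += meta.letter_map.encode("ascii")
    for v in (meta.n_reads, meta.top_seeds, meta.anchor_cap, meta.letter_cost, meta.mem_record_cost):
        encode_uvarint(v, header)
    header.append(FLAG_HAS_PERMUTATION if meta.has_permutation else 0)

    names = list(archive.streams)
    blobs = [_compress(archive.streams[name], meta.codec) for name in names]
    encode_uvarint(len(names), header)
    for name, blob in zip(names, blobs):
        raw = archive.streams[name]
        nb = name.encode("ascii")
        header.append(len(nb))
        header += nb
        encode_uvarint(len(raw), header)
        encode_uvarint(len(blob), header)

    with open(path, "wb") as fh:
        fh.write(header)
        for blob in blobs:
            fh.write(blob)
    return {name: len(blob) for name, blob in zip(names, blobs)}


class _Cursor:
    def __init__(self, data: bytes):
        self.data = data
        self.pos = 0

    def take(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ArchiveError("truncated archive")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def uvarint(self) -> int:
        value = 0
        shift = 0
        while True:
            byte = self.take(1)[0]
            value |= (byte & 0x7F) << shift
            if not byte & 0x80:
                return value
            shift += 7


def read_archive(path: str | Path) -> Archive:
    with open(path, "rb") as fh:
        data = fh.read()
    cur = _Cursor(data)
    if cur.take(4) != MAGIC:
        raise ArchiveError("not a recoil archive (bad magic)")
    version, codec_id, k_graph, k_encode = struct.unpack("<BBBB", cur.take(4))
    if version != VERSION:
        raise ArchiveError(f"unsupported archive version {version}")
    if codec_id not in CODEC_NAMES:
        raise ArchiveError(f"unknown codec id {codec_id}")
    letter_map = cur.take(4).decode("ascii")
    n_reads = cur.uvarint()
    top_seeds = cur.uvarint()
    anchor_cap = cur.uvarint()
    letter_cost = cur.uvarint()
    mem_record_cost = cur.uvarint()
    flags = cur.take(1)[0]
    meta = ArchiveMeta(
        n_reads=n_reads,
        k_graph=k_graph,
        k_encode=k_encode,
        letter_map=letter_map,
        codec=CODEC_NAMES[codec_id],
        top_seeds=top_seeds,
        anchor_cap=anchor_cap,
        letter_cost=letter_cost,
        mem_record_cost=mem_record_cost,
        has_permutation=bool(flags & FLAG_HAS_PERMUTATION),
    )
    n_streams = cur.uvarint()
    table: list[tuple[str, int, int]] = []
    for _ in range(n_streams):
        name_len = cur.take(1)[0]
        name = cur.take(name_len).decode("ascii")
        raw_len = cur.uvarint()
        comp_len = cur.uvarint()
        table.append((name, raw_len, comp_len))
    streams: dict[str, bytes] = {}
    for name, raw_len, comp_len in table:
        blob = _decompress(cur.take(comp_len), meta.codec)
        if len(blob) != raw_len:
            raise ArchiveError(f"stream {name!r}: expected {raw_len} bytes, got {len(blob)}")
        streams[name] = blob
    return Archive(meta=meta, streams=streams)
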