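"""Variable-length integers, zig-zag mapping, and difference coding.

Difference coding stores the first value verbatim and then zig-zag-mapped
successive deltas, each as an LEB128-style varint; it shrinks the numeric
ranges of the archive's integer streams before the final entropy stage.
"""

from __future__ import annotations

from typing import Iterable, Iterator


def encode_uvarint(value: int, out: bytearray) -> None:
    if value < 0:
        raise ValueError("uvarint requires a non-negative integer")
    while True:
        byte = value & 0x7F
        value >>= 7
        if value:
            out.append(byte | 0x80)
        else:
            out.append(byte)
            return


def uvarint_len(value: int) -> int:
    n = 1
    while value > 0x7F:
        value >>= 7
        n += 1
    return n


def decode_uvarints(data: bytes | memoryview) -> Iterator[int]:
    value = 0
    shift = 0
    pending = False
    for byte in data:
        value |= (byte & 0x7F) << shift
        if byte & 0x80:
            shift += 7
            pending = True
        else:
            yield value
            value = 0
            shift = 0
            pending = False
    if pending:
        raise ValueError("truncated varint stream")


def zigzag(n: int) -> int:
    return (n << 1) if n >= 0 else ((-n) << 1) - 1


def unzigzag(z: int) -> int:
    return (z >> 1) if not z & 1 else -((z + 1) >> 1)


def pack_uvarints(values: Iterable[int]) -> bytes:
    out = bytearray()
    for v in values:
        encode_uvarint(v, out)
    return bytes(out)


def difference_code(values: Iterable[int]) -> bytes:
    """First value verbatim, then zig-zag deltas, all as varints."""
    out = bytearray()
    prev = None
    for v in values:
        if v < 0:
            raise ValueError("difference_code requires non-negative values")
        if prev is None:
            encode_uvarint(v, out)
        else:
            encode_uvarint(zigzag(v - prev), out)
        prev = v
    return bytes(out)


def difference_decode(data: bytes | memoryview) -> list[int]:
    values: list[int] = []
    for z in decode_uvarints(data):
        if not values:
            values.append(z)
        else:
            values.append(values[-1] + unzigzag(z))
    if any(v < 0 for v in values):
        raise ValueError("difference stream decoded to a negative value")
    return values
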