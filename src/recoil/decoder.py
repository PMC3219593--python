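"""Streaming decompression.

Reads are decoded in BFS order: the root is emitted verbatim, every other
read is rebuilt by copying its MEM spans out of its already-decoded parent
(or the parent's reverse complement) and interleaving the plaintext letters.
Parent positions are non-decreasing along the BFS order, so the decoded-read
store is scanned strictly forward; a final external sort on the stored
permutation restores the original dataset order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

from recoil.archive import Archive, ArchiveError, read_archive
from recoil.encoder import MODE_EXPLICIT, MODE_FORWARD, MODE_REVCOMP, ReadEncoding, iter_encodings
from recoil.extsort import external_sort
from recoil.sequence import Read, reverse_complement
from recoil.streamstore import SequentialStore
from recoil.varint import difference_decode


class IntegrityError(ValueError):
    """Archive streams are mutually inconsistent."""


def reconstruct_read(encoding: ReadEncoding, parent: str) -> str:
    """Rebuild one read from its encoding and its (fully decoded) parent."""
    if encoding.mode == MODE_EXPLICIT:
        if len(encoding.plaintext) != encoding.read_len:
            raise IntegrityError("explicit read length disagrees with plaintext")
        return encoding.plaintext
    if encoding.mode == MODE_REVCOMP:
        parent = reverse_complement(parent)
    elif encoding.mode != MODE_FORWARD:
        raise IntegrityError(f"unknown encoding mode {encoding.mode}")
    out: list[str] = []
    plain = encoding.plaintext
    pcur = 0
    dcur = 0
    for mem in encoding.mems:
        if mem.start_in_dest < dcur:
            raise IntegrityError("MEM chain overlaps in destination")
        gap = mem.start_in_dest - dcur
        out.append(plain[pcur : pcur + gap])
        pcur += gap
        if mem.source_end > len(parent) or mem.start_in_source < 0:
            raise IntegrityError("MEM span exceeds parent length")
        out.append(parent[mem.start_in_source : mem.source_end])
        dcur = mem.dest_end
    out.append(plain[pcur:])
    seq = "".join(out)
    if len(seq) != encoding.read_len:
        raise IntegrityError(
            f"decoded length {len(seq)} != recorded read length {encoding.read_len}"
        )
    return seq


def decode_bfs(
    archive: Archive, tmpdir: str | Path | None = None, buffer_records: int = 1024
) -> Iterator[str]:
    """Yield decoded sequences in BFS (archive) order."""
    with SequentialStore(tmpdir=tmpdir, buffer_records=buffer_records) as store:
        parent_positions = _parent_positions(archive)
        for i, enc in enumerate(iter_encodings(archive)):
            try:
                if enc.mode == MODE_EXPLICIT:
                    seq = reconstruct_read(enc, "")
                else:
                    seq = reconstruct_read(enc, store.get(parent_positions[i]))
            except (IntegrityError, AssertionError, IndexError) as exc:
                raise IntegrityError(f"BFS read {i}: {exc}") from exc
            store.append(seq)
            yield seq


def _parent_positions(archive: Archive) -> list[int]:
    """Parent BFS position per read (root: 0), difference-decoded and validated."""
    if "parents" not in archive.streams:
        raise IntegrityError("archive is missing the parents stream")
    parents = difference_decode(archive.streams["parents"])
    for i, p in enumerate(parents):
        if i > 0 and p >= i:
            raise IntegrityError(f"BFS read {i}: parent position {p} not strictly earlier")
    return parents


def decode_archive(
    path: str | Path,
    tmpdir: str | Path | None = None,
    buffer_records: int = 1024,
    restore_order: bool = True,
    chunk_limit: int = 1_000_000,
) -> Iterator[Read]:
    """Stream-decode an archive into reads.

    With ``restore_order`` (and a stored permutation) reads come out carrying
    their original dataset ids, in original order, via an external sort keyed
    by original id; otherwise they come out in BFS order with ids 0,1,2,...
    """
    archive = read_archive(path)
    n = archive.meta.n_reads
    if n == 0:
        return
    if archive.meta.has_permutation:
        perm = difference_decode(archive.streams["perm"])
        if sorted(perm) != list(range(n)):
            raise IntegrityError("permutation stream is not a permutation of read ids")
    else:
        perm = list(range(n))

    decoded = zip(perm, decode_bfs(archive, tmpdir=tmpdir, buffer_records=buffer_records))
    if restore_order and archive.meta.has_permutation:
        ordered = external_sort(decoded, chunk_limit=chunk_limit, key=lambda rec: rec[0], tmpdir=tmpdir)
    else:
        ordered = ((i, seq) for i, (_, seq) in enumerate(decoded))
    for orig_id, seq in ordered:
        yield Read(id=orig_id, seq=seq)
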