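"""MEM finding, gain-optimal chaining, and dataset encoding.

A read is stored as a chain of maximal exact matches (MEMs) into its parent
in the encoding tree (or into the parent's reverse complement, whichever is
smaller), plus the plaintext letters the chain leaves uncovered.  MEMs are
found by merging shared k-mer hits sorted by diagonal; the chain is selected
by dynamic programming that maximizes the space gained, the sparse-alignment
objective under an affine gap cost where opening a gap costs one MEM record
and every uncovered letter costs ``letter_cost`` bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

from recoil.archive import Archive, ArchiveMeta
from recoil.graph import EncodingTree
from recoil.sequence import kmer_scan, reverse_complement
from recoil.streamstore import SequentialStore
from recoil.varint import difference_code, pack_uvarints

MODE_EXPLICIT = 0
MODE_FORWARD = 1
MODE_REVCOMP = 2

STREAM_NAMES = (
    "lengths",
    "modes",
    "parents",
    "mem_counts",
    "mem_src",
    "mem_dgap",
    "mem_len",
    "plaintext",
    "perm",
)


class MemMatch(NamedTuple):
    """An exact match dest[start_in_dest:+length] == source[start_in_source:+length]."""

    start_in_source: int
    start_in_dest: int
    length: int

    @property
    def source_end(self) -> int:
        return self.start_in_source + self.length

    @property
    def dest_end(self) -> int:
        return self.start_in_dest + self.length


@dataclass(frozen=True)
class GainModel:
    """Space accounting for the chaining objective.

    ``mem_record_cost`` is the bits charged for one stored MEM record (the
    gap-open penalty); ``letter_cost`` is bits per plaintext nucleotide (the
    gap-extension penalty).  A MEM of length L saves ``L*letter_cost -
    mem_record_cost`` bits, so the shortest profitable MEM is
    ceil(mem_record_cost / letter_cost) nucleotides.
    """

    letter_cost: int = 2
    mem_record_cost: int = 20

    @property
    def min_profitable_mem(self) -> int:
        return math.ceil(self.mem_record_cost / self.letter_cost)

    def gain(self, length: int) -> int:
        return length * self.letter_cost - self.mem_record_cost

    @staticmethod
    def for_k(k: int, letter_cost: int = 2) -> "GainModel":
        """Default model: the profitability threshold coincides with the seed length."""
        return GainModel(letter_cost=letter_cost, mem_record_cost=letter_cost * k)


@dataclass
class ReadEncoding:
    read_len: int
    mode: int  # MODE_EXPLICIT / MODE_FORWARD / MODE_REVCOMP
    mems: list[MemMatch] = field(default_factory=list)
    plaintext: str = ""

    def validate(self) -> None:
        covered = sum(m.length for m in self.mems)
        if covered + len(self.plaintext) != self.read_len:
            raise ValueError(
                f"encoding inconsistent: {covered} MEM + {len(self.plaintext)} plaintext "
                f"!= read_len {self.read_len}"
            )

    def encoded_bits(self, model: GainModel) -> int:
        return len(self.mems) * model.mem_record_cost + len(self.plaintext) * model.letter_cost


def find_mems(source: str, dest: str, k: int) -> list[MemMatch]:
    """All maximal exact matches of length >= k between source and dest.

    Shared k-mer hits are sorted by (diagonal, position) so the hits of one
    MEM are consecutive; each new hit is extended maximally in both directions
    by direct comparison and later hits inside the extended match are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index: dict[int, list[int]] = {}
    for off, value in kmer_scan(source, k):
        index.setdefault(value, []).append(off)
    hits: list[tuple[int, int]] = []  # (r1 in source, r2 in dest)
    for off2, value in kmer_scan(dest, k):
        for off1 in index.get(value, ()):
            hits.append((off1, off2))
    hits.sort(key=lambda h: (h[0] - h[1], h[0]))

    mems: list[MemMatch] = []
    covered_end = 0
    diag = None
    ns, nd = len(source), len(dest)
    for r1, r2 in hits:
        d = r1 - r2
        if d != diag:
            diag = d
            covered_end = 0
        if r1 < covered_end:
            continue
        s, t = r1, r2
        while s > 0 and t > 0 and source[s - 1] == dest[t - 1]:
            s -= 1
            t -= 1
        e1, e2 = r1 + k, r2 + k
        while e1 < ns and e2 < nd and source[e1] == dest[e2]:
            e1 += 1
            e2 += 1
        covered_end = e1
        mems.append(MemMatch(s, t, e1 - s))
    mems.sort(key=lambda m: (m.start_in_dest, m.start_in_source))
    return mems


def trim_to_follow(mem: MemMatch, prev: MemMatch) -> MemMatch | None:
    """Shrink ``mem`` from the left so it overlaps ``prev`` in neither string.

    Returns None when nothing of the match survives.
    """
    overlap = max(0, prev.dest_end - mem.start_in_dest, prev.source_end - mem.start_in_source)
    if overlap == 0:
        return mem
    if overlap >= mem.length:
        return None
    return MemMatch(mem.start_in_source + overlap, mem.start_in_dest + overlap, mem.length - overlap)


def chain_mems(mems: list[MemMatch], model: GainModel) -> list[MemMatch]:
    """Gain-maximal MEM chain, strictly increasing in both coordinates.

    O(n^2) dynamic programming over MEMs sorted by destination start (n is the
    MEM count for one read pair, which is small).  Where a MEM overlaps its
    predecessor it is trimmed from the left; a trimmed MEM that stops being
    profitable is simply not chosen.  Returns the chained (possibly trimmed)
    MEMs; empty when no chain has non-negative total gain.
    """
    if not mems:
        return []
    order = sorted(mems, key=lambda m: (m.start_in_dest, m.start_in_source, m.length))
    n = len(order)
    best: list[int] = [0] * n  # best chain gain ending at i
    trimmed: list[MemMatch | None] = [None] * n
    back: list[int] = [-1] * n
    for i, mem in enumerate(order):
        best[i] = model.gain(mem.length)
        trimmed[i] = mem
        for j in range(i):
            cand = trim_to_follow(mem, order[j])
            if cand is None:
                continue
            score = best[j] + model.gain(cand.length)
            if score > best[i]:
                best[i] = score
                trimmed[i] = cand
                back[i] = j
    end = max(range(n), key=lambda i: best[i])
    if best[end] < 0:
        return []
    chain: list[MemMatch] = []
    i = end
    while i != -1:
        chain.append(trimmed[i])  # type: ignore[arg-type]
        i = back[i]
    chain.reverse()
    return chain


def chain_gain(chain: list[MemMatch], model: GainModel) -> int:
    return sum(model.gain(m.length) for m in chain)


def _encode_against(child: str, parent: str, k: int, model: GainModel) -> tuple[list[MemMatch], str]:
    chain = chain_mems(find_mems(parent, child, k), model)
    uncovered = []
    cursor = 0
    for mem in chain:
        uncovered.append(child[cursor : mem.start_in_dest])
        cursor = mem.dest_end
    uncovered.append(child[cursor:])
    return chain, "".join(uncovered)


def encode_read(
    child_seq: str, parent_seq: str, k: int, model: GainModel | None = None
) -> ReadEncoding:
    """Encode one read against its parent, its parent's reverse complement, or explicitly.

    The orientation with the smaller encoded size wins (forward on ties); the
    read falls back to explicit 2-bit-style storage when no MEM chain beats
    it, which covers roots and reads linked only by connectivity chain edges.
    """
    model = model or GainModel.for_k(k)
    explicit = ReadEncoding(len(child_seq), MODE_EXPLICIT, [], child_seq)
    candidates = [explicit]
    fwd_chain, fwd_plain = _encode_against(child_seq, parent_seq, k, model)
    if fwd_chain:
        candidates.append(ReadEncoding(len(child_seq), MODE_FORWARD, fwd_chain, fwd_plain))
    rev_chain, rev_plain = _encode_against(child_seq, reverse_complement(parent_seq), k, model)
    if rev_chain:
        candidates.append(ReadEncoding(len(child_seq), MODE_REVCOMP, rev_chain, rev_plain))
    # explicit only when strictly smaller: zero-gain MEMs still count as profitable,
    # and ties between orientations go to forward
    best = min(candidates, key=lambda enc: (enc.encoded_bits(model), enc.mode == MODE_EXPLICIT, enc.mode))
    best.validate()
    return best


@dataclass
class EncodeStats:
    n_reads: int = 0
    explicit_reads: int = 0
    mem_records: int = 0
    plaintext_letters: int = 0
    raw_bases: int = 0


def encode_dataset(
    bfs_reads: Iterable[tuple[int, str]],
    tree: EncodingTree,
    k: int = 10,
    model: GainModel | None = None,
    buffer_records: int = 1024,
    tmpdir: str | None = None,
    meta: ArchiveMeta | None = None,
    keep_order: bool = True,
) -> tuple[Archive, EncodeStats]:
    """Encode a BFS-ordered read stream along its encoding tree into an archive.

    ``bfs_reads`` yields (original id, sequence) aligned with
    ``tree.bfs_order``.  The child cursor is the input stream itself; the
    parent cursor replays the same records from a spill file strictly forward
    (parent BFS positions are non-decreasing), so memory stays bounded by the
    scan buffers.  The root is always stored explicitly.
    """
    model = model or GainModel.for_k(k)
    stats = EncodeStats()
    lengths: list[int] = []
    modes = bytearray()
    parents: list[int] = []  # parent BFS position per read (root: 0); non-decreasing
    mem_counts: list[int] = []
    mem_src: list[int] = []
    mem_dgap: list[int] = []
    mem_len: list[int] = []
    plaintext: list[str] = []
    perm: list[int] = []

    last_parent_pos = 0
    with SequentialStore(tmpdir=tmpdir, buffer_records=buffer_records) as store:
        for i, (orig_id, seq) in enumerate(bfs_reads):
            if orig_id != tree.bfs_order[i]:
                raise ValueError(
                    f"BFS stream mismatch at position {i}: read {orig_id}, expected {tree.bfs_order[i]}"
                )
            if i == 0:
                enc = ReadEncoding(len(seq), MODE_EXPLICIT, [], seq)
                parents.append(0)
            else:
                parent_pos = tree.position[tree.parent[orig_id]]
                if parent_pos >= i:
                    raise ValueError(f"parent of BFS read {i} lies at or after it ({parent_pos})")
                if parent_pos < last_parent_pos:
                    raise ValueError("parent positions regressed; BFS invariant violated")
                last_parent_pos = parent_pos
                parent_seq = store.get(parent_pos)
                enc = encode_read(seq, parent_seq, k, model)
                parents.append(parent_pos)
            store.append(seq)

            lengths.append(enc.read_len)
            modes.append(enc.mode)
            mem_counts.append(len(enc.mems))
            for mem in enc.mems:
                mem_src.append(mem.start_in_source)
            prev_end = 0
            for mem in enc.mems:
                mem_dgap.append(mem.start_in_dest - prev_end)
                prev_end = mem.dest_end
                mem_len.append(mem.length - 1)
            plaintext.append(enc.plaintext)
            perm.append(orig_id)

            stats.n_reads += 1
            stats.raw_bases += enc.read_len
            stats.mem_records += len(enc.mems)
            stats.plaintext_letters += len(enc.plaintext)
            if enc.mode == MODE_EXPLICIT:
                stats.explicit_reads += 1

    if meta is None:
        meta = ArchiveMeta(n_reads=stats.n_reads, k_encode=k)
    meta.n_reads = stats.n_reads
    meta.letter_cost = model.letter_cost
    meta.mem_record_cost = model.mem_record_cost
    meta.has_permutation = keep_order

    streams: dict[str, bytes] = {
        "lengths": difference_code(lengths),
        "modes": bytes(modes),
        "parents": difference_code(parents),
        "mem_counts": pack_uvarints(mem_counts),
        "mem_src": difference_code(mem_src),
        "mem_dgap": pack_uvarints(mem_dgap),
        "mem_len": pack_uvarints(mem_len),
        "plaintext": "".join(plaintext).encode("ascii"),
    }
    if keep_order:
        streams["perm"] = difference_code(perm)
    return Archive(meta=meta, streams=streams), stats


def iter_encodings(archive: Archive) -> Iterator[ReadEncoding]:
    """Re-materialize the per-read encodings stored in an archive's streams."""
    from recoil.varint import decode_uvarints, difference_decode

    meta = archive.meta
    lengths = difference_decode(archive.streams["lengths"])
    modes = archive.streams["modes"]
    mem_counts = list(decode_uvarints(archive.streams["mem_counts"]))
    srcs = iter(difference_decode(archive.streams["mem_src"]))
    dgaps = decode_uvarints(archive.streams["mem_dgap"])
    lens = decode_uvarints(archive.streams["mem_len"])
    plain = archive.streams["plaintext"].decode("ascii")
    if not (len(lengths) == len(modes) == len(mem_counts) == meta.n_reads):
        raise ValueError("stream lengths disagree with read count")
    cursor = 0
    for i in range(meta.n_reads):
        mems: list[MemMatch] = []
        prev_end = 0
        for _ in range(mem_counts[i]):
            src = next(srcs)
            dst = prev_end + next(dgaps)
            length = next(lens) + 1
            mems.append(MemMatch(src, dst, length))
            prev_end = dst + length
        covered = sum(m.length for m in mems)
        n_plain = lengths[i] - covered
        if n_plain < 0 or cursor + n_plain > len(plain):
            raise ValueError(f"plaintext stream inconsistent at BFS read {i}")
        enc = ReadEncoding(lengths[i], modes[i], mems, plain[cursor : cursor + n_plain])
        cursor += n_plain
        yield enc
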