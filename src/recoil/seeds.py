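"""Seed generation, top-t filtering, and anchor emission.

Every read contributes the k-mers of both its forward sequence and its
reverse complement.  To bound the seed volume per read, only occurrences of
the t largest distinct k-mer values of the read are kept (the Minimus
seed-filtering heuristic); all occurrences of a selected value survive.
Reads that end up in the same run of the value-sorted seed stream share that
seed, and each such run emits read-pair anchors in rings of increasing index
distance, capped per seed value so highly repetitive k-mers cannot blow up
the anchor file quadratically.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Literal, NamedTuple

from recoil.extsort import StructSerializer
from recoil.sequence import Read, kmer_scan, reverse_complement

FORWARD = 0
REVERSE = 1

#: spill-file layout: kmer u64, read_id u32, offset u32, strand u8
SEED_STRUCT = StructSerializer("<QIIB")
#: spill-file layout: read_a u32, read_b u32
ANCHOR_STRUCT = StructSerializer("<II")


class SeedRecord(NamedTuple):
    kmer: int
    read_id: int
    offset: int
    strand: int  # FORWARD or REVERSE; offset is within that strand's string


class Anchor(NamedTuple):
    read_a: int
    read_b: int  # read_a < read_b always


def extract_seeds(
    read: Read,
    k: int,
    t: int,
    top_mode: Literal["distinct", "records"] = "distinct",
) -> list[SeedRecord]:
    """Seeds of a read whose k-mer values are among the read's t topmost.

    ``top_mode="distinct"`` keeps every occurrence of the t largest distinct
    values (the default reading of the top-t filter); ``"records"`` keeps the
    t highest-valued individual occurrences instead.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if t < 1:
        raise ValueError("t must be >= 1")
    records = [
        SeedRecord(value, read.id, off, FORWARD) for off, value in kmer_scan(read.seq, k)
    ]
    records += [
        SeedRecord(value, read.id, off, REVERSE)
        for off, value in kmer_scan(reverse_complement(read.seq), k)
    ]
    if not records:
        return []
    if top_mode == "records":
        records.sort(key=lambda r: (-r.kmer, r.strand, r.offset))
        kept = sorted(records[:t])
        return kept
    values = sorted({r.kmer for r in records}, reverse=True)[:t]
    keep = set(values)
    return sorted(r for r in records if r.kmer in keep)


def iter_all_seeds(
    reads: Iterable[Read], k: int, t: int, top_mode: Literal["distinct", "records"] = "distinct"
) -> Iterator[SeedRecord]:
    for read in reads:
        yield from extract_seeds(read, k, t, top_mode)


def generate_anchors(
    sorted_seeds: Iterable[SeedRecord | tuple], cap_per_seed: int = 80
) -> Iterator[Anchor]:
    """Emit capped read-pair anchors from a value-sorted seed stream.

    Within each run of records sharing a k-mer value, pairs are produced in
    rings of increasing index distance inside the run (all adjacent pairs
    first, then distance two, ...) until ``cap_per_seed`` anchors have been
    emitted for that value.  Pairs are normalized (smaller read id first);
    self-pairs — e.g. a read meeting its own reverse complement — are skipped
    and do not count against the cap.
    """
    if cap_per_seed < 1:
        raise ValueError("cap_per_seed must be >= 1")
    run: list[int] = []
    current = None
    last_kmer = None
    for rec in sorted_seeds:
        kmer, read_id = rec[0], rec[1]
        if last_kmer is not None and kmer < last_kmer:
            raise ValueError("seed stream is not sorted by k-mer value")
        last_kmer = kmer
        if kmer != current:
            yield from _emit_run(run, cap_per_seed)
            run = []
            current = kmer
        run.append(read_id)
    yield from _emit_run(run, cap_per_seed)


def _emit_run(run: list[int], cap: int) -> Iterator[Anchor]:
    n = len(run)
    if n < 2:
        return
    emitted = 0
    for dist in range(1, n):
        for i in range(n - dist):
            a, b = run[i], run[i + dist]
            if a == b:
                continue
            yield Anchor(min(a, b), max(a, b))
            emitted += 1
            if emitted >= cap:
                return
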