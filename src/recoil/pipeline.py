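"""End-to-end compression pipeline: every stage a bounded-memory scan or sort.

    reads ──► seeds (top-t, both strands) ──► external sort by k-mer value
          ──► capped anchors ──► external sort by read pair ──► weighted edges
          (+ weight-0 chain edges) ──► maximum spanning tree ──► BFS rooting
          ──► external sort of reads into BFS order ──► MEM encoding
          ──► difference-coded streams ──► general-purpose codec ──► .recoil
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from recoil.archive import Archive, ArchiveMeta, read_archive, write_archive
from recoil.decoder import decode_archive
from recoil.encoder import EncodeStats, GainModel, MODE_EXPLICIT, encode_dataset, iter_encodings
from recoil.extsort import PickleSerializer, SortStats, external_sort
from recoil.graph import (
    EncodingTree,
    add_chain_edges,
    aggregate_edges,
    maximum_spanning_tree,
    root_and_bfs,
)
from recoil.seeds import ANCHOR_STRUCT, SEED_STRUCT, generate_anchors, iter_all_seeds
from recoil.sequence import Read, read_sequences, write_fasta


@dataclass
class PipelineConfig:
    k_graph: int = 15
    k_encode: int = 10
    top_seeds: int = 8
    anchor_cap: int = 80
    codec: str = "lzma"
    chunk_limit: int = 2_000_000  # records resident per external-sort chunk
    buffer_records: int = 1024  # parent-scan buffer during encoding
    tmpdir: str | None = None
    keep_order: bool = True
    gain_model: GainModel | None = None

    def model(self) -> GainModel:
        return self.gain_model or GainModel.for_k(self.k_encode)


@dataclass
class PipelineReport:
    n_reads: int = 0
    n_seeds: int = 0
    n_anchors: int = 0
    n_edges: int = 0
    encode: EncodeStats = field(default_factory=EncodeStats)
    seed_sort: SortStats = field(default_factory=SortStats)
    anchor_sort: SortStats = field(default_factory=SortStats)
    stream_sizes: dict[str, int] = field(default_factory=dict)
    archive_bytes: int = 0


def build_tree(
    reads_path: str | Path, config: PipelineConfig, n_reads: int
) -> tuple[EncodingTree, PipelineReport]:
    """Similarity graph + maximum spanning tree + BFS order for a read file."""
    report = PipelineReport(n_reads=n_reads)

    def counted_seeds() -> Iterator[tuple]:
        for rec in iter_all_seeds(
            read_sequences(reads_path), config.k_graph, config.top_seeds
        ):
            report.n_seeds += 1
            yield rec

    sorted_seeds = external_sort(
        counted_seeds(),
        chunk_limit=config.chunk_limit,
        serializer=SEED_STRUCT,
        tmpdir=config.tmpdir,
        stats=report.seed_sort,
    )

    def counted_anchors() -> Iterator[tuple]:
        for a in generate_anchors(sorted_seeds, config.anchor_cap):
            report.n_anchors += 1
            yield a

    sorted_anchors = external_sort(
        counted_anchors(),
        chunk_limit=config.chunk_limit,
        serializer=ANCHOR_STRUCT,
        tmpdir=config.tmpdir,
        stats=report.anchor_sort,
    )
    anchor_edges = list(aggregate_edges(sorted_anchors))
    report.n_edges = len(anchor_edges)
    edges = itertools.chain(anchor_edges, add_chain_edges(n_reads))
    tree_edges = maximum_spanning_tree(edges, n_reads)
    tree = root_and_bfs(tree_edges, n_reads, root=0)
    return tree, report


def compress_file(
    reads_path: str | Path,
    archive_path: str | Path,
    config: PipelineConfig | None = None,
) -> PipelineReport:
    """Compress a FASTA/FASTQ read file into a .recoil archive."""
    config = config or PipelineConfig()
    n_input = sum(1 for _ in read_sequences(reads_path))
    if n_input == 0:
        archive = Archive(meta=_meta(config, 0))
        write_archive(archive, archive_path)
        return PipelineReport(n_reads=0, archive_bytes=Path(archive_path).stat().st_size)

    tree, report = build_tree(reads_path, config, n_input)

    bfs_stream = reorder_reads(reads_path, tree, config)
    archive, enc_stats = encode_dataset(
        bfs_stream,
        tree,
        k=config.k_encode,
        model=config.model(),
        buffer_records=config.buffer_records,
        tmpdir=config.tmpdir,
        meta=_meta(config, report.n_reads),
        keep_order=config.keep_order,
    )
    report.encode = enc_stats
    report.stream_sizes = write_archive(archive, archive_path)
    report.archive_bytes = Path(archive_path).stat().st_size
    return report


def _meta(config: PipelineConfig, n_reads: int) -> ArchiveMeta:
    model = config.model()
    return ArchiveMeta(
        n_reads=n_reads,
        k_graph=config.k_graph,
        k_encode=config.k_encode,
        codec=config.codec,
        top_seeds=config.top_seeds,
        anchor_cap=config.anchor_cap,
        letter_cost=model.letter_cost,
        mem_record_cost=model.mem_record_cost,
        has_permutation=config.keep_order,
    )


def reorder_reads(
    reads_path: str | Path, tree: EncodingTree, config: PipelineConfig
) -> Iterator[tuple[int, str]]:
    """Stream reads in BFS order via an external sort keyed by BFS position."""
    position = tree.position

    def keyed() -> Iterator[tuple[int, int, str]]:
        for read in read_sequences(reads_path):
            yield position[read.id], read.id, read.seq

    for _pos, orig_id, seq in external_sort(
        keyed(),
        chunk_limit=config.chunk_limit,
        serializer=PickleSerializer(),
        tmpdir=config.tmpdir,
    ):
        yield orig_id, seq


def decompress_file(
    archive_path: str | Path,
    out_path: str | Path,
    tmpdir: str | None = None,
    buffer_records: int = 1024,
    restore_order: bool = True,
    chunk_limit: int = 2_000_000,
) -> int:
    """Decode an archive to multi-FASTA; returns the number of reads written."""
    reads = decode_archive(
        archive_path,
        tmpdir=tmpdir,
        buffer_records=buffer_records,
        restore_order=restore_order,
        chunk_limit=chunk_limit,
    )
    return write_fasta(reads, out_path)


def archive_stats(archive_path: str | Path) -> dict:
    """Summary of an archive: stream sizes, explicit reads, ratios."""
    archive = read_archive(archive_path)
    raw_bases = 0
    explicit = 0
    mems = 0
    plain = 0
    encodings = iter_encodings(archive) if archive.meta.n_reads else ()
    for enc in encodings:
        raw_bases += enc.read_len
        mems += len(enc.mems)
        plain += len(enc.plaintext)
        if enc.mode == MODE_EXPLICIT:
            explicit += 1
    size = Path(archive_path).stat().st_size
    two_bit = (raw_bases + 3) // 4
    return {
        "n_reads": archive.meta.n_reads,
        "codec": archive.meta.codec,
        "raw_bases": raw_bases,
        "archive_bytes": size,
        "explicit_reads": explicit,
        "mem_records": mems,
        "plaintext_letters": plain,
        "stream_bytes": archive.stream_sizes(),
        "ratio_vs_raw": size / raw_bases if raw_bases else float("nan"),
        "ratio_vs_2bit": size / two_bit if two_bit else float("nan"),
    }
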