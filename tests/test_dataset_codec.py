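"""Dataset-level encode → archive → decode behaviour."""

from __future__ import annotations

import random

import pytest

from conftest import TOY_READS, TOY_TREE_EDGES, random_dna
from recoil.archive import read_archive, write_archive
from recoil.decoder import IntegrityError, decode_archive, decode_bfs, reconstruct_read
from recoil.encoder import (
    GainModel,
    MODE_EXPLICIT,
    MODE_FORWARD,
    MemMatch,
    ReadEncoding,
    encode_dataset,
    iter_encodings,
)
from recoil.graph import root_and_bfs
from recoil.sequence import reverse_complement


def toy_tree():
    return root_and_bfs(TOY_TREE_EDGES, 3, root=0)


def toy_bfs_stream():
    by_id = {r.id: r.seq for r in TOY_READS}
    tree = toy_tree()
    return [(i, by_id[i]) for i in tree.bfs_order], tree


class TestEncodeDataset:
    def test_toy_stream_structure(self):
        bfs, tree = toy_bfs_stream()
        archive, stats = encode_dataset(bfs, tree, k=4, model=GainModel.for_k(4))
        encodings = list(iter_encodings(archive))
        assert stats.explicit_reads == 1
        # root stored explicitly, then one single-MEM encoding per child
        assert encodings[0].mode == MODE_EXPLICIT
        assert encodings[0].plaintext == "ACCGTTA"
        assert [len(e.mems) for e in encodings] == [0, 1, 1]
        assert encodings[1].mems == [MemMatch(3, 0, 4)]
        assert encodings[2].mems == [MemMatch(1, 3, 4)]
        assert [len(e.plaintext) for e in encodings[1:]] == [3, 3]
        assert [e.read_len for e in encodings] == [7, 7, 7]

    def test_buffer_size_invariance(self, tmp_path):
        rng = random.Random(17)
        genome = random_dna(rng, 3000)
        seqs = []
        for i in range(400):
            start = rng.randrange(0, len(genome) - 60)
            seqs.append(genome[start : start + 60])
        parent = [0] * 400
        for i in range(1, 400):
            parent[i] = rng.randrange(i)
        tree = root_and_bfs([(min(i, parent[i]), max(i, parent[i]), 1, 0) for i in range(1, 400)], 400, root=0)
        bfs = [(r, seqs[r]) for r in tree.bfs_order]
        archives = []
        for buffer_records in (1, 2, 10**6):
            archive, _ = encode_dataset(list(bfs), tree, k=10, buffer_records=buffer_records)
            path = tmp_path / f"b{buffer_records}.recoil"
            write_archive(archive, path)
            archives.append(path.read_bytes())
        assert archives[0] == archives[1] == archives[2]

    def test_identical_reads_become_full_length_mems(self):
        seq = "ACGGTTACCA" * 4
        n = 6
        tree = root_and_bfs([(i, i + 1, 1, 0) for i in range(n - 1)], n, root=0)
        archive, stats = encode_dataset([(i, seq) for i in range(n)], tree, k=10)
        encodings = list(iter_encodings(archive))
        assert stats.explicit_reads == 1
        for enc in encodings[1:]:
            assert enc.mems == [MemMatch(0, 0, len(seq))]
            assert enc.plaintext == ""

    def test_misordered_stream_rejected(self):
        bfs, tree = toy_bfs_stream()
        bfs[1], bfs[2] = bfs[2], bfs[1]
        with pytest.raises(ValueError, match="BFS stream mismatch"):
            encode_dataset(bfs, tree, k=4)


class TestReconstructRead:
    def test_explicit_verbatim(self):
        enc = ReadEncoding(4, MODE_EXPLICIT, [], "ACGT")
        assert reconstruct_read(enc, "") == "ACGT"

    def test_single_mem_with_plaintext(self):
        enc = ReadEncoding(7, MODE_FORWARD, [MemMatch(3, 0, 4)], "GCA")
        assert reconstruct_read(enc, "ACCGTTA") == "GTTAGCA"

    def test_full_length_mem_copies_parent(self):
        enc = ReadEncoding(7, MODE_FORWARD, [MemMatch(0, 0, 7)], "")
        assert reconstruct_read(enc, "ACCGTTA") == "ACCGTTA"

    def test_revcomp_mode(self):
        parent = "ACCGTTA"
        enc = ReadEncoding(7, 2, [MemMatch(0, 0, 7)], "")
        assert reconstruct_read(enc, parent) == reverse_complement(parent)

    def test_mem_exceeding_parent_rejected(self):
        enc = ReadEncoding(9, MODE_FORWARD, [MemMatch(5, 0, 9)], "")
        with pytest.raises(IntegrityError, match="parent"):
            reconstruct_read(enc, "ACCGTTA")

    def test_length_mismatch_rejected(self):
        enc = ReadEncoding(10, MODE_FORWARD, [MemMatch(0, 0, 4)], "GG")
        with pytest.raises(IntegrityError, match="length"):
            reconstruct_read(enc, "ACCGTTA")


class TestRoundTrip:
    def test_toy_round_trip(self, tmp_path):
        bfs, tree = toy_bfs_stream()
        archive, _ = encode_dataset(bfs, tree, k=4, model=GainModel.for_k(4))
        path = tmp_path / "toy.recoil"
        write_archive(archive, path)
        reads = list(decode_archive(path))
        assert [(r.id, r.seq) for r in reads] == [
            (0, "ACCGTTA"),
            (1, "CCCTTAG"),
            (2, "GTTAGCA"),
        ]

    def test_random_tree_round_trip_restores_order(self, tmp_path):
        rng = random.Random(55)
        genome = random_dna(rng, 5000)
        n = 300
        seqs = []
        for _ in range(n):
            start = rng.randrange(0, len(genome) - 70)
            s = genome[start : start + 70]
            if rng.random() < 0.5:
                s = reverse_complement(s)
            seqs.append(s)
        parent = [rng.randrange(max(i, 1)) for i in range(n)]
        tree = root_and_bfs(
            [(min(i, parent[i]), max(i, parent[i]), 1, 0) for i in range(1, n)], n, root=0
        )
        archive, _ = encode_dataset([(r, seqs[r]) for r in tree.bfs_order], tree, k=10)
        path = tmp_path / "rt.recoil"
        write_archive(archive, path)
        decoded = list(decode_archive(path, buffer_records=3, chunk_limit=16))
        assert [r.id for r in decoded] == list(range(n))
        assert [r.seq for r in decoded] == seqs

    def test_decoder_scans_strictly_forward(self, tmp_path):
        """Parent positions are replayed without backward seeks."""
        bfs, tree = toy_bfs_stream()
        archive, _ = encode_dataset(bfs, tree, k=4, model=GainModel.for_k(4))
        # decode_bfs raises through SequentialStore if any backward read occurs
        seqs = list(decode_bfs(archive))
        assert seqs == [s for _, s in bfs]

    def test_corrupt_parent_stream_names_bfs_index(self, tmp_path):
        bfs, tree = toy_bfs_stream()
        archive, _ = encode_dataset(bfs, tree, k=4, model=GainModel.for_k(4))
        from recoil.varint import difference_code

        archive.streams["parents"] = difference_code([0, 5, 1])
        path = tmp_path / "bad.recoil"
        write_archive(archive, path)
        with pytest.raises(IntegrityError, match="BFS read 1"):
            list(decode_archive(path))

    def test_empty_dataset_round_trip(self, tmp_path):
        from recoil.archive import Archive, ArchiveMeta

        path = tmp_path / "empty.recoil"
        write_archive(Archive(meta=ArchiveMeta(n_reads=0)), path)
        assert list(decode_archive(path)) == []
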