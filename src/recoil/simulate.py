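"""Synthetic short-read datasets for evaluating the compressor.

Reads are uniform random samples of fixed length from a source genome
(a supplied FASTA or a seeded i.i.d. random sequence), with single-nucleotide
errors — insertion, deletion or substitution, chosen uniformly — applied
independently at each emitted base with probability ``error_rate`` (default
0.02), and each read reverse-complemented with probability ``revcomp_prob``
(default 0.5).  The genome is treated as circular so every start position
yields a full-length read and sampling stays exactly uniform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from recoil.sequence import LETTER_MAP, Read, read_sequences, reverse_complement, write_fasta


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    genome_fasta: str | Path | None = None  # overrides genome_length when given
    read_length: int = 70
    coverage: float | None = 10.0
    n_reads: int | None = None  # overrides coverage when given
    error_rate: float = 0.02
    revcomp_prob: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.revcomp_prob <= 1.0:
            raise ValueError("revcomp_prob must be in [0, 1]")
        if self.n_reads is None and self.coverage is None:
            raise ValueError("either n_reads or coverage is required")


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(LETTER_MAP))[rng.integers(0, 4, size=length)])


def load_genome(path: str | Path) -> str:
    parts = [read.seq for read in read_sequences(path)]
    if not parts:
        raise ValueError(f"no sequence records in {path}")
    return "".join(parts)


def _mutate(template: str, start: int, read_length: int, rng: np.random.Generator, p: float) -> str:
    """Emit ``read_length`` bases walking the circular template from ``start``."""
    g = len(template)
    out: list[str] = []
    pos = start
    while len(out) < read_length:
        base = template[pos % g]
        if p > 0 and rng.random() < p:
            kind = rng.integers(0, 3)  # 0 substitution, 1 insertion, 2 deletion
            if kind == 0:
                choices = LETTER_MAP.replace(base if base in LETTER_MAP else "A", "")
                out.append(choices[rng.integers(0, 3)])
                pos += 1
            elif kind == 1:
                out.append(LETTER_MAP[rng.integers(0, 4)])
                # insertion does not consume a template base
            else:
                pos += 1  # deletion: consume without emitting
        else:
            out.append(base)
            pos += 1
    return "".join(out)


def simulate_sequences(config: SimulationConfig) -> list[str]:
    """Generate the read sequences (no file I/O); fully determined by rng_seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    if config.genome_fasta is not None:
        genome = load_genome(config.genome_fasta)
    else:
        genome = random_genome(config.genome_length, rng)
    if config.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    if config.n_reads is not None:
        n = config.n_reads
    else:
        n = math.ceil(config.coverage * len(genome) / config.read_length)
    reads: list[str] = []
    for _ in range(n):
        start = int(rng.integers(0, len(genome)))
        seq = _mutate(genome, start, config.read_length, rng, config.error_rate)
        if rng.random() < config.revcomp_prob:
            seq = reverse_complement(seq)
        reads.append(seq)
    return reads


def simulate_reads(config: SimulationConfig, out_path: str | Path) -> int:
    """Write a simulated dataset as multi-FASTA; returns the read count."""
    seqs = simulate_sequences(config)
    return write_fasta((Read(id=i, seq=s) for i, s in enumerate(seqs)), out_path)
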