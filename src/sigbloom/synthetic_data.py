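"""Seeded generators for synthetic communities and sequencing reads.

The community generator plants controllable k-mer sharing: a fraction of
each genome is copied verbatim, in contiguous blocks, from a common pool
sequence, emulating related strains; the rest is i.i.d. uniform over
{A,C,G,T}. The read simulator draws reads uniformly along each genome to
a requested coverage, samples both strands uniformly, and applies a
per-base substitution error (no indels: k-mer classification is
position-free, so substitutions capture the relevant failure mode).
Everything is deterministic under the given seed.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hashing import revcomp
from .index_builder import GenomeRecord

__all__ = [
    "CommunitySpec",
    "ReadSimSpec",
    "SimulatedRead",
    "generate_community",
    "simulate_reads",
    "write_community_fasta",
    "write_reads_fastq",
    "write_truth_table",
    "reads_per_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    """Synthetic community parameters.

    ``shared_block_fraction`` in [0, 1) is the fraction of each genome
    copied from the shared pool; ``shared_block_length`` is the size of
    each copied block (blocks longer than k guarantee shared k-mers).
    """

    n_genomes: int
    lengths: tuple[int, ...]
    shared_block_fraction: float = 0.0
    shared_block_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if len(self.lengths) != self.n_genomes:
            raise ValueError("lengths must have one entry per genome")
        if not (0.0 <= self.shared_block_fraction < 1.0):
            raise ValueError("shared_block_fraction must be in [0, 1)")

    @classmethod
    def uniform(
        cls,
        n_genomes: int,
        length: int,
        shared_block_fraction: float = 0.0,
        seed: int = 0,
        shared_block_length: int = 300,
    ) -> "CommunitySpec":
        return cls(
            n_genomes=n_genomes,
            lengths=(length,) * n_genomes,
            shared_block_fraction=shared_block_fraction,
            shared_block_length=shared_block_length,
            seed=seed,
        )


@dataclass(frozen=True)
class ReadSimSpec:
    """Read simulation parameters: length, per-genome coverage, error rate."""

    read_length: int
    coverage: float
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise ValueError("substitution_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    gid: int
    position: int
    strand: str  # '+' or '-'


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def generate_community(spec: CommunitySpec) -> list[GenomeRecord]:
    """Generate G single-contig genomes with planted shared blocks."""
    rng = np.random.default_rng(spec.seed)
    pool = _random_seq(rng, max(spec.lengths))
    genomes: list[GenomeRecord] = []
    for i, length in enumerate(spec.lengths):
        seq = _random_seq(rng, length)
        target_shared = int(spec.shared_block_fraction * length)
        block = min(spec.shared_block_length, length)
        # pool blocks are taken in cycling order so every genome at the same
        # sharing fraction carries the same pool content, and destinations
        # are non-overlapping block slots in random order: the shared k-mer
        # fraction then tracks shared_block_fraction directly instead of the
        # chance overlap of independently sampled ranges
        n_src_slots = max(1, len(pool) // block)
        dst_slots = rng.permutation(max(1, length // block))
        placed = 0
        for j in range(math.ceil(target_shared / block) if target_shared else 0):
            b = min(block, target_shared - placed)
            src = (j % n_src_slots) * block
            dst = min(int(dst_slots[j % len(dst_slots)]) * block, length - b)
            seq[dst : dst + b] = pool[src : src + b]
            placed += b
        genomes.append(
            GenomeRecord(
                gid=i + 1,
                name=f"genome_{i + 1:03d}",
                sequences=[seq.tobytes().decode("ascii")],
            )
        )
    return genomes


def reads_per_genome(coverage: float, genome_length: int, read_length: int) -> int:
    """ceil(coverage * genome_length / read_length)."""
    return math.ceil(coverage * genome_length / read_length)


def simulate_reads(
    genomes: Sequence[GenomeRecord], spec: ReadSimSpec
) -> list[SimulatedRead]:
    """Uniformly placed, both-strand reads with substitution errors.

    Reads are drawn per genome to the requested coverage; each read's
    start is uniform over valid positions, its strand uniform, and each
    base is substituted with probability ``substitution_error_rate`` to a
    uniformly chosen different base. The truth (gid, position, strand)
    travels with each read.
    """
    rng = np.random.default_rng(spec.seed)
    reads: list[SimulatedRead] = []
    L = spec.read_length
    for g in genomes:
        genome_seq = "".join(g.sequences)
        if L > len(genome_seq):
            raise ValueError(
                f"read_length {L} exceeds genome {g.name!r} length {len(genome_seq)}"
            )
        n_reads = reads_per_genome(spec.coverage, len(genome_seq), L)
        starts = rng.integers(0, len(genome_seq) - L + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for j in range(n_reads):
            start = int(starts[j])
            fragment = genome_seq[start : start + L]
            strand = "+" if strands[j] == 0 else "-"
            if strand == "-":
                fragment = revcomp(fragment)
            if spec.substitution_error_rate > 0:
                arr = np.frombuffer(fragment.encode("ascii"), dtype=np.uint8).copy()
                hits = np.nonzero(rng.random(L) < spec.substitution_error_rate)[0]
                for p in hits:
                    current = arr[p]
                    choices = _BASES[_BASES != current]
                    arr[p] = choices[rng.integers(0, len(choices))]
                fragment = arr.tobytes().decode("ascii")
            reads.append(
                SimulatedRead(
                    read_id=f"{g.name}_r{j:06d}",
                    sequence=fragment,
                    gid=g.gid,
                    position=start,
                    strand=strand,
                )
            )
    return reads


def write_community_fasta(
    genomes: Sequence[GenomeRecord], outdir: str | Path
) -> Path:
    """One FASTA per genome plus a TSV manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", newline="") as mf:
        writer = csv.writer(mf, delimiter="\t")
        for g in genomes:
            fasta = outdir / f"{g.name}.fasta"
            with open(fasta, "w") as fh:
                for ci, seq in enumerate(g.sequences):
                    fh.write(f">{g.name}_contig{ci}\n")
                    for off in range(0, len(seq), 80):
                        fh.write(seq[off : off + 80] + "\n")
            writer.writerow([g.gid, g.name, fasta.name])
    return manifest


def write_reads_fastq(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """Plain FASTQ with uniform dummy qualities (qualities are ignored)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def write_truth_table(reads: Sequence[SimulatedRead], path: str | Path) -> None:
    """TSV truth: read_id, gid, position, strand."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "gid", "position", "strand"])
        for r in reads:
            writer.writerow([r.read_id, r.gid, r.position, r.strand])
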