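"""Construction of the signature index F — a modified Bloom filter.

F is an array of m signed entries. Each entry is 0 (never touched),
-1 ("dirty": hit by k-mers of two different genomes), or a positive
genome id meaning every k-mer hashing there is unique, in hash-footprint
terms, to that genome. Genomes are processed sequentially; a two-phase
build (every genome processed twice, same order) is required for the
marks of ALL genomes to be correct — after a single pass only the
last-processed genome's marks are guaranteed.

An optional thinning pass ("reduce") keeps, per contig, only signature
k-mers spaced more than omega bases apart, dirtying the rest, to shrink
the signature set. The dirty-then-restamp order of that pass is applied
literally: entries shared between a dirtied and a kept k-mer end up
re-stamped with the genome id, which can make a dirtied k-mer classify
back to its genome if the footprints coincide. This is a documented
property of the procedure, not corrected here.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hashing import HashFamily, canonicalize, extract_kmers, kmer_codes

__all__ = [
    "GenomeRecord",
    "SignatureIndex",
    "IndexFormatError",
    "IndexIntegrityError",
    "DIRTY",
    "EMPTY",
    "build_index",
    "process_genome",
    "reduce_signatures",
    "write_index",
    "read_index",
    "oracle_unique_kmers",
    "entries_for_bytes",
]

EMPTY = 0
DIRTY = -1

_MAGIC = b"SIGF"
_FORMAT_VERSION = 1


class IndexFormatError(ValueError):
    """The file is not a signature index (bad magic or version)."""


class IndexIntegrityError(ValueError):
    """The file is truncated or its checksum does not match."""


@dataclass
class GenomeRecord:
    """A reference genome: 1-based gid, label, and one or more contigs."""

    gid: int
    name: str
    sequences: list[str]

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass
class SignatureIndex:
    """The m-entry array F plus its hash family and genome table.

    ``entries[v]`` is 0 / -1 / gid. ``genome_table`` maps gid-1 ->
    (name, genome length); gids are consecutive 1..G in processing order,
    which is recorded because one-phase correctness depends on it.
    ``signature_positions`` (phase-2 builds only, kept in memory, not
    serialized) records per gid the kept signature k-mer positions as
    (contig ordinal, 0-based offset) pairs.
    """

    entries: np.ndarray
    k: int
    family: HashFamily
    genome_table: list[tuple[str, int]]
    phases_built: int
    omega: int
    canonical: bool
    signature_positions: dict[int, list[tuple[int, int]]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def m(self) -> int:
        return len(self.entries)

    @property
    def num_genomes(self) -> int:
        return len(self.genome_table)

    def gid_of(self, name: str) -> int:
        for i, (nm, _) in enumerate(self.genome_table):
            if nm == name:
                return i + 1
        raise KeyError(f"genome {name!r} not in index table")


def entries_for_bytes(size: str | int, entry_width: int = 32) -> int:
    """Convert a byte size such as '8GB' into an entry count.

    m is always specified in entries internally; this helper resolves the
    ambiguity of byte-denominated index sizes given the entry width.
    """
    if entry_width not in (16, 32):
        raise ValueError("entry_width must be 16 or 32")
    if isinstance(size, int):
        nbytes = size
    else:
        s = size.strip().upper()
        units = {"TB": 2**40, "GB": 2**30, "MB": 2**20, "KB": 2**10, "B": 1}
        for suffix, mult in units.items():
            if s.endswith(suffix):
                nbytes = int(float(s[: -len(suffix)]) * mult)
                break
        else:
            nbytes = int(s)
    m = nbytes // (entry_width // 8)
    if m < 1:
        raise ValueError(f"byte size {size!r} too small for one entry")
    return m


def _validate_genome(index: SignatureIndex, genome: GenomeRecord) -> None:
    if not (1 <= genome.gid <= index.num_genomes):
        raise ValueError(
            f"gid {genome.gid} outside genome table (G={index.num_genomes})"
        )


def process_genome(
    index: SignatureIndex, genome: GenomeRecord, phase: int
) -> list[tuple[int, int]] | None:
    """One pass of the per-genome marking procedure over all contigs.

    For each k-mer, its n hash positions are computed; if any holds a
    value other than 0 or this gid, the k-mer is non-unique and all its
    positions are set dirty, otherwise all are stamped with the gid. In
    phase 2 the positions of k-mers stamped unique are collected and, when
    omega > 0, thinned per contig by :func:`reduce_signatures` at the end
    of the genome. Returns the kept (contig, position) pairs in phase 2.
    """
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    _validate_genome(index, genome)
    gid = genome.gid
    family = index.family
    k = index.k
    # plain Python list is markedly faster than per-element ndarray access
    # in the sequential, state-dependent inner loop
    F = index.entries.tolist()
    kept_all: list[tuple[int, int]] = []
    for ci, seq in enumerate(genome.sequences):
        pos_arr, codes = kmer_codes(seq, k, canonical=index.canonical)
        hashes = family.hash_codes(codes).tolist()
        positions: list[int] = []
        pos_list = pos_arr.tolist()
        for i, idx in enumerate(hashes):
            unique = True
            for v in idx:
                fv = F[v]
                if fv != 0 and fv != gid:
                    unique = False
                    break
            if unique:
                if phase == 2:
                    positions.append(pos_list[i])
                for v in idx:
                    F[v] = gid
            else:
                for v in idx:
                    F[v] = DIRTY
        if phase == 2:
            index.entries[:] = F
            if positions and index.omega > 0:
                kept = reduce_signatures(
                    index, genome, positions, index.omega, contig_index=ci
                )
            else:
                kept = positions
            F = index.entries.tolist()
            kept_all.extend((ci, p) for p in kept)
    index.entries[:] = F
    if phase == 2:
        index.signature_positions[gid] = kept_all
        return kept_all
    return None


def reduce_signatures(
    index: SignatureIndex,
    genome: GenomeRecord,
    positions: Sequence[int],
    omega: int,
    contig_index: int = 0,
) -> list[int]:
    """Thin a sorted list of signature positions to spacing > omega.

    The first position is always kept; a later one is kept iff it exceeds
    (last kept + omega). Each dropped position's k-mer has all its hash
    entries set dirty as it is encountered; afterwards every kept
    position's k-mer is re-stamped with the gid. The dirty-then-restamp
    order is semantically significant (see module docstring). Returns the
    kept positions. Empty input is a no-op.
    """
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    _validate_genome(index, genome)
    if not positions:
        return []
    seq = genome.sequences[contig_index]
    gid = genome.gid
    family = index.family
    k = index.k
    F = index.entries

    def _hash_at(p: int) -> list[int]:
        kmer = seq[p : p + k]
        if index.canonical:
            kmer = canonicalize(kmer)
        return family.hash_kmer(kmer)

    selected = [positions[0]]
    for i in range(1, len(positions)):
        p = positions[i]
        if selected[-1] + omega < p:
            selected.append(p)
        else:
            for v in _hash_at(p):
                F[v] = DIRTY
    for p in selected:
        for v in _hash_at(p):
            F[v] = gid
    return selected


def build_index(
    genomes: Sequence[GenomeRecord],
    m: int,
    n: int,
    k: int,
    phases: int = 2,
    omega: int = 0,
    master_seed: int = 0,
    canonical: bool = True,
    entry_width: int = 32,
) -> SignatureIndex:
    """Build F over a community: phase 1 for all genomes, then optionally
    phase 2 in the same order.

    Genome ids are (re)assigned 1..G in input order and recorded in the
    table; the order matters because single-phase marks are only
    guaranteed correct for the last genome processed. omega=0 disables
    the thinning pass entirely.
    """
    if not genomes:
        raise ValueError("at least one genome required")
    if phases not in (1, 2):
        raise ValueError(f"phases must be 1 or 2, got {phases}")
    if omega < 0:
        raise ValueError(f"omega must be >= 0, got {omega}")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate genome names in community")
    if entry_width == 16:
        if len(genomes) > np.iinfo(np.int16).max:
            raise ValueError("16-bit entries support at most 32767 genomes")
        dtype = np.int16
    elif entry_width == 32:
        dtype = np.int32
    else:
        raise ValueError("entry_width must be 16 or 32")

    ordered = [
        GenomeRecord(gid=i + 1, name=g.name, sequences=g.sequences)
        for i, g in enumerate(genomes)
    ]
    family = HashFamily.from_master_seed(n=n, m=m, master_seed=master_seed)
    index = SignatureIndex(
        entries=np.zeros(m, dtype=dtype),
        k=k,
        family=family,
        genome_table=[(g.name, g.length) for g in ordered],
        phases_built=phases,
        omega=omega,
        canonical=canonical,
    )
    for g in ordered:
        process_genome(index, g, phase=1)
    if phases == 2:
        for g in ordered:
            process_genome(index, g, phase=2)
    return index


# ---------------------------------------------------------------------------
# serialization: little-endian binary, CRC-32 checksummed


def write_index(index: SignatureIndex, path: str | Path) -> None:
    """Write the index to a bespoke binary file (see read_index)."""
    entry_width = index.entries.dtype.itemsize * 8
    parts: list[bytes] = [
        _MAGIC,
        struct.pack(
            "<HHHBBBQQQ",
            _FORMAT_VERSION,
            index.k,
            index.family.n,
            entry_width,
            1 if index.canonical else 0,
            index.phases_built,
            index.omega,
            index.m,
            index.family.master_seed,
        ),
    ]
    for seed in index.family.seeds:
        parts.append(struct.pack("<Q", seed))
    parts.append(struct.pack("<I", index.num_genomes))
    for name, length in index.genome_table:
        raw = name.encode("utf-8")
        parts.append(struct.pack("<H", len(raw)) + raw + struct.pack("<Q", length))
    dtype = np.dtype("<i2") if entry_width == 16 else np.dtype("<i4")
    parts.append(index.entries.astype(dtype, copy=False).tobytes())
    payload = b"".join(parts)
    crc = zlib.crc32(payload) & 0xFFFFFFFF
    with open(path, "wb") as fh:
        fh.write(payload)
        fh.write(struct.pack("<I", crc))


def read_index(path: str | Path) -> SignatureIndex:
    """Read an index written by :func:`write_index`; bit-exact round trip."""
    data = Path(path).read_bytes()
    if len(data) < 4 or data[:4] != _MAGIC:
        raise IndexFormatError(f"{path}: not a signature index file (bad magic)")
    if len(data) < 8:
        raise IndexIntegrityError(f"{path}: truncated file")
    payload, crc_bytes = data[:-4], data[-4:]
    (crc_stored,) = struct.unpack("<I", crc_bytes)
    if zlib.crc32(payload) & 0xFFFFFFFF != crc_stored:
        raise IndexIntegrityError(f"{path}: checksum mismatch (corrupt or truncated)")
    off = 4
    header = struct.Struct("<HHHBBBQQQ")
    version, k, n, entry_width, canonical, phases, omega, m, master_seed = (
        header.unpack_from(payload, off)
    )
    off += header.size
    if version != _FORMAT_VERSION:
        raise IndexFormatError(f"{path}: unsupported format version {version}")
    seeds = struct.unpack_from(f"<{n}Q", payload, off)
    off += 8 * n
    (num_genomes,) = struct.unpack_from("<I", payload, off)
    off += 4
    table: list[tuple[str, int]] = []
    for _ in range(num_genomes):
        (name_len,) = struct.unpack_from("<H", payload, off)
        off += 2
        name = payload[off : off + name_len].decode("utf-8")
        off += name_len
        (length,) = struct.unpack_from("<Q", payload, off)
        off += 8
        table.append((name, length))
    dtype = np.dtype("<i2") if entry_width == 16 else np.dtype("<i4")
    expected = m * dtype.itemsize
    blob = payload[off : off + expected]
    if len(blob) != expected:
        raise IndexIntegrityError(f"{path}: truncated entry array")
    entries = np.frombuffer(blob, dtype=dtype).astype(
        np.int16 if entry_width == 16 else np.int32
    )
    family = HashFamily(m=m, n=n, seeds=tuple(seeds), master_seed=master_seed)
    return SignatureIndex(
        entries=entries,
        k=k,
        family=family,
        genome_table=table,
        phases_built=phases,
        omega=omega,
        canonical=bool(canonical),
    )


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_unique_kmers(
    genomes: Sequence[GenomeRecord],
    family: HashFamily,
    k: int,
    canonical: bool = True,
) -> dict[int, dict[str, list[tuple[int, int]]]]:
    """Brute-force definition of hash-unique k-mers (test-scale only).

    A k-mer of genome g is unique iff none of its n hash positions is
    touched by any k-mer occurring in a genome other than g. Returns per
    gid a dict mapping each unique k-mer to its (contig, position)
    occurrences. Independent of the incremental build: it enumerates the
    full hash footprint of every genome directly.
    """
    per_genome: dict[int, dict[str, list[tuple[int, int]]]] = {}
    kmer_hashes: dict[str, list[int]] = {}
    touched_by: dict[int, set[int]] = {}
    for g in genomes:
        occ: dict[str, list[tuple[int, int]]] = {}
        for ci, seq in enumerate(g.sequences):
            for pos, kmer in extract_kmers(seq, k, canonical=canonical):
                occ.setdefault(kmer, []).append((ci, pos))
        per_genome[g.gid] = occ
        footprint: set[int] = set()
        for kmer in occ:
            if kmer not in kmer_hashes:
                kmer_hashes[kmer] = family.hash_kmer(kmer)
            footprint.update(kmer_hashes[kmer])
        touched_by[g.gid] = footprint
    result: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for g in genomes:
        others: set[int] = set()
        for h in genomes:
            if h.gid != g.gid:
                others |= touched_by[h.gid]
        result[g.gid] = {
            kmer: positions
            for kmer, positions in per_genome[g.gid].items()
            if not (set(kmer_hashes[kmer]) & others)
        }
    return result
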