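"""K-mer extraction, canonicalization, and the seeded hash family.

K-mers over {A,C,G,T} are 2-bit packed into a single 64-bit word
(A=0, C=1, G=2, T=3; first base in the most significant position), which
makes numeric comparison of packed codes identical to lexicographic
comparison of the strings. Hashing is a splitmix64-style finalizer applied
to ``code XOR seed``, reduced mod m — a pure function of (key, seed, m)
that is bit-stable across runs and platforms, which the on-disk index
format depends on. The packing restricts k to 1..32; the method's usual
k=31 fits comfortably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "MAX_K",
    "HashFamily",
    "revcomp",
    "canonicalize",
    "extract_kmers",
    "encode_kmer",
    "decode_kmer",
    "kmer_codes",
    "revcomp_codes",
    "optimal_num_hashes",
]

MAX_K = 32  # one 2-bit base per 2 bits of a uint64

_MASK64 = (1 << 64) - 1
_MIX_C1 = 0xBF58476D1CE4E5B9
_MIX_C2 = 0x94D049BB133111EB
_GOLDEN = 0x9E3779B97F4A7C15

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# base -> 2-bit code lookup; 255 marks ambiguity characters
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i
_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base map)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _check_k(k: int) -> None:
    if not isinstance(k, int) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    if k > MAX_K:
        raise ValueError(f"k must be <= {MAX_K} (2-bit packing), got {k}")


def extract_kmers(
    sequence: str, k: int, canonical: bool = True
) -> list[tuple[int, str]]:
    """All k-mers of ``sequence`` as ``(start, kmer)`` pairs, 0-based.

    Windows containing any non-ACGT character are skipped entirely; their
    start positions are absent from the output. With ``canonical`` each
    k-mer is replaced by the lexicographic min of itself and its reverse
    complement. A sequence shorter than k yields an empty list.
    """
    _check_k(k)
    seq = sequence.upper()
    out: list[tuple[int, str]] = []
    for pos in range(len(seq) - k + 1):
        window = seq[pos : pos + k]
        if any(b not in "ACGT" for b in window):
            continue
        out.append((pos, canonicalize(window) if canonical else window))
    return out


def encode_kmer(kmer: str) -> int:
    """2-bit pack a k-mer string into an integer (first base most significant)."""
    _check_k(len(kmer))
    code = 0
    for b in kmer.upper():
        v = _BASE_CODE[ord(b)]
        if v == 255:
            raise ValueError(f"non-ACGT character in k-mer: {kmer!r}")
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    _check_k(k)
    return "".join(_BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement 2-bit packed k-mer codes (vectorized).

    Complementing a base is bitwise NOT of its 2-bit group; the group
    order is then reversed across the 64-bit word and the result shifted
    down so the k-mer again occupies the low 2k bits.
    """
    x = np.bitwise_not(codes.astype(np.uint64))
    m2 = np.uint64(0x3333333333333333)
    m4 = np.uint64(0x0F0F0F0F0F0F0F0F)
    m8 = np.uint64(0x00FF00FF00FF00FF)
    m16 = np.uint64(0x0000FFFF0000FFFF)
    x = ((x & m2) << np.uint64(2)) | ((x >> np.uint64(2)) & m2)
    x = ((x & m4) << np.uint64(4)) | ((x >> np.uint64(4)) & m4)
    x = ((x & m8) << np.uint64(8)) | ((x >> np.uint64(8)) & m8)
    x = ((x & m16) << np.uint64(16)) | ((x >> np.uint64(16)) & m16)
    x = (x << np.uint64(32)) | (x >> np.uint64(32))
    return x >> np.uint64(64 - 2 * k)


def kmer_codes(
    sequence: str, k: int, canonical: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized k-mer scan: 0-based window starts and packed codes.

    Equivalent to :func:`extract_kmers` followed by :func:`encode_kmer`,
    but operating on whole sequences at numpy speed. Returns
    ``(positions int64[nv], codes uint64[nv])`` over the valid (all-ACGT)
    windows only.
    """
    _check_k(k)
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    nwin = len(raw) - k + 1
    if nwin <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.uint64)
    base = _BASE_CODE[raw]
    invalid = (base == 255).astype(np.int32)
    # window is valid iff it contains no invalid base
    cs = np.concatenate(([0], np.cumsum(invalid)))
    valid = (cs[k:] - cs[:-k]) == 0
    b64 = np.where(base == 255, 0, base).astype(np.uint64)
    codes = np.zeros(nwin, dtype=np.uint64)
    for j in range(k):
        codes = (codes << np.uint64(2)) | b64[j : j + nwin]
    positions = np.nonzero(valid)[0].astype(np.int64)
    codes = codes[valid]
    if canonical:
        codes = np.minimum(codes, revcomp_codes(codes, k))
    return positions, codes


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer, vectorized over uint64 (wraps mod 2^64)."""
    z = x.astype(np.uint64)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(_MIX_C1)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(_MIX_C2)
    return z ^ (z >> np.uint64(31))


def _mix64_int(x: int) -> int:
    z = x & _MASK64
    z = ((z ^ (z >> 30)) * _MIX_C1) & _MASK64
    z = ((z ^ (z >> 27)) * _MIX_C2) & _MASK64
    return z ^ (z >> 31)


def _seed_stream(master_seed: int) -> Iterator[int]:
    """Deterministic stream of 64-bit seeds from one master seed."""
    state = master_seed & _MASK64
    while True:
        state = (state + _GOLDEN) & _MASK64
        yield _mix64_int(state)


@dataclass(frozen=True)
class HashFamily:
    """n seeded hash functions mapping a packed k-mer code into [0, m).

    ``seeds`` are pairwise-distinct 64-bit values derived deterministically
    from ``master_seed``, so recording the master seed (or the seeds
    themselves) in an index header reproduces the family exactly.
    """

    m: int
    n: int
    seeds: tuple[int, ...]
    master_seed: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if len(self.seeds) != self.n:
            raise ValueError("seeds length must equal n")
        if len(set(self.seeds)) != self.n:
            raise ValueError("seeds must be pairwise distinct")

    @classmethod
    def from_master_seed(cls, n: int, m: int, master_seed: int) -> "HashFamily":
        stream = _seed_stream(master_seed)
        seeds: list[int] = []
        seen: set[int] = set()
        while len(seeds) < n:
            s = next(stream)
            if s not in seen:  # distinctness; collisions astronomically rare
                seen.add(s)
                seeds.append(s)
        return cls(m=m, n=n, seeds=tuple(seeds), master_seed=master_seed & _MASK64)

    def hash_codes(self, codes: np.ndarray) -> np.ndarray:
        """Positions for an array of packed codes; shape (len(codes), n)."""
        codes = np.asarray(codes, dtype=np.uint64)
        out = np.empty((len(codes), self.n), dtype=np.int64)
        for i, seed in enumerate(self.seeds):
            out[:, i] = (_mix64(codes ^ np.uint64(seed)) % np.uint64(self.m)).astype(
                np.int64
            )
        return out

    def hash_code(self, code: int) -> list[int]:
        """Positions for one packed code."""
        return [
            _mix64_int(code ^ seed) % self.m for seed in self.seeds
        ]

    def hash_kmer(self, kmer: str) -> list[int]:
        """Positions for a k-mer string (exactly n values, seed order)."""
        return self.hash_code(encode_kmer(kmer))


def optimal_num_hashes(m: int, elements: int) -> int:
    """Bloom-filter optimal hash count (m/elements)*ln 2, rounded, min 1."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if elements < 1:
        raise ValueError(f"elements must be >= 1, got {elements}")
    return max(1, int((m / elements) * math.log(2) + 0.5))
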