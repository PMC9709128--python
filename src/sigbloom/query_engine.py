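"""Per-k-mer classification and read-to-genome assignment strategies.

A k-mer lookup inspects the n entries at its hash positions. If any
entry is 0 the k-mer was never stored (Bloom-filter no-false-negative
logic: a stored signature stamped all n entries), so the call is
"absent". If all n entries hold the same positive gid the call is that
gid. Anything else — a dirty entry or conflicting positive gids — is
"dirty". Over a read, the multiset V of per-k-mer calls feeds one of
three strategies:

- majority:       a gid held by >50% of the POSITIVE calls wins;
- first_hit:      the first positive call in scan order wins;
- one_or_nothing: a gid wins only if it is the sole distinct positive.

Every strategy discards a read whose V contains no positive call. The
majority denominator is positives only: signature thinning makes
positive calls deliberately sparse along a genome, so a
denominator over all k-mers would discard nearly everything.

Per-read classification is a pure function of (index, read); any
parallel partitioning of a read stream therefore yields the same
multiset of assignments.
"""

from __future__ import annotations

import csv
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .hashing import canonicalize, encode_kmer, kmer_codes
from .index_builder import SignatureIndex

__all__ = [
    "ABSENT",
    "DIRTY",
    "DISCARDED",
    "STRATEGIES",
    "ReadAssignment",
    "classify_kmer",
    "read_calls",
    "majority_from_calls",
    "first_hit_from_calls",
    "one_or_nothing_from_calls",
    "classify_read_majority",
    "classify_read_first_hit",
    "classify_read_one_or_nothing",
    "classify_read",
    "query_sample",
    "write_assignments_tsv",
]

ABSENT = 0
DIRTY = -1
DISCARDED = None

STRATEGIES = ("majority", "first_hit", "one_or_nothing")


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of classifying one read under one strategy.

    ``outcome`` is a positive gid or None (discarded). ``n_positive`` and
    ``n_total`` summarize the evidence multiset V; both are None under
    the first-hit fast path, which stops at the first positive call.
    """

    read_id: str
    strategy: str
    outcome: int | None
    n_positive: int | None
    n_total: int | None


def classify_kmer(index: SignatureIndex, kmer: str) -> int:
    """Classify one k-mer: 0 absent, -1 dirty, or a positive gid."""
    if len(kmer) != index.k:
        raise ValueError(f"k-mer length {len(kmer)} != index k={index.k}")
    if index.canonical:
        kmer = canonicalize(kmer)
    values = index.entries[index.family.hash_code(encode_kmer(kmer))]
    return _call_from_entries(values)


def _call_from_entries(values: np.ndarray) -> int:
    if (values == 0).any():
        return ABSENT
    first = int(values[0])
    if first > 0 and (values == first).all():
        return first
    return DIRTY


def read_calls(index: SignatureIndex, sequence: str) -> np.ndarray:
    """Per-k-mer calls for every valid k-mer of a read, in scan order."""
    _, codes = kmer_codes(sequence, index.k, canonical=index.canonical)
    if len(codes) == 0:
        return np.empty(0, dtype=np.int64)
    idx = index.family.hash_codes(codes)  # (nk, n)
    entries = index.entries[idx].astype(np.int64)
    any_zero = (entries == 0).any(axis=1)
    first = entries[:, 0]
    unanimous = (entries == entries[:, :1]).all(axis=1) & (first > 0)
    return np.where(any_zero, ABSENT, np.where(unanimous, first, DIRTY))


def majority_from_calls(calls: Sequence[int]) -> int | None:
    """Strict majority over the positive calls; tie or no positives discard."""
    positives = [c for c in calls if c > 0]
    if not positives:
        return DISCARDED
    counts: dict[int, int] = {}
    for g in positives:
        counts[g] = counts.get(g, 0) + 1
    top_gid, top = max(counts.items(), key=lambda kv: kv[1])
    if 2 * top > len(positives):
        return top_gid
    return DISCARDED


def first_hit_from_calls(calls: Sequence[int]) -> int | None:
    """First positive call in scan order; none discards."""
    for c in calls:
        if c > 0:
            return int(c)
    return DISCARDED


def one_or_nothing_from_calls(calls: Sequence[int]) -> int | None:
    """Sole distinct positive gid (multiplicity irrelevant) or discard."""
    distinct = {int(c) for c in calls if c > 0}
    if len(distinct) == 1:
        return distinct.pop()
    return DISCARDED


def _evidence(calls: np.ndarray) -> tuple[int, int]:
    return int((calls > 0).sum()), int(len(calls))


def classify_read_majority(
    index: SignatureIndex, sequence: str, read_id: str = ""
) -> ReadAssignment:
    calls = read_calls(index, sequence)
    n_pos, n_tot = _evidence(calls)
    return ReadAssignment(read_id, "majority", majority_from_calls(calls), n_pos, n_tot)


def classify_read_first_hit(
    index: SignatureIndex, sequence: str, read_id: str = ""
) -> ReadAssignment:
    calls = read_calls(index, sequence)
    # fast path: evidence beyond the first positive is never inspected
    return ReadAssignment(read_id, "first_hit", first_hit_from_calls(calls), None, None)


def classify_read_one_or_nothing(
    index: SignatureIndex, sequence: str, read_id: str = ""
) -> ReadAssignment:
    calls = read_calls(index, sequence)
    n_pos, n_tot = _evidence(calls)
    return ReadAssignment(
        read_id, "one_or_nothing", one_or_nothing_from_calls(calls), n_pos, n_tot
    )


_CLASSIFIERS = {
    "majority": classify_read_majority,
    "first_hit": classify_read_first_hit,
    "one_or_nothing": classify_read_one_or_nothing,
}


def classify_read(
    index: SignatureIndex, sequence: str, strategy: str, read_id: str = ""
) -> ReadAssignment:
    try:
        fn = _CLASSIFIERS[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
        ) from None
    return fn(index, sequence, read_id)


def query_sample(
    index: SignatureIndex,
    reads: Iterable[tuple[str, str]],
    strategy: str = "majority",
    sample_fraction: float = 1.0,
    rng_seed: int = 0,
    threads: int = 1,
) -> Iterator[ReadAssignment]:
    """Classify a (sub)sample of a read stream.

    Each read is retained independently with probability
    ``sample_fraction`` (seeded Bernoulli in stream order, so a fixed
    seed reproduces the retained set exactly). Classification is pure
    per read; with ``threads`` > 1 reads are dispatched to a thread pool
    and results are yielded in input order, so the output is identical
    to a serial run.
    """
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError(f"sample_fraction must be in (0, 1], got {sample_fraction}")
    if strategy not in _CLASSIFIERS:
        raise ValueError(
            f"unknown strategy {strategy!r}; choose from {STRATEGIES}"
        )
    rng = np.random.default_rng(rng_seed)
    fn = _CLASSIFIERS[strategy]

    def retained() -> Iterator[tuple[str, str]]:
        for read_id, seq in reads:
            if sample_fraction >= 1.0 or rng.random() < sample_fraction:
                yield read_id, seq

    if threads <= 1:
        for read_id, seq in retained():
            yield fn(index, seq, read_id)
    else:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            yield from pool.map(lambda rs: fn(index, rs[1], rs[0]), retained())


def write_assignments_tsv(
    assignments: Iterable[ReadAssignment], path: str | Path
) -> int:
    """Write one TSV row per read; returns the row count.

    Columns: read_id, strategy, outcome gid or "-", positive k-mer
    calls, total k-mer calls ("-" placeholders under the first-hit fast
    path, which does not tally evidence).
    """
    count = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "strategy", "outcome", "n_positive", "n_total"])
        for a in assignments:
            writer.writerow(
                [
                    a.read_id,
                    a.strategy,
                    a.outcome if a.outcome is not None else "-",
                    a.n_positive if a.n_positive is not None else "-",
                    a.n_total if a.n_total is not None else "-",
                ]
            )
            count += 1
    return count
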