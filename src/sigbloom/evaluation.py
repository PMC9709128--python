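"""Signature statistics, presence calling, and precision/recall/F1.

Presence is evaluated at the genome level: a genome is called present
when at least ``min_reads`` reads are assigned to it. The default of 1
is deliberately permissive — a single assigned read suffices — which is
the regime that makes recall easy and precision hard.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .index_builder import GenomeRecord, SignatureIndex
from .query_engine import ReadAssignment, read_calls

__all__ = [
    "SignatureStats",
    "EvalResult",
    "signature_stats",
    "call_presence",
    "evaluate",
    "write_stats",
    "write_eval",
]


@dataclass(frozen=True)
class SignatureStats:
    """Per-genome signature position counts with min/max/total summary."""

    per_genome: dict[int, int]
    total: int
    min: int
    max: int
    zero_signature_gids: list[int]


@dataclass(frozen=True)
class EvalResult:
    precision: float
    recall: float
    f1: float
    n_predicted: int
    n_truth: int
    true_positives: int


def signature_stats(
    index: SignatureIndex, genomes: Sequence[GenomeRecord]
) -> SignatureStats:
    """Count, per genome, the k-mer positions that classify back to it.

    Each genome is re-scanned and every valid k-mer position whose
    classification equals the genome's own gid is counted (duplicate
    k-mers contribute once per position). Genomes must match the index
    table by name and order.
    """
    counts: dict[int, int] = {}
    for g in genomes:
        if not (1 <= g.gid <= index.num_genomes):
            raise ValueError(f"gid {g.gid} not in index table")
        name, _ = index.genome_table[g.gid - 1]
        if name != g.name:
            raise ValueError(
                f"genome {g.name!r} does not match index table entry {name!r} "
                f"at gid {g.gid}"
            )
        c = 0
        for seq in g.sequences:
            calls = read_calls(index, seq)
            c += int((calls == g.gid).sum())
        counts[g.gid] = c
    values = list(counts.values())
    return SignatureStats(
        per_genome=counts,
        total=sum(values),
        min=min(values),
        max=max(values),
        zero_signature_gids=[gid for gid, c in counts.items() if c == 0],
    )


def call_presence(
    assignments: Iterable[ReadAssignment], min_reads: int = 1
) -> set[int]:
    """Gids with at least ``min_reads`` assigned reads."""
    if min_reads < 1:
        raise ValueError(f"min_reads must be >= 1, got {min_reads}")
    counts = Counter(a.outcome for a in assignments if a.outcome is not None)
    return {gid for gid, c in counts.items() if c >= min_reads}


def evaluate(predicted: set, truth: set) -> EvalResult:
    """Precision/recall/F1 of a predicted genome set against the truth set.

    precision = |predicted ∩ truth| / |predicted| (0 when nothing is
    predicted); recall = |predicted ∩ truth| / |truth|; F1 is their
    harmonic mean, 0 when both are 0. An empty truth set is an error
    (recall undefined).
    """
    if not truth:
        raise ValueError("truth set is empty; recall undefined")
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return EvalResult(
        precision=precision,
        recall=recall,
        f1=f1,
        n_predicted=len(predicted),
        n_truth=len(truth),
        true_positives=tp,
    )


def write_stats(
    stats: SignatureStats,
    index: SignatureIndex,
    tsv_path: str | Path,
    json_path: str | Path,
) -> None:
    """Per-genome TSV plus a JSON min/max/total summary."""
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["gid", "name", "genome_length", "signature_count"])
        for gid, count in sorted(stats.per_genome.items()):
            name, length = index.genome_table[gid - 1]
            writer.writerow([gid, name, length, count])
    summary = {
        "total": stats.total,
        "min": stats.min,
        "max": stats.max,
        "zero_signature_genomes": [
            index.genome_table[gid - 1][0] for gid in stats.zero_signature_gids
        ],
    }
    Path(json_path).write_text(json.dumps(summary, indent=2) + "\n")


def write_eval(result: EvalResult, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "precision": result.precision,
                "recall": result.recall,
                "f1": result.f1,
                "n_predicted": result.n_predicted,
                "n_truth": result.n_truth,
                "true_positives": result.true_positives,
            },
            indent=2,
        )
        + "\n"
    )
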