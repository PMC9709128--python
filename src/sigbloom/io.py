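"""Reading reference genomes and read sets (FASTA/FASTQ, optionally gzipped)."""

from __future__ import annotations

import csv
import gzip
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "open_maybe_gzip",
    "read_genome_fasta",
    "load_community",
    "read_manifest",
    "iter_reads",
]


def open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_genome_fasta(path: str | Path) -> tuple[str, list[str]]:
    """One genome per file: returns (name, contig sequences in file order).

    The genome name is the file stem (minus .gz/.fa etc.); contigs keep
    their FASTA order because signature thinning runs per contig.
    """
    path = Path(path)
    with open_maybe_gzip(path) as fh:
        seqs = [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")]
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    name = path.name
    for suffix in (".gz", ".fasta", ".fa", ".fna"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name, seqs


def read_manifest(path: str | Path) -> list[tuple[str, Path]]:
    """TSV manifest: gid-order, name, path. Returns (name, path) in gid order."""
    path = Path(path)
    rows: list[tuple[int, str, Path]] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            order, name, fasta = row[0], row[1], row[2]
            fasta_path = Path(fasta)
            if not fasta_path.is_absolute():
                fasta_path = path.parent / fasta_path
            rows.append((int(order), name, fasta_path))
    rows.sort(key=lambda r: r[0])
    return [(name, p) for _, name, p in rows]


def load_community(paths: Sequence[str | Path], manifest: str | Path | None = None):
    """Load genomes as GenomeRecords with gids assigned by input order."""
    from .index_builder import GenomeRecord

    records: list[GenomeRecord] = []
    if manifest is not None:
        for gid, (name, p) in enumerate(read_manifest(manifest), start=1):
            _, seqs = read_genome_fasta(p)
            records.append(GenomeRecord(gid=gid, name=name, sequences=seqs))
    else:
        for gid, p in enumerate(paths, start=1):
            name, seqs = read_genome_fasta(p)
            records.append(GenomeRecord(gid=gid, name=name, sequences=seqs))
    return records


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.suffix == ".gz" else path.name
    if name.endswith((".fq", ".fastq")):
        return "fastq"
    return "fasta"


def iter_reads(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from FASTA or FASTQ; qualities ignored."""
    path = Path(path)
    fmt = _sniff_format(path)
    with open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()
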