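"""File I/O: FASTA, FASTQ, BED6 and the TSV tables the pipeline emits.

FASTA/FASTQ go through Biopython; BED is carried as a pandas DataFrame with
the six conventional columns (0-based half-open coordinates throughout).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a dict of upper-case sequences keyed by id."""
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def read_fastq(path) -> Iterable[tuple[str, str, str]]:
    """Yield (title, sequence, quality) triples from a FASTQ file."""
    with _open_text(path) as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(records: Iterable[tuple[str, str, str]], path) -> None:
    """Write (title, sequence, quality) triples as FASTQ."""
    with _open_text(path, "wt") as handle:
        for title, seq, qual in records:
            handle.write(f"@{title}\n{seq}\n+\n{qual}\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file (3-6+ columns) into a DataFrame.

    Missing name/score/strand columns are filled with '.', 0 and '.'.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    n = df.shape[1]
    names = BED_COLUMNS[:n] + [f"extra{i}" for i in range(max(0, n - 6))]
    df.columns = names
    if "name" not in df:
        df["name"] = "."
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns] + (extra_cols or [])
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def make_bed(intervals, names=None) -> pd.DataFrame:
    """Build a BED DataFrame from (chrom, start, end[, strand]) tuples."""
    rows = []
    for i, iv in enumerate(intervals):
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        strand = iv[3] if len(iv) > 3 else "."
        name = names[i] if names is not None else f"iv{i}"
        rows.append((chrom, start, end, name, 0, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)
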