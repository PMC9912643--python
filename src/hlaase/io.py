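"""File-format helpers: FASTA/FASTQ via Biopython, TSV via pandas.

All writers use deterministic ordering and a fixed float format
(6 significant digits) so that identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import math
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

FLOAT_FORMAT = "%.6g"


def fmt_float(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return FLOAT_FORMAT % x


def open_text(path, mode: str = "rt"):
    """Open a path, transparently handling a .gz suffix."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    """Return (header, sequence) pairs; header is the full description line."""
    with open_text(path) as handle:
        return [(rec.description, str(rec.seq)) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open_text(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_fastq_seqs(path) -> list[str]:
    """Read sequences (only) from a FASTQ file, plain or gzipped."""
    with open_text(path) as handle:
        return [str(rec.seq) for rec in SeqIO.parse(handle, "fastq")]


def write_fastq(names: Iterable[str], seqs: Iterable[str], path) -> None:
    with open_text(path, "wt") as handle:
        for name, seq in zip(names, seqs):
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
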