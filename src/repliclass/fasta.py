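"""Minimal FASTA I/O helpers (plain or gzip) shared by the CLI and pipeline."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from a FASTA file, transparently gunzipping."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq)
    else:
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                yield rec.id, str(rec.seq)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for name, seq in records:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
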