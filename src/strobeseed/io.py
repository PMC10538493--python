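"""FASTA input and TSV table output shared by the CLI subcommands."""

from __future__ import annotations

import gzip
import sys
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .seeds import Sequence

__all__ = ["read_fasta", "write_fasta", "write_table"]

FLOAT_FORMAT = "%.6g"


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[Sequence]:
    """Read a (possibly gzipped) multi-record FASTA; residues are uppercased.

    An empty file yields an empty list (with a warning on stderr); a file
    with content that is not FASTA is rejected.
    """
    with _open_text(path) as fh:
        head = fh.read(1)
        if not head:
            print(f"warning: empty FASTA file {path}", file=sys.stderr)
            return []
        if head != ">":
            raise ValueError(f"{path}: not FASTA (line 1 does not start with '>')")
    with _open_text(path) as fh:
        records = [Sequence(rec.id, str(rec.seq).upper())
                   for rec in SeqIO.parse(fh, "fasta")]
    return records


def write_fasta(seqs, path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), 80):
                fh.write(s.residues[i : i + 80] + "\n")


def write_table(rows, path=None) -> None:
    """Write rows (DataFrame or list of dicts) as TSV with a header.

    Floats use a fixed %.6g format so identical runs produce byte-identical
    output.  ``path`` None or "-" writes to stdout.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    out = sys.stdout if path in (None, "-") else open(path, "w")
    try:
        df.to_csv(out, sep="\t", index=False, float_format=FLOAT_FORMAT)
    finally:
        if out is not sys.stdout:
            out.close()
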