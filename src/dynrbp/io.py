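"""File-format helpers: FASTA and gzip-tolerant text access."""

from __future__ import annotations

import gzip
from pathlib import Path
from Bio import SeqIO

from .dataset import TranscriptSet

__all__ = ["open_text", "read_fasta", "write_fasta"]


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> TranscriptSet:
    """Read a (possibly gzipped) FASTA into a TranscriptSet (T mapped to U)."""
    with open_text(path) as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    return TranscriptSet(records)


def write_fasta(transcripts: TranscriptSet, path, width: int = 70) -> None:
    with open_text(path, "wt") as fh:
        for tid, seq in transcripts.items():
            fh.write(f">{tid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
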