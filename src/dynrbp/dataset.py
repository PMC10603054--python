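"""Build fixed-length labelled samples from binding peaks and a transcriptome.

Coordinates are 0-based half-open internally (BED semantics); reports and
tables use 1-based positions.  ``T`` is silently mapped to ``U``; any other
non-ACGU symbol is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_LEN = 101
STRUCT_SENTINEL = -1.0

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

__all__ = [
    "TranscriptSet",
    "PeakRecord",
    "FixedSample",
    "TokenSequence",
    "clean_rna",
    "reverse_complement",
    "fix_site_length",
    "select_positives",
    "sample_negatives",
    "split_dataset",
    "tokenize",
    "align_structure_to_tokens",
    "extract_interval_sequences",
    "read_bed_peaks",
    "write_sample_manifest",
    "read_sample_manifest",
]


def clean_rna(sequence: str, name: str = "sequence") -> str:
    """Uppercase, map T->U, and reject any other non-ACGU character."""
    seq = sequence.upper().replace("T", "U")
    for i, base in enumerate(seq):
        if base not in "ACGU":
            raise ValueError(f"{name}: invalid character {base!r} at position {i + 1}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


class TranscriptSet:
    """Mapping of unique transcript ids to RNA sequences."""

    def __init__(self, records: Dict[str, str] | Sequence[Tuple[str, str]]):
        items = records.items() if isinstance(records, dict) else records
        self._seqs: Dict[str, str] = {}
        for tid, seq in items:
            if tid in self._seqs:
                raise ValueError(f"duplicate transcript id {tid!r}")
            if not seq:
                raise ValueError(f"transcript {tid!r} has an empty sequence")
            self._seqs[tid] = clean_rna(seq, name=tid)

    def __getitem__(self, tid: str) -> str:
        return self._seqs[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self._seqs

    def __len__(self) -> int:
        return len(self._seqs)

    def __iter__(self):
        return iter(self._seqs)

    def items(self):
        return self._seqs.items()

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())


@dataclass(frozen=True)
class PeakRecord:
    transcript_id: str
    start: int  # 0-based half-open
    end: int
    confidence: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid peak interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FixedSample:
    sequence: str
    label: int
    structure: Optional[np.ndarray] = None  # per-base score, NaN = missing
    origin: Tuple[str, int] = ("", 0)

    def __post_init__(self):
        if len(self.sequence) != TARGET_LEN:
            raise ValueError(
                f"sample sequence must be {TARGET_LEN} nt, got {len(self.sequence)}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.structure is not None:
            self.structure = np.asarray(self.structure, dtype=float)
            if len(self.structure) != TARGET_LEN:
                raise ValueError("structure vector length must match sequence")


@dataclass
class TokenSequence:
    tokens: List[str]  # includes [CLS] ... [SEP]
    k: int

    @property
    def interior(self) -> List[str]:
        return self.tokens[1:-1]

    def __len__(self) -> int:
        return len(self.tokens)


def fix_site_length(peak: PeakRecord, transcripts: TranscriptSet,
                    target_len: int = TARGET_LEN) -> Optional[FixedSample]:
    """Center a window of ``target_len`` nt on the peak midpoint.

    Shorter peaks are extended from the middle to both sides, longer peaks
    trimmed from both sides; windows running off a transcript end are shifted
    inward.  Returns ``None`` (with a logged reason) when the transcript is
    shorter than ``target_len``.
    """
    seq = transcripts[peak.transcript_id]
    if peak.end > len(seq):
        raise ValueError(
            f"peak [{peak.start},{peak.end}) exceeds transcript "
            f"{peak.transcript_id} length {len(seq)}")
    if len(seq) < target_len:
        logger.info("rejecting peak on %s: transcript length %d < %d",
                    peak.transcript_id, len(seq), target_len)
        return None
    mid = (peak.start + peak.end) // 2
    left_flank = (target_len - 1) // 2  # extra base (even targets) goes 3'
    start = mid - left_flank
    start = min(max(start, 0), len(seq) - target_len)
    return FixedSample(sequence=seq[start:start + target_len], label=1,
                       origin=(peak.transcript_id, start))


def select_positives(peaks: Sequence[PeakRecord], n: int = 5000) -> List[PeakRecord]:
    """The ``n`` highest-confidence peaks; ties broken by (transcript_id,
    start)."""
    ranked = sorted(peaks, key=lambda p: (-p.confidence, p.transcript_id, p.start))
    return ranked[:n]


def sample_negatives(transcripts: TranscriptSet, n: int = 10000,
                     length: int = TARGET_LEN,
                     exclude: Sequence[PeakRecord] = (),
                     seed: int = 0) -> List[FixedSample]:
    """Sample ``n`` distinct windows uniformly over all eligible start
    positions, optionally excluding windows that overlap any excluded peak."""
    excluded_by_tid: Dict[str, List[Tuple[int, int]]] = {}
    for p in exclude:
        excluded_by_tid.setdefault(p.transcript_id, []).append((p.start, p.end))
    candidates: List[Tuple[str, int]] = []
    for tid, seq in transcripts.items():
        n_starts = len(seq) - length + 1
        if n_starts <= 0:
            continue
        eligible = np.ones(n_starts, dtype=bool)
        for (s, e) in excluded_by_tid.get(tid, ()):
            lo = max(0, s - length + 1)
            hi = min(n_starts, e)
            eligible[lo:hi] = False
        for start in np.flatnonzero(eligible):
            candidates.append((tid, int(start)))
    if len(candidates) < n:
        raise ValueError(
            f"only {len(candidates)} eligible windows for {n} negatives "
            f"(shortfall {n - len(candidates)})")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    samples = []
    for idx in sorted(chosen.tolist()):
        tid, start = candidates[idx]
        samples.append(FixedSample(
            sequence=transcripts[tid][start:start + length], label=0,
            origin=(tid, start)))
    return samples


def split_dataset(samples: Sequence[FixedSample], seed: int = 0
                  ) -> Tuple[List[FixedSample], List[FixedSample], List[FixedSample]]:
    """Seeded shuffle, then 20% test and 20% of the remainder as validation.

    Returns ``(train, validation, test)``.
    """
    if len(samples) < 5:
        raise ValueError("need at least 5 samples to split")
    order = np.random.default_rng(seed).permutation(len(samples))
    shuffled = [samples[i] for i in order]
    n = len(shuffled)
    n_test = round(0.2 * n)
    n_val = round(0.2 * (n - n_test))
    test = shuffled[:n_test]
    val = shuffled[n_test:n_test + n_val]
    train = shuffled[n_test + n_val:]
    return train, val, test


def tokenize(sequence: str, k: int = 3) -> TokenSequence:
    """Overlapping k-mers (step 1) flanked by [CLS] and [SEP]."""
    if k not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"k must be in 1..6, got {k}")
    seq = clean_rna(sequence)
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    return TokenSequence(tokens=["[CLS]"] + kmers + ["[SEP]"], k=k)


def align_structure_to_tokens(profile: np.ndarray, k: int) -> np.ndarray:
    """Token i carries the mean of its k covered base scores, ignoring NaN;
    all-NaN windows get the -1 sentinel.  Output length = len(profile)-k+1."""
    profile = np.asarray(profile, dtype=float)
    n_tok = len(profile) - k + 1
    if n_tok < 1:
        raise ValueError("profile shorter than k")
    windows = np.lib.stride_tricks.sliding_window_view(profile, k)
    counts = np.isfinite(windows).sum(axis=1)
    sums = np.nansum(windows, axis=1)
    out = np.full(n_tok, STRUCT_SENTINEL)
    ok = counts > 0
    out[ok] = sums[ok] / counts[ok]
    return out


def extract_interval_sequences(intervals: Sequence[dict], genome) -> TranscriptSet:
    """Extract BED-style half-open intervals from an indexed FASTA
    (pyfaidx.Fasta or any mapping of name -> sequence-like).

    Minus-strand intervals are reverse-complemented; T is mapped to U.
    Each interval dict needs chrom/start/end and may carry name and strand.
    """
    missing = sorted({iv["chrom"] for iv in intervals
                      if iv["chrom"] not in genome})
    if missing:
        raise KeyError(f"chromosomes absent from FASTA: {missing}")
    records = []
    for i, iv in enumerate(intervals):
        raw = str(genome[iv["chrom"]][iv["start"]:iv["end"]])
        seq = clean_rna(raw, name=f"{iv['chrom']}:{iv['start']}-{iv['end']}")
        if iv.get("strand", "+") == "-":
            seq = reverse_complement(seq)
        name = iv.get("name") or f"{iv['chrom']}:{iv['start']}-{iv['end']}({iv.get('strand', '+')})"
        records.append((name, seq))
    return TranscriptSet(records)


# -- tabular I/O ----------------------------------------------------------

def read_bed_peaks(path) -> List[PeakRecord]:
    """Parse BED6 (or BED4+score) peaks; column 5 is the confidence score."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        conf = float(row[4]) if len(row) > 4 else 0.0
        peaks.append(PeakRecord(transcript_id=str(row[0]), start=int(row[1]),
                                end=int(row[2]), confidence=conf))
    return peaks


def write_sample_manifest(samples: Sequence[FixedSample], path) -> None:
    rows = []
    for s in samples:
        struct = ""
        if s.structure is not None:
            struct = ",".join("NULL" if not np.isfinite(v) else f"{v:.4f}"
                              for v in s.structure)
        rows.append((s.origin[0], s.origin[1], s.label, s.sequence, struct))
    pd.DataFrame(rows, columns=["transcript_id", "start", "label",
                                "sequence", "structure"]).to_csv(
        path, sep="\t", index=False)


def read_sample_manifest(path) -> List[FixedSample]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    samples = []
    for row in df.itertuples(index=False):
        struct = None
        if row.structure:
            struct = np.array([np.nan if v == "NULL" else float(v)
                               for v in str(row.structure).split(",")])
        samples.append(FixedSample(sequence=row.sequence, label=int(row.label),
                                   structure=struct,
                                   origin=(str(row.transcript_id), int(row.start))))
    return samples
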