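"""In-vivo reactivity scoring from RT-stop / base-density count tables.

The pipeline processes each transcript in sliding windows: replicate counts
are merged by addition, each merged vector is winsorize-normalized by the
mean of its upper rank slice, a background-subtracted enrichment is formed,
and the enrichment is rescaled to [0, 1] between its lower and upper
quantiles.  Bases whose merged control base density falls below the coverage
cutoff (default 200) receive no score (NULL, represented as NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RTBDCounts",
    "IcshapeConfig",
    "NormalizationError",
    "combine_replicates",
    "normalize_counts",
    "enrichment",
    "rescale_scores",
    "score_transcript",
    "read_counts_table",
    "write_reactivity_table",
]


class NormalizationError(ValueError):
    """Raised when a window's normalization factor is unusable; the caller
    should skip the window."""


@dataclass
class RTBDCounts:
    """Per-base counts for one transcript: two replicates each of control
    (DMSO) RT-stops and base density, plus two treatment (NAI) RT-stop
    replicates."""

    transcript_id: str
    rt_dmso_rep1: np.ndarray
    rt_dmso_rep2: np.ndarray
    rt_nai_rep1: np.ndarray
    rt_nai_rep2: np.ndarray
    bd_dmso_rep1: np.ndarray
    bd_dmso_rep2: np.ndarray

    def __post_init__(self):
        vecs = [self.rt_dmso_rep1, self.rt_dmso_rep2, self.rt_nai_rep1,
                self.rt_nai_rep2, self.bd_dmso_rep1, self.bd_dmso_rep2]
        vecs = [np.asarray(v) for v in vecs]
        (self.rt_dmso_rep1, self.rt_dmso_rep2, self.rt_nai_rep1,
         self.rt_nai_rep2, self.bd_dmso_rep1, self.bd_dmso_rep2) = vecs
        lengths = {len(v) for v in vecs}
        if len(lengths) != 1:
            raise ValueError(
                f"transcript {self.transcript_id}: replicate vectors have "
                f"unequal lengths {sorted(lengths)}")
        for v in vecs:
            if np.any(np.asarray(v) < 0):
                raise ValueError(
                    f"transcript {self.transcript_id}: negative counts")

    def __len__(self) -> int:
        return len(self.rt_dmso_rep1)


@dataclass
class IcshapeConfig:
    alpha: float = 0.25
    window_size: int = 200
    window_step: int = 5
    coverage_min: int = 200
    norm_lo: float = 0.90
    norm_hi: float = 0.95
    scale_lo: float = 0.05
    scale_hi: float = 0.95

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 < self.norm_lo < self.norm_hi <= 1):
            raise ValueError("require 0 < norm_lo < norm_hi <= 1")
        if not (0 <= self.scale_lo < self.scale_hi <= 1):
            raise ValueError("require 0 <= scale_lo < scale_hi <= 1")
        if self.window_step > self.window_size:
            raise ValueError("window_step must be <= window_size")


def combine_replicates(counts: RTBDCounts) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge the two replicates of each library by elementwise addition.

    Returns ``(rt_dmso, rt_nai, bd_dmso)`` as float arrays.
    """
    rt_dmso = counts.rt_dmso_rep1.astype(float) + counts.rt_dmso_rep2
    rt_nai = counts.rt_nai_rep1.astype(float) + counts.rt_nai_rep2
    bd_dmso = counts.bd_dmso_rep1.astype(float) + counts.bd_dmso_rep2
    return rt_dmso, rt_nai, bd_dmso


def _rank_slice(n: int, lo: float, hi: float) -> Tuple[int, int]:
    """Ascending 1-based rank slice (start, end] used for the normalization
    factor; guaranteed non-empty (at least the single rank round(hi*n),
    floored at 1)."""
    start = int(round(lo * n))
    end = int(round(hi * n))
    end = max(end, 1)
    start = min(start, end - 1)
    start = max(start, 0)
    return start, end


def normalize_counts(values: np.ndarray, lo: float = 0.90,
                     hi: float = 0.95) -> Tuple[np.ndarray, float]:
    """Divide ``values`` by the mean of the sorted values whose ascending
    ranks fall in (lo*n, hi*n].

    Returns the normalized vector and the factor.  Raises
    :class:`NormalizationError` when the factor is not positive.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise NormalizationError("empty window")
    if not (0 < lo < hi <= 1):
        raise ValueError("require 0 < lo < hi <= 1")
    srt = np.sort(values)
    start, end = _rank_slice(values.size, lo, hi)
    factor = float(srt[start:end].mean())
    if not np.isfinite(factor) or factor <= 0:
        raise NormalizationError(
            f"normalization factor {factor!r} is not positive; skip window")
    return values / factor, factor


def enrichment(rt_nai: np.ndarray, rt_dmso: np.ndarray, bd_dmso: np.ndarray,
               alpha: float) -> np.ndarray:
    """Background-subtracted enrichment (rt_nai - alpha*rt_dmso) / bd_dmso.

    Positions with zero base density are undefined and returned as NaN.
    """
    rt_nai = np.asarray(rt_nai, dtype=float)
    rt_dmso = np.asarray(rt_dmso, dtype=float)
    bd_dmso = np.asarray(bd_dmso, dtype=float)
    if not (len(rt_nai) == len(rt_dmso) == len(bd_dmso)):
        raise ValueError("enrichment inputs must share one length")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    out = np.full(len(rt_nai), np.nan)
    ok = bd_dmso > 0
    out[ok] = (rt_nai[ok] - alpha * rt_dmso[ok]) / bd_dmso[ok]
    return out


def rescale_scores(e: np.ndarray, bd_dmso_raw: np.ndarray,
                   cfg: IcshapeConfig) -> np.ndarray:
    """Rescale enrichment between its lower/upper quantiles, clamp to [0, 1],
    and NULL out low-coverage or undefined bases.

    ``bd_dmso_raw`` is the *raw* merged base density used for the coverage
    cutoff (score only when bd >= cfg.coverage_min).
    """
    e = np.asarray(e, dtype=float)
    bd = np.asarray(bd_dmso_raw, dtype=float)
    defined = np.isfinite(e)
    out = np.full(e.shape, np.nan)
    if not defined.any():
        warnings.warn("all enrichment values undefined; all-NULL profile")
        return out
    q5 = np.quantile(e[defined], cfg.scale_lo)
    q95 = np.quantile(e[defined], cfg.scale_hi)
    if not q95 > q5:
        warnings.warn("degenerate enrichment quantiles; all-NULL profile")
        return out
    ok = defined & (bd >= cfg.coverage_min)
    out[ok] = np.clip((e[ok] - q5) / (q95 - q5), 0.0, 1.0)
    return out


def _window_starts(length: int, size: int, step: int) -> Iterable[Tuple[int, int]]:
    if length <= size:
        yield 0, length
        return
    last = length - size
    starts = list(range(0, last + 1, step))
    if starts[-1] != last:
        starts.append(last)
    for s in starts:
        yield s, s + size


def score_transcript(counts: RTBDCounts, cfg: IcshapeConfig | None = None) -> np.ndarray:
    """Full per-transcript pipeline: combine, then per sliding window
    normalize / enrich / rescale; overlapping windows averaged per base
    (NULL only when every covering window gives NULL).

    Returns a float array of the transcript length with NaN marking NULL.
    """
    cfg = cfg or IcshapeConfig()
    rt_dmso, rt_nai, bd_dmso = combine_replicates(counts)
    length = len(counts)
    acc = np.zeros(length)
    n_win = np.zeros(length, dtype=int)
    for start, end in _window_starts(length, cfg.window_size, cfg.window_step):
        try:
            rc, _ = normalize_counts(rt_dmso[start:end], cfg.norm_lo, cfg.norm_hi)
            rt, _ = normalize_counts(rt_nai[start:end], cfg.norm_lo, cfg.norm_hi)
            bc, _ = normalize_counts(bd_dmso[start:end], cfg.norm_lo, cfg.norm_hi)
        except NormalizationError:
            continue
        e = enrichment(rt, rc, bc, cfg.alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores = rescale_scores(e, bd_dmso[start:end], cfg)
        ok = np.isfinite(scores)
        acc[start:end][ok] += scores[ok]
        n_win[start:end][ok] += 1
    out = np.full(length, np.nan)
    covered = n_win > 0
    out[covered] = acc[covered] / n_win[covered]
    return out


# -- tabular I/O ----------------------------------------------------------

_COUNT_COLUMNS = ["transcript_id", "position", "rt_dmso_1", "rt_dmso_2",
                  "rt_nai_1", "rt_nai_2", "bd_dmso_1", "bd_dmso_2"]


def read_counts_table(path) -> Dict[str, RTBDCounts]:
    """Read a TSV of per-base counts (1-based positions) into per-transcript
    :class:`RTBDCounts`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    out: Dict[str, RTBDCounts] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if pos[0] != 1 or np.any(np.diff(pos) != 1):
            raise ValueError(f"transcript {tid}: positions must be 1..L contiguous")
        out[str(tid)] = RTBDCounts(
            transcript_id=str(tid),
            rt_dmso_rep1=grp["rt_dmso_1"].to_numpy(),
            rt_dmso_rep2=grp["rt_dmso_2"].to_numpy(),
            rt_nai_rep1=grp["rt_nai_1"].to_numpy(),
            rt_nai_rep2=grp["rt_nai_2"].to_numpy(),
            bd_dmso_rep1=grp["bd_dmso_1"].to_numpy(),
            bd_dmso_rep2=grp["bd_dmso_2"].to_numpy(),
        )
    return out


def write_reactivity_table(profiles: Dict[str, np.ndarray], path) -> None:
    """Write per-base scores as TSV (1-based positions, literal NULL for
    missing)."""
    rows = []
    for tid, scores in profiles.items():
        for i, s in enumerate(scores, start=1):
            rows.append((tid, i, "NULL" if not np.isfinite(s) else f"{s:.6f}"))
    pd.DataFrame(rows, columns=["transcript_id", "position", "score"]).to_csv(
        path, sep="\t", index=False)


def read_reactivity_table(path) -> Dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", na_values=["NULL"])
    out: Dict[str, np.ndarray] = {}
    for tid, grp in df.groupby("transcript_id", sort=False):
        grp = grp.sort_values("position")
        out[str(tid)] = grp["score"].to_numpy(dtype=float)
    return out
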