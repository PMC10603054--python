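"""Synthetic fixtures: random transcriptomes, confidence-ranked peaks,
motif-planted labelled datasets with structure preferences, and Poisson
RT/BD count tables consistent with a known reactivity truth.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .dataset import FixedSample, PeakRecord, TranscriptSet, TARGET_LEN, clean_rna
from .icshape import RTBDCounts

BASES = np.array(list("ACGU"))

__all__ = ["SynthConfig", "generate_transcriptome", "generate_peaks",
           "plant_motif_dataset", "simulate_rtbd"]


@dataclass
class SynthConfig:
    seed: int = 0
    n_transcripts: int = 20
    transcript_length_range: Tuple[int, int] = (300, 1200)
    motif: str = "GGACUACGG"
    motif_structure_mean: float = 0.9
    background_structure_mean: float = 0.3
    n_pos: int = 500
    n_neg: int = 1000
    read_depth: float = 100.0
    noise_sd: float = 0.1
    # count-model fixture constants
    background_rate: float = 0.1
    rt_gain: float = 1.0
    # when True the motif is planted in negatives too, so only the structure
    # profile separates the classes
    motif_in_negatives: bool = False

    def __post_init__(self):
        self.motif = clean_rna(self.motif, name="motif")
        if not (0 <= self.motif_structure_mean <= 1
                and 0 <= self.background_structure_mean <= 1):
            raise ValueError("structure means must be in [0, 1]")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_transcriptome(cfg: SynthConfig) -> TranscriptSet:
    """I.i.d.-uniform ACGU transcripts with lengths from the configured
    range."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.transcript_length_range
    records = []
    for i in range(cfg.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        records.append((f"synth_tx_{i:05d}", _random_rna(rng, length)))
    return TranscriptSet(records)


def generate_peaks(transcripts: TranscriptSet, n: int, seed: int = 0,
                   length_range: Tuple[int, int] = (30, 200)) -> List[PeakRecord]:
    """Random confidence-ranked peaks on the given transcriptome."""
    rng = np.random.default_rng(seed)
    tids = [tid for tid in transcripts
            if len(transcripts[tid]) >= length_range[1]]
    if not tids:
        raise ValueError("no transcript long enough for the peak length range")
    peaks = []
    for _ in range(n):
        tid = tids[rng.integers(0, len(tids))]
        plen = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, len(transcripts[tid]) - plen + 1))
        peaks.append(PeakRecord(transcript_id=tid, start=start,
                                end=start + plen,
                                confidence=float(rng.random())))
    return peaks


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               size: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), 0.0, 1.0)


def plant_motif_dataset(cfg: SynthConfig
                        ) -> Tuple[List[FixedSample], List[Optional[int]]]:
    """Labelled 101-nt samples with the motif planted at a uniform offset in
    every positive (and, if configured, every negative), plus per-base
    structure drawn around the motif/background means.

    Returns ``(samples, truth)`` where ``truth[i]`` is the 0-based planted
    offset or ``None``.
    """
    rng = np.random.default_rng(cfg.seed)
    m = len(cfg.motif)
    if m >= TARGET_LEN:
        raise ValueError("motif must be shorter than the sample length")
    samples: List[FixedSample] = []
    truth: List[Optional[int]] = []

    def make(label: int, plant: bool, idx: int):
        seq = list(_random_rna(rng, TARGET_LEN))
        struct = _truncnorm(rng, cfg.background_structure_mean, cfg.noise_sd,
                            TARGET_LEN)
        offset = None
        if plant:
            offset = int(rng.integers(0, TARGET_LEN - m + 1))
            seq[offset:offset + m] = cfg.motif
            if label == 1:
                struct[offset:offset + m] = _truncnorm(
                    rng, cfg.motif_structure_mean, cfg.noise_sd, m)
        samples.append(FixedSample(sequence="".join(seq), label=label,
                                   structure=struct,
                                   origin=(f"synth_{'pos' if label else 'neg'}_{idx}", 0)))
        truth.append(offset if label == 1 else None)

    for i in range(cfg.n_pos):
        make(1, True, i)
    for i in range(cfg.n_neg):
        make(0, cfg.motif_in_negatives, i)
    return samples, truth


def simulate_rtbd(transcript_id: str, truth_reactivity: np.ndarray,
                  cfg: SynthConfig) -> RTBDCounts:
    """Poisson count tables consistent with a known reactivity truth.

    Per replicate: base density ~ Poisson(read_depth); control RT-stops ~
    Poisson(read_depth * background_rate); treatment RT-stops ~
    Poisson(read_depth * (background_rate + rt_gain * truth)).
    """
    truth = np.asarray(truth_reactivity, dtype=float)
    if np.any((truth < 0) | (truth > 1)):
        raise ValueError("truth reactivity must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    n = len(truth)
    depth = cfg.read_depth
    bg = depth * cfg.background_rate
    nai_rate = depth * (cfg.background_rate + cfg.rt_gain * truth)

    def pois(rate):
        return rng.poisson(rate, size=n)

    return RTBDCounts(
        transcript_id=transcript_id,
        rt_dmso_rep1=pois(bg), rt_dmso_rep2=pois(bg),
        rt_nai_rep1=pois(nai_rate), rt_nai_rep2=pois(nai_rate),
        bd_dmso_rep1=pois(depth), bd_dmso_rep2=pois(depth),
    )
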