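"""Model interpretation: attention-based motif calling, PWM construction,
token-to-nucleotide saliency spreading, and gradient attribution.

Motif calling keeps maximal runs of consecutive tokens whose attention
(1) strictly exceeds the sequence mean and (2) is at least ten times the
floor score; runs whose nucleotide span is shorter than 6 nt are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .autograd import Tensor
from .dataset import FixedSample
from .model import BindingModel

MIN_FRAGMENT_NT = 6
FLOOR_EPS = 1e-8  # floor = max(min score, FLOOR_EPS * max score)

__all__ = ["MotifHit", "call_motifs", "build_pwm", "spread_attention",
           "gradient_saliency", "write_meme", "write_motif_hits"]


@dataclass
class MotifHit:
    token_start: int   # 0-based over interior tokens
    token_end: int     # inclusive
    nt_start: int      # 1-based inclusive
    nt_end: int        # 1-based inclusive
    fragment: str
    mean_score: float

    @property
    def nt_length(self) -> int:
        return self.nt_end - self.nt_start + 1


def call_motifs(att: np.ndarray, sample: FixedSample, k: int = 3
                ) -> List[MotifHit]:
    """Call high-attention fragments from a per-token attention vector."""
    att = np.asarray(att, dtype=float)
    n_tok = len(sample.sequence) - k + 1
    if len(att) != n_tok:
        raise ValueError(f"attention length {len(att)} != token count {n_tok}")
    mean = att.mean()
    floor = max(att.min(), FLOOR_EPS * att.max())
    qualifies = (att > mean) & (att >= 10.0 * floor)
    hits: List[MotifHit] = []
    i = 0
    while i < n_tok:
        if not qualifies[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_tok and qualifies[j + 1]:
            j += 1
        nt_start, nt_end = i + 1, j + k  # 1-based inclusive
        if nt_end - nt_start + 1 >= MIN_FRAGMENT_NT:
            hits.append(MotifHit(
                token_start=i, token_end=j, nt_start=nt_start, nt_end=nt_end,
                fragment=sample.sequence[nt_start - 1:nt_end],
                mean_score=float(att[i:j + 1].mean())))
        i = j + 1
    return hits


def build_pwm(fragments: Sequence[str], pseudocount: float = 0.0) -> np.ndarray:
    """4 x width position-probability matrix over A/C/G/U.

    Fragments are center-trimmed to the modal fragment length (ties broken
    toward the shorter length) and stacked without gaps.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    lengths = [len(f) for f in fragments]
    values, counts = np.unique(lengths, return_counts=True)
    width = int(values[np.argmax(counts)])
    base_index = {b: i for i, b in enumerate("ACGU")}
    counts_mat = np.full((4, width), float(pseudocount))
    for frag in fragments:
        extra = len(frag) - width
        if extra < 0:
            continue  # shorter than modal length: cannot trim to width
        lead = extra // 2
        for pos, base in enumerate(frag[lead:lead + width]):
            counts_mat[base_index[base], pos] += 1.0
    col_sums = counts_mat.sum(axis=0)
    if np.any(col_sums <= 0):
        raise ValueError("PWM has empty columns; fragments too short")
    return counts_mat / col_sums


def spread_attention(att: np.ndarray) -> np.ndarray:
    """Spread a 99-long token attention vector onto 101 nucleotides using
    the fixed five-case boundary rule (1-based indices)."""
    att = np.asarray(att, dtype=float)
    if len(att) != 99:
        raise ValueError(f"expected attention length 99, got {len(att)}")
    a = np.concatenate([[0.0], att])  # a[i] = Att_i, 1-based
    out = np.empty(101)
    for i in range(1, 102):
        if i == 1:
            out[i - 1] = a[1]
        elif i == 2:
            out[i - 1] = (a[i - 1] + a[i]) / 2.0
        elif i == 100:
            out[i - 1] = (a[i - 1] + a[i - 2]) / 2.0
        elif i == 101:
            # the only token covering the last base is the final one
            out[i - 1] = a[99]
        else:
            out[i - 1] = (a[i] + a[i - 1] + a[i - 2]) / 3.0
    return out


def gradient_saliency(model: BindingModel, seq_emb: np.ndarray,
                      struct_vec: np.ndarray, n_baselines: int = 16,
                      seed: int = 0, baseline: str = "shuffle",
                      reduce: bool = True) -> Tuple[np.ndarray, np.ndarray]:
    """Expected-gradients attribution of the binding logit with respect to
    the input features, reduced per token by the maximum over feature
    dimensions.

    ``seq_emb``: (d, L) embedding matrix; ``struct_vec``: (L,) structure
    vector.  Baselines are token-shuffled copies of the inputs (or zeros
    with ``baseline='zero'``); for each baseline the gradient is taken at a
    random point on the straight path from baseline to input and multiplied
    by (input - baseline).

    Returns ``(seq_scores, struct_scores)``, each of length L.
    """
    seq_emb = np.asarray(seq_emb, dtype=float)
    struct_vec = np.asarray(struct_vec, dtype=float)
    d, length = seq_emb.shape
    rng = np.random.default_rng(seed)
    was_training = model.training
    model.eval()
    seq_attr = np.zeros((d, length))
    struct_attr = np.zeros(length)
    for _ in range(max(1, n_baselines)):
        if baseline == "zero":
            base_seq = np.zeros_like(seq_emb)
            base_struct = np.zeros_like(struct_vec)
        else:
            perm = rng.permutation(length)
            base_seq = seq_emb[:, perm]
            base_struct = struct_vec[perm]
        t = rng.random()
        point_seq = Tensor(base_seq + t * (seq_emb - base_seq),
                           requires_grad=True)
        point_struct = Tensor(base_struct + t * (struct_vec - base_struct),
                              requires_grad=True)
        logit = model(point_seq.reshape(1, d, length),
                      point_struct.reshape(1, 1, length))
        logit.backward(np.ones(1))
        seq_attr += point_seq.grad * (seq_emb - base_seq)
        struct_attr += point_struct.grad * (struct_vec - base_struct)
    n = max(1, n_baselines)
    model.train(was_training)
    if not reduce:
        return seq_attr / n, struct_attr / n
    return (seq_attr / n).max(axis=0), struct_attr / n


def saliency_for_sample(predictor, sample: FixedSample, n_baselines: int = 16,
                        seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper: embed a sample with the predictor's encoder and
    attribute its logit."""
    seq_emb, struct = predictor.features([sample])
    return gradient_saliency(predictor.model, seq_emb.data[0],
                             struct.data[0, 0], n_baselines=n_baselines,
                             seed=seed)


def write_meme(pwms: Dict[str, np.ndarray], path) -> None:
    """Write PWMs in MEME minimal motif format (RNA alphabet)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for name, pwm in pwms.items():
            pwm = np.asarray(pwm)
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {pwm.shape[1]}\n")
            for col in pwm.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def write_motif_hits(hits: Dict[str, List[MotifHit]], path) -> None:
    import pandas as pd

    rows = []
    for sid, sample_hits in hits.items():
        for h in sample_hits:
            rows.append((sid, h.nt_start, h.nt_end, round(h.mean_score, 6),
                         h.fragment))
    pd.DataFrame(rows, columns=["sample_id", "nt_start", "nt_end",
                                "mean_score", "fragment"]).to_csv(
        path, sep="\t", index=False)
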