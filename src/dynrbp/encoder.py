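"""Per-token feature encoders.

Three interchangeable sources of token embeddings:

* :class:`TransformerEncoder` — a trainable multi-head self-attention
  encoder producing context-dependent ("dynamic") token vectors.  The
  full-size default is 12 layers x 768 units x 12 heads; a small 2-layer
  configuration is used for desk-scale training.
* :class:`OneHotEncoder` — static fallback; identical tokens always map to
  identical rows.
* :func:`load_precomputed` — reads per-sample token x d matrices from an
  HDF5 container keyed by sample id.

The encoder also exposes the [CLS]-row attention weights summed over heads,
used by the interpretation module for motif calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Optional, Sequence

import numpy as np

from . import nn
from .autograd import Tensor, concatenate, no_grad
from .dataset import TokenSequence, tokenize

SPECIAL_TOKENS = ["[PAD]", "[UNK]", "[CLS]", "[SEP]"]

__all__ = ["EncoderConfig", "KmerVocab", "AttentionParams", "self_attention",
           "TransformerEncoder", "OneHotEncoder", "load_precomputed",
           "save_precomputed"]


@dataclass
class EncoderConfig:
    k: int = 3
    d_model: int = 768
    n_layers: int = 12
    n_heads: int = 12
    d_ff: Optional[int] = None  # defaults to 4 * d_model
    max_len: int = 512
    dropout: float = 0.1
    attn_dropout: float = 0.1

    def __post_init__(self):
        if self.k not in (1, 2, 3, 4, 5, 6):
            raise ValueError("k must be in 1..6")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model

    @classmethod
    def small(cls, k: int = 3) -> "EncoderConfig":
        return cls(k=k, d_model=64, n_layers=2, n_heads=4, max_len=128)


class KmerVocab:
    """All 4^k k-mers plus the four special tokens."""

    def __init__(self, k: int):
        self.k = k
        kmers = ["".join(p) for p in product("ACGU", repeat=k)]
        self.tokens = SPECIAL_TOKENS + kmers
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.unk_id = self.index["[UNK]"]

    def __len__(self) -> int:
        return len(self.tokens)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.index.get(t, self.unk_id) for t in tokens],
                        dtype=np.int64)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\n".join(self.tokens) + "\n")


@dataclass
class AttentionParams:
    """Stacked per-head projections: wq/wk/wv (h, d_model, d_head) and the
    output projection wo (d_model, d_model)."""

    wq: np.ndarray
    wk: np.ndarray
    wv: np.ndarray
    wo: np.ndarray

    def __post_init__(self):
        h, d_model, d_head = np.shape(self.wq)
        for name in ("wk", "wv"):
            if np.shape(getattr(self, name)) != (h, d_model, d_head):
                raise ValueError(f"{name} shape inconsistent with wq")
        if np.shape(self.wo) != (h * d_head, d_model) \
                and np.shape(self.wo) != (d_model, d_model):
            raise ValueError("wo shape inconsistent with heads")


def self_attention(x: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Scaled dot-product multi-head self-attention on a tokens x d matrix.

    Per head: softmax(Q K^T / sqrt(d_head)) V with Q = X Wq etc.; head
    outputs are concatenated and projected by Wo.  Output shape equals the
    input shape.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D tokens x d matrix")
    if x.shape[1] != params.wq.shape[1]:
        raise ValueError(
            f"input width {x.shape[1]} != projection width {params.wq.shape[1]}")
    d_head = params.wq.shape[2]
    heads = []
    for wq, wk, wv in zip(params.wq, params.wk, params.wv):
        q, k, v = x @ wq, x @ wk, x @ wv
        logits = q @ k.T / np.sqrt(d_head)
        logits -= logits.max(axis=-1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=-1, keepdims=True)
        heads.append(probs @ v)
    return np.concatenate(heads, axis=1) @ params.wo


class MultiHeadAttention(nn.Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator,
                 attn_dropout: float = 0.0):
        super().__init__()
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = nn.Linear(d_model, d_model, rng)
        self.wk = nn.Linear(d_model, d_model, rng)
        self.wv = nn.Linear(d_model, d_model, rng)
        self.wo = nn.Linear(d_model, d_model, rng)
        self.attn_drop = nn.Dropout(attn_dropout, rng)
        self.last_attention: Optional[np.ndarray] = None

    def forward(self, x: Tensor, store_attention: bool = False) -> Tensor:
        n, t, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(z: Tensor) -> Tensor:  # (N,T,D) -> (N,h,T,dh)
            return z.reshape(n, t, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        probs = logits.softmax(axis=-1)
        if store_attention:
            self.last_attention = probs.data.copy()
        out = self.attn_drop(probs) @ v  # (N,h,T,dh)
        out = out.transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.wo(out)


class TransformerLayer(nn.Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng,
                                       attn_dropout=cfg.attn_dropout)
        self.ln1 = nn.LayerNorm(cfg.d_model)
        self.ln2 = nn.LayerNorm(cfg.d_model)
        self.ff1 = nn.Linear(cfg.d_model, cfg.d_ff, rng)
        self.ff2 = nn.Linear(cfg.d_ff, cfg.d_model, rng)
        self.drop = nn.Dropout(cfg.dropout, rng)

    def forward(self, x: Tensor, store_attention: bool = False) -> Tensor:
        x = self.ln1(x + self.drop(self.attn(x, store_attention=store_attention)))
        x = self.ln2(x + self.drop(self.ff2(self.ff1(x).relu())))
        return x


class TransformerEncoder(nn.Module):
    """Trainable dynamic contextual encoder over k-mer tokens."""

    def __init__(self, cfg: EncoderConfig, seed: int = 0,
                 positional: bool = True):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.vocab = KmerVocab(cfg.k)
        self.token_emb = nn.Embedding(len(self.vocab), cfg.d_model, rng)
        self.positional = positional
        self.pos_emb = nn.Embedding(cfg.max_len, cfg.d_model, rng) \
            if positional else None
        self.layers = [TransformerLayer(cfg, rng) for _ in range(cfg.n_layers)]

    @property
    def d_model(self) -> int:
        return self.cfg.d_model

    def encode_ids(self, sequences: Sequence[str]) -> np.ndarray:
        """Tokenize a batch of equal-length RNA strings -> (N, T) id array."""
        ids = [self.vocab.encode(tokenize(s, self.cfg.k).tokens)
               for s in sequences]
        lengths = {len(i) for i in ids}
        if len(lengths) != 1:
            raise ValueError("batch sequences must share one length")
        return np.stack(ids)

    def forward(self, ids: np.ndarray, store_attention: bool = False) -> Tensor:
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        if ids.shape[1] > self.cfg.max_len:
            raise ValueError(
                f"sequence of {ids.shape[1]} tokens exceeds max_len "
                f"{self.cfg.max_len}")
        x = self.token_emb(ids)
        if self.positional:
            x = x + self.pos_emb(np.arange(ids.shape[1]))
        for layer in self.layers:
            x = layer(x, store_attention=store_attention)
        return x  # (N, T, d)

    def embed_batch(self, sequences: Sequence[str]) -> Tensor:
        """Final-layer hidden states with [CLS]/[SEP] rows removed:
        (N, tokens, d)."""
        hidden = self.forward(self.encode_ids(sequences))
        return hidden[:, 1:-1, :]

    def embed(self, tokens: TokenSequence) -> np.ndarray:
        """Tokens x d matrix for one sample (special rows removed)."""
        ids = self.vocab.encode(tokens.tokens)
        with no_grad():
            was_training = self.training
            self.eval()
            hidden = self.forward(ids)
            self.train(was_training)
        out = hidden.data[0, 1:-1, :]
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite embedding values")
        return out

    def cls_attention_scores(self, tokens: TokenSequence,
                             layers: Sequence[int] | int = -1) -> np.ndarray:
        """Per-interior-token attention received from the [CLS] query,
        summed over heads (softmax denominator spans all tokens, specials
        included).  ``layers`` selects which layer(s) to read; multiple
        layers are averaged."""
        if isinstance(layers, int):
            layers = [layers]
        ids = self.vocab.encode(tokens.tokens)
        with no_grad():
            was_training = self.training
            self.eval()
            self.forward(ids, store_attention=True)
            self.train(was_training)
        per_layer = []
        for li in layers:
            probs = self.layers[li].attn.last_attention  # (1, h, T, T)
            per_layer.append(probs[0, :, 0, :].sum(axis=0))  # sum heads
        scores = np.mean(per_layer, axis=0)
        return scores[1:-1]  # interior tokens only


class OneHotEncoder:
    """Static encoder: one-hot over the k-mer vocabulary."""

    def __init__(self, k: int = 3):
        self.k = k
        self.vocab = KmerVocab(k)
        self.d_model = len(self.vocab)

    def embed(self, tokens: TokenSequence) -> np.ndarray:
        ids = self.vocab.encode(tokens.interior)
        out = np.zeros((len(ids), self.d_model))
        out[np.arange(len(ids)), ids] = 1.0
        return out

    def embed_batch(self, sequences: Sequence[str]) -> Tensor:
        mats = [self.embed(tokenize(s, self.k)) for s in sequences]
        return Tensor(np.stack(mats))


def save_precomputed(path, matrices: Dict[str, np.ndarray]) -> None:
    """Write per-sample token x d embedding matrices to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for sid, mat in matrices.items():
            fh.create_dataset(sid, data=np.asarray(mat))


def load_precomputed(path, sample_ids: Sequence[str],
                     d_model: Optional[int] = None) -> Dict[str, np.ndarray]:
    """Load per-sample embedding matrices, validating ids and width."""
    import h5py

    out: Dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        missing = [sid for sid in sample_ids if sid not in fh]
        if missing:
            raise KeyError(f"sample ids missing from {path}: {missing}")
        for sid in sample_ids:
            mat = np.asarray(fh[sid])
            if d_model is not None and mat.shape[1] != d_model:
                raise ValueError(
                    f"{sid}: embedding width {mat.shape[1]} != expected {d_model}")
            out[sid] = mat
    return out
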