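"""The binding-prediction network.

Pipeline: unified alignment of sequence-embedding and structure inputs to a
common channel width -> two independent multi-scale residual stacks (one
per input source) -> channel fusion (concatenation by default) -> a pyramid
of residual convolution blocks with stride-2 max-pooling that reduces the
token axis to length 1 -> fully connected layer -> sigmoid probability.

All convolutions are bias-free Conv-BN-ReLU blocks with same-padding;
dropout follows each activation and is disabled in evaluation mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import List, Sequence, Tuple

import numpy as np

from . import nn
from .autograd import Tensor, concatenate, no_grad
from .dataset import (FixedSample, TARGET_LEN, STRUCT_SENTINEL,
                      align_structure_to_tokens)

def _sigmoid64(logits: np.ndarray) -> np.ndarray:
    """Sigmoid in float64, clamped to the open interval (0, 1)."""
    p = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    return np.clip(p, 1e-12, 1.0 - 1e-12)


__all__ = ["ModelConfig", "CNNBlock", "UnifiedAlignment", "MultiScaleResidual",
           "PyramidPredictor", "BindingModel", "BindingPredictor",
           "pooled_length_trajectory", "variant_effect"]


@dataclass
class ModelConfig:
    d_model: int = 768          # width of the incoming token embeddings
    seq_len: int = 99           # token count (101 nt, k=3)
    align_channels: int = 128
    seq_align_kernel: int = 1
    struct_align_kernel: int = 3
    hmrn_branch_kernels: Tuple[int, ...] = (1, 3, 5, 7)
    hmrn_branch_depths: Tuple[int, ...] = (1, 2, 3, 4)
    hmrn_branch_channels: int = 32
    dprbp_kernel: int = 5
    dprbp_channels: int = 256
    dropout: float = 0.3
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    combine: str = "concat"     # or "add"
    use_structure: bool = True

    def __post_init__(self):
        if len(self.hmrn_branch_kernels) != len(self.hmrn_branch_depths):
            raise ValueError("branch kernel and depth lists must match")
        if any(k % 2 == 0 for k in self.hmrn_branch_kernels + (
                self.seq_align_kernel, self.struct_align_kernel,
                self.dprbp_kernel)):
            raise ValueError("all kernels must be odd for same-padding")
        n_branch = len(self.hmrn_branch_kernels)
        if n_branch * self.hmrn_branch_channels != self.align_channels:
            raise ValueError(
                f"branch channels x {n_branch} must equal align_channels "
                f"({n_branch * self.hmrn_branch_channels} != {self.align_channels})")
        fused = 2 * self.align_channels if self.combine == "concat" \
            else self.align_channels
        if fused != self.dprbp_channels:
            raise ValueError(
                f"fused channels {fused} must equal dprbp_channels "
                f"{self.dprbp_channels}")

    @classmethod
    def small(cls, d_model: int = 64, seq_len: int = 99) -> "ModelConfig":
        return cls(d_model=d_model, seq_len=seq_len, align_channels=64,
                   hmrn_branch_channels=16, dprbp_channels=128)


def pooled_length_trajectory(length: int) -> List[int]:
    """Lengths after each pool stage (pool size 3, stride 2, right-padded
    when shorter than the pool) until reaching 1."""
    traj = [length]
    while traj[-1] > 1:
        cur = max(traj[-1], 3)
        traj.append((cur - 3) // 2 + 1)
    return traj


class CNNBlock(nn.Module):
    """Conv (no bias, same padding) -> BatchNorm -> ReLU -> Dropout."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv1d(in_channels, out_channels, kernel, rng)
        self.bn = nn.BatchNorm1d(out_channels, momentum=cfg.bn_momentum,
                                 eps=cfg.bn_eps)
        self.drop = nn.Dropout(cfg.dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.drop(self.bn(self.conv(x)).relu())


class UnifiedAlignment(nn.Module):
    """Project the wide sequence embedding down and the 1-channel structure
    vector up to a common channel width."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.seq_block = CNNBlock(cfg.d_model, cfg.align_channels,
                                  cfg.seq_align_kernel, cfg, rng)
        self.struct_block = CNNBlock(1, cfg.align_channels,
                                     cfg.struct_align_kernel, cfg, rng)

    def forward(self, seq_emb: Tensor, struct_vec: Tensor) -> Tuple[Tensor, Tensor]:
        if seq_emb.shape[-1] != struct_vec.shape[-1]:
            raise ValueError(
                f"sequence length {seq_emb.shape[-1]} != structure length "
                f"{struct_vec.shape[-1]}")
        return self.seq_block(seq_emb), self.struct_block(struct_vec)


class MultiScaleResidual(nn.Module):
    """Parallel branches of stacked same-padding conv blocks with growing
    kernel sizes and depths; branch outputs concatenate back to the input
    width and join it through a residual ReLU."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.branches: List[nn.Sequential] = []
        for kernel, depth in zip(cfg.hmrn_branch_kernels, cfg.hmrn_branch_depths):
            blocks = []
            in_ch = cfg.align_channels
            for _ in range(depth):
                blocks.append(CNNBlock(in_ch, cfg.hmrn_branch_channels,
                                       kernel, cfg, rng))
                in_ch = cfg.hmrn_branch_channels
            self.branches.append(nn.Sequential(*blocks))

    def forward(self, x: Tensor) -> Tensor:
        multi = concatenate([b(x) for b in self.branches], axis=1)
        return (x + multi).relu()


class PyramidPredictor(nn.Module):
    """Stacked residual conv stages, each followed by max-pool(3, stride 2),
    until the token axis has length 1.  The two conv blocks inside a stage
    (and across stages) have independent parameters."""

    PAD_VALUE = -1e30  # max-pool-neutral right padding

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.trajectory = pooled_length_trajectory(cfg.seq_len)
        ch, kern = cfg.dprbp_channels, cfg.dprbp_kernel
        self.stages: List[List[CNNBlock]] = [
            [CNNBlock(ch, ch, kern, cfg, rng), CNNBlock(ch, ch, kern, cfg, rng)]
            for _ in self.trajectory[:-1]]

    def forward(self, x: Tensor) -> Tensor:
        for c1, c2 in self.stages:
            t = c1(c2(x))
            x = (x + t).relu()
            if x.shape[-1] < 3:
                x = x.pad_last(0, 3 - x.shape[-1], value=self.PAD_VALUE)
            x = x.maxpool1d(3, 2)
        return x.reshape(x.shape[0], x.shape[1])  # (N, C)


class BindingModel(nn.Module):
    """End-to-end network from (embedding matrix, structure vector) to a
    binding logit."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.alignment = UnifiedAlignment(cfg, rng)
        self.seq_hmrn = MultiScaleResidual(cfg, rng)
        self.struct_hmrn = MultiScaleResidual(cfg, rng)
        self.pyramid = PyramidPredictor(cfg, rng)
        self.head = nn.Linear(cfg.dprbp_channels, 1, rng)

    def forward(self, seq_emb: Tensor, struct_vec: Tensor) -> Tensor:
        """seq_emb: (N, d_model, L); struct_vec: (N, 1, L) -> logits (N,)."""
        if not np.all(np.isfinite(seq_emb.data)):
            raise FloatingPointError("non-finite sequence features")
        if not self.cfg.use_structure:
            struct_vec = Tensor(np.full_like(struct_vec.data, STRUCT_SENTINEL))
        seq_feat, struct_feat = self.alignment(seq_emb, struct_vec)
        seq_feat = self.seq_hmrn(seq_feat)
        struct_feat = self.struct_hmrn(struct_feat)
        if self.cfg.combine == "concat":
            fused = concatenate([seq_feat, struct_feat], axis=1)
        else:
            fused = seq_feat + struct_feat
        h = self.pyramid(fused)
        return self.head(h).reshape(h.shape[0])

    def predict_proba(self, seq_emb: Tensor, struct_vec: Tensor) -> np.ndarray:
        was_training = self.training
        self.eval()
        with no_grad():
            logits = self.forward(seq_emb, struct_vec)
        self.train(was_training)
        return _sigmoid64(logits.data)


class BindingPredictor:
    """Encoder + model pair operating directly on :class:`FixedSample`s."""

    def __init__(self, encoder, model: BindingModel, k: int = 3):
        self.encoder = encoder
        self.model = model
        self.k = k

    # -- feature assembly ----------------------------------------------------
    def structure_tokens(self, sample: FixedSample) -> np.ndarray:
        if sample.structure is None:
            return np.full(TARGET_LEN - self.k + 1, STRUCT_SENTINEL)
        return align_structure_to_tokens(sample.structure, self.k)

    def features(self, samples: Sequence[FixedSample]) -> Tuple[Tensor, Tensor]:
        """(N, d, L) embedding tensor (grad-capable) and (N, 1, L) structure
        tensor."""
        seq_emb = self.encoder.embed_batch([s.sequence for s in samples])
        seq_emb = seq_emb.transpose(0, 2, 1)  # (N, d, L)
        struct = np.stack([self.structure_tokens(s) for s in samples])
        struct = struct.astype(seq_emb.data.dtype, copy=False)
        return seq_emb, Tensor(struct[:, None, :])

    def forward_batch(self, samples: Sequence[FixedSample]) -> Tensor:
        seq_emb, struct = self.features(samples)
        return self.model(seq_emb, struct)

    def predict_proba(self, samples: Sequence[FixedSample],
                      batch_size: int = 64) -> np.ndarray:
        enc_training = getattr(self.encoder, "training", False)
        if hasattr(self.encoder, "eval"):
            self.encoder.eval()
        model_training = self.model.training
        self.model.eval()
        probs = []
        with no_grad():
            for i in range(0, len(samples), batch_size):
                logits = self.forward_batch(samples[i:i + batch_size])
                probs.append(_sigmoid64(logits.data))
        if hasattr(self.encoder, "train"):
            self.encoder.train(enc_training)
        self.model.train(model_training)
        return np.concatenate(probs) if probs else np.array([])

    def predict(self, sample: FixedSample) -> float:
        return float(self.predict_proba([sample])[0])

    def parameters(self):
        params = list(self.model.parameters())
        if hasattr(self.encoder, "parameters"):
            params += self.encoder.parameters()
        return params

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        from .encoder import TransformerEncoder

        payload = {"format_version": 1, "k": self.k,
                   "model_config": asdict(self.model.cfg)}
        arrays = {f"model/{k}": v for k, v in self.model.state_dict().items()}
        if isinstance(self.encoder, TransformerEncoder):
            payload["encoder_config"] = asdict(self.encoder.cfg)
            arrays.update({f"encoder/{k}": v
                           for k, v in self.encoder.state_dict().items()})
        else:
            payload["encoder_config"] = None
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(payload).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "BindingPredictor":
        from .encoder import EncoderConfig, OneHotEncoder, TransformerEncoder

        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
        mcfg = ModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["model_config"].items()})
        model = BindingModel(mcfg)
        model.load_state_dict({k[len("model/"):]: v for k, v in arrays.items()
                               if k.startswith("model/")})
        if meta["encoder_config"] is not None:
            enc = TransformerEncoder(EncoderConfig(**meta["encoder_config"]))
            enc.load_state_dict({k[len("encoder/"):]: v
                                 for k, v in arrays.items()
                                 if k.startswith("encoder/")})
        else:
            enc = OneHotEncoder(meta["k"])
        return cls(enc, model, k=meta["k"])


def variant_effect(predictor: BindingPredictor, sample: FixedSample,
                   position: int, alt_base: str
                   ) -> Tuple[float, float, float]:
    """Substitute one base (1-based position), re-embed and re-predict.

    Returns ``(p_ref, p_alt, delta)`` with ``delta = p_alt - p_ref``.  The
    structure vector is reused unchanged.
    """
    if not (1 <= position <= len(sample.sequence)):
        raise ValueError(f"position {position} outside 1..{len(sample.sequence)}")
    alt_base = alt_base.upper().replace("T", "U")
    if alt_base not in "ACGU":
        raise ValueError(f"alt base must be one of A/C/G/U, got {alt_base!r}")
    p_ref = predictor.predict(sample)
    ref_base = sample.sequence[position - 1]
    if alt_base == ref_base:
        warnings.warn("alt allele equals the reference base; delta is 0")
        return p_ref, p_ref, 0.0
    mutated = (sample.sequence[:position - 1] + alt_base
               + sample.sequence[position:])
    alt_sample = FixedSample(sequence=mutated, label=sample.label,
                             structure=sample.structure, origin=sample.origin)
    p_alt = predictor.predict(alt_sample)
    return p_ref, p_alt, p_alt - p_ref
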