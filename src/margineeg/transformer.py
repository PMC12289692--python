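"""Transformer pathway: cropping, patch encoding, encoder blocks.

Epochs are cut into non-overlapping 45-sample crops (each inheriting its
trial's label), linearly resized to 72 samples, split into patches and
linearly projected into tokens with learned positional embeddings.  Each
encoder block applies LayerNorm -> attention -> skip -> LayerNorm -> MLP ->
skip; the attention is either standard multi-head softmax attention or the
margin-optimized attention layer, selected by config.  Only the encoder is
used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .margin import MarginAttentionLayer
from .preprocess import EpochSet
from .training import TrainConfig, train_with_early_stopping

__all__ = ["TransformerConfig", "CropSet", "crop_series", "resize_crops",
           "PatchEncoder", "TransformerBlock", "TransformerClassifier",
           "build_transformer", "train_with_early_stopping", "TrainConfig"]


@dataclass(frozen=True)
class TransformerConfig:
    crop_len: int = 45
    resize_len: int = 72
    patch_size: int = 8          # unstated upstream; config-exposed default
    n_blocks: int = 1
    n_heads: int = 2
    projection_dim: int = 16
    mlp_hidden: tuple[int, ...] = (32,)
    use_conv_down: bool = False
    conv_depths: tuple[int, ...] = ()
    conv_kernel: int = 8
    attention_kind: str = "multi_head"   # multi_head | svm_margin
    margin_d_phi: int = 16
    margin_C: float = 1.0

    def __post_init__(self):
        if self.resize_len % self.patch_size:
            raise ValueError("resize_len must be divisible by patch_size")
        if self.projection_dim % self.n_heads:
            raise ValueError("n_heads must divide projection_dim")
        if self.attention_kind not in ("multi_head", "svm_margin"):
            raise ValueError(f"unknown attention kind {self.attention_kind!r}")

    @property
    def n_tokens(self) -> int:
        return self.resize_len // self.patch_size


@dataclass
class CropSet:
    """Non-overlapping crops with trial bookkeeping."""

    data: np.ndarray        # (n_crops, channels, crop_len)
    labels: np.ndarray      # inherited trial labels, {-1,+1}
    trial_index: np.ndarray  # source trial of each crop

    @property
    def n_crops(self) -> int:
        return self.data.shape[0]


def crop_series(epochs: EpochSet, crop_len: int = 45) -> CropSet:
    """floor(samples/crop_len) consecutive crops per trial; remainder dropped."""
    if crop_len > epochs.n_samples:
        raise ValueError(f"crop_len {crop_len} exceeds epoch length {epochs.n_samples}")
    per_trial = epochs.n_samples // crop_len
    usable = epochs.data[:, :, :per_trial * crop_len]
    n_tr, C, _ = usable.shape
    crops = usable.reshape(n_tr, C, per_trial, crop_len)
    crops = crops.transpose(0, 2, 1, 3).reshape(n_tr * per_trial, C, crop_len)
    labels = np.repeat(epochs.labels, per_trial)
    trial_index = np.repeat(np.arange(n_tr), per_trial)
    return CropSet(data=crops, labels=labels, trial_index=trial_index)


def resize_crops(crops: np.ndarray, resize_len: int) -> np.ndarray:
    """1-D linear interpolation of each channel onto resize_len samples."""
    n_in = crops.shape[-1]
    if n_in == resize_len:
        return crops
    # two-point interpolation weights as a (resize_len, n_in) matrix
    pos = np.linspace(0.0, n_in - 1.0, resize_len)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = pos - lo
    W = np.zeros((resize_len, n_in))
    W[np.arange(resize_len), lo] += 1.0 - frac
    W[np.arange(resize_len), hi] += frac
    return crops @ W.T


class PatchEncoder(nn.Module):
    """Flattened patches -> linear projection + learned positional embedding."""

    def __init__(self, n_channels: int, cfg: TransformerConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.proj = nn.Linear(n_channels * cfg.patch_size, cfg.projection_dim, rng)
        self.pos = nn.Tensor(rng.normal(0, 0.02,
                                        size=(cfg.n_tokens, cfg.projection_dim)),
                             requires_grad=True)

    def __call__(self, x: np.ndarray) -> nn.Tensor:
        B, C, L = x.shape
        p = self.cfg.patch_size
        n_tok = L // p
        patches = x.reshape(B, C, n_tok, p).transpose(0, 2, 1, 3)
        flat = nn.Tensor(patches.reshape(B, n_tok, C * p))
        return self.proj(flat) + self.pos


class TransformerBlock(nn.Module):
    """LN -> attention -> skip -> LN -> MLP -> skip.

    With zero-initialized attention/MLP output projections the block is the
    identity map (both residual branches vanish).
    """

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator,
                 zero_residual: bool = False):
        super().__init__()
        d = cfg.projection_dim
        self.kind = cfg.attention_kind
        self.ln1 = nn.LayerNorm(d)
        self.ln2 = nn.LayerNorm(d)
        if cfg.attention_kind == "multi_head":
            self.attn = nn.MultiHeadSelfAttention(d, cfg.n_heads, rng,
                                                  zero_out=zero_residual)
        else:
            self.margin_attn = MarginAttentionLayer(
                d_model=d, d_phi=cfg.margin_d_phi, rng=rng, C=cfg.margin_C,
                n_heads=cfg.n_heads, mode="svm_margin")
            self.attn_out = nn.Linear(d, d, rng, zero_init=zero_residual)
        self.mlp = nn.MLP(d, list(cfg.mlp_hidden), d, rng,
                          zero_out=zero_residual)

    def __call__(self, tokens: nn.Tensor, labels: np.ndarray | None = None):
        aux = nn.Tensor(0.0)
        h = self.ln1(tokens)
        if self.kind == "multi_head":
            a = self.attn(h)
        else:
            # margin scores are query-independent: every token receives the
            # same margin-weighted mixture of values
            ctx, _, aux = self.margin_attn(h, labels=labels)
            B, T, d = h.shape
            a = self.attn_out(ctx.reshape(B, 1, d) + h * 0.0)
        t2 = tokens + a
        return t2 + self.mlp(self.ln2(t2)), aux


class TransformerClassifier(nn.Module):
    """Encoder-only classifier over crops: tokens -> blocks -> pooled head."""

    def __init__(self, n_channels: int, cfg: TransformerConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.convs = []
        ch = n_channels
        if cfg.use_conv_down and cfg.conv_depths:
            in_d = n_channels
            for d in cfg.conv_depths:
                self.convs.append(nn.ConvTemporal(in_d, d, cfg.conv_kernel, rng))
                in_d = d
            ch = cfg.conv_depths[-1]
        self.encoder = PatchEncoder(ch, cfg, rng)
        self.blocks = [TransformerBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.ln = nn.LayerNorm(cfg.projection_dim)
        self.head = nn.MLP(cfg.projection_dim, [2 * cfg.projection_dim], 2, rng)

    def _front(self, x: np.ndarray) -> np.ndarray:
        if self.convs:
            t = nn.Tensor(x[:, :, None, :])
            for conv in self.convs:
                t = conv(t).relu()
            x = t.data[:, :, 0, :]
        return resize_crops(x, self.cfg.resize_len)

    def forward(self, x: np.ndarray, labels: np.ndarray | None = None):
        tokens = self.encoder(self._front(np.asarray(x, dtype=np.float64)))
        aux_total = nn.Tensor(0.0)
        for blk in self.blocks:
            tokens, aux = blk(tokens, labels=labels)
            aux_total = aux_total + aux
        pooled = self.ln(tokens).mean(axis=1)
        return self.head(pooled), aux_total, None

    def predict_logits(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            logits, _, _ = self.forward(x[i:i + batch_size])
            outs.append(logits.data)
        self.train()
        return np.concatenate(outs, axis=0)

    def pooled_features(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            tokens = self.encoder(self._front(np.asarray(x[i:i + batch_size],
                                                         dtype=np.float64)))
            for blk in self.blocks:
                tokens, _ = blk(tokens)
            outs.append(self.ln(tokens).mean(axis=1).data)
        self.train()
        return np.concatenate(outs, axis=0)


def build_transformer(n_channels: int, cfg: TransformerConfig,
                      seed: int = 0) -> TransformerClassifier:
    return TransformerClassifier(n_channels, cfg, np.random.default_rng(seed))
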