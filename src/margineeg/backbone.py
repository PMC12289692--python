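"""Channels-as-depth CNN + bidirectional LSTM decoding backbone.

The convolutional front end treats EEG electrodes the way image networks
treat RGB planes: the electrode axis becomes the convolutional depth, kernels
are purely temporal, (1, k), and each layer halves the time axis
(out = ceil(in / 2)) via stride-2 convolution with same-style zero padding.
Depth grows in an algebraic progression chans*k0, chans*(k0+1), ... rather
than geometrically, which keeps the flattened feature count small: with 64
electrodes, a 180-sample window and six layers the final feature map is
(448, 1, 3) - 1,344 features instead of the 49,152 a preserved-spatial
baseline produces, and the per-timestep LSTM input is 448 instead of 16,384.

The remaining time steps of the last feature map form the sequence fed to a
many-to-one bidirectional LSTM; an optional attention layer (softmax,
multi-head, or margin-optimized) pools the LSTM output sequence before the
fully connected head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import nn
from .margin import MarginAttentionLayer
from .preprocess import EpochSet

__all__ = [
    "BackboneConfig", "LayerShape", "depth_progression", "shape_trace",
    "build_backbone", "abs_tanh", "CNNBiLSTM", "prepare_input",
]


def depth_progression(chans: int, n_layers: int, k0: int = 1) -> list[int]:
    """Algebraic depth schedule [chans*k0, chans*(k0+1), ...]."""
    if chans < 1 or n_layers < 1 or k0 < 1:
        raise ValueError("chans, n_layers and k0 must be positive")
    return [chans * (k0 + i) for i in range(n_layers)]


def abs_tanh(x):
    """Experimental activation |x| * tanh(x) for the fully connected head.

    Odd, monotone non-decreasing, ~x^2 near zero (dampens small
    fluctuations) and ~|x| for large inputs.
    """
    x = np.asarray(x, dtype=float)
    out = np.abs(x) * np.tanh(x)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BackboneConfig:
    in_channels: int = 22
    n_layers: int = 6
    depth_start_multiplier: int = 1          # k0
    kernel: int = 8                          # temporal kernel (1, k)
    spatial_mode: str = "collapsed"          # channels-as-depth; "preserved" baseline
    depths: tuple[int, ...] | None = None    # explicit override of the progression
    lstm_hidden: int = 128
    lstm_bidirectional: bool = True
    activation: str = "relu"                 # head activation: relu | abs_tanh
    batch_norm: bool = True
    attention: str = "none"                  # none | softmax | multi_head | svm_margin
    attn_dim: int = 32
    n_heads: int = 1
    head_hidden: int = 32
    input_time: int = 180                    # samples fed to the CNN
    input_map: str = "decimate"              # crop | decimate (epoch -> input_time)
    margin_C: float = 1.0
    lambda_aux: float = 0.1

    def __post_init__(self):
        if self.depth_start_multiplier < 1 or self.n_layers < 1 or self.in_channels < 1:
            raise ValueError("counts must be positive")
        if self.kernel not in (8, 24, 40):
            raise ValueError("kernel width must be one of 8, 24, 40")
        if self.spatial_mode not in ("collapsed", "preserved"):
            raise ValueError("spatial_mode must be 'collapsed' or 'preserved'")
        if self.activation not in ("relu", "abs_tanh"):
            raise ValueError("activation must be 'relu' or 'abs_tanh'")
        if self.attention not in ("none", "softmax", "multi_head", "svm_margin"):
            raise ValueError(f"unknown attention kind {self.attention!r}")

    def depth_schedule(self) -> list[int]:
        if self.depths is not None:
            return list(self.depths)
        return depth_progression(self.in_channels, self.n_layers,
                                 self.depth_start_multiplier)


@dataclass(frozen=True)
class LayerShape:
    batch: int
    depth: int
    spatial: int
    time: int

    def __post_init__(self):
        if min(self.batch, self.depth, self.spatial, self.time) < 1:
            raise ValueError("layer dimensions must be positive")

    @property
    def flattened(self) -> int:
        return self.depth * self.spatial * self.time

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.batch, self.depth, self.spatial, self.time)


def shape_trace(cfg: BackboneConfig, input_time: int | None = None,
                batch: int = 1) -> list[LayerShape]:
    """Per-layer output shapes (batch, depth, spatial, time) of the CNN stack.

    The time axis follows out = ceil(in / 2); spatial is 1 in collapsed mode
    (electrodes become depth) and in_channels in preserved mode.
    """
    t = int(input_time if input_time is not None else cfg.input_time)
    if t < 2 ** cfg.n_layers:
        raise ValueError(
            f"input_time {t} too short for {cfg.n_layers} halvings")
    depths = cfg.depth_schedule()
    spatial = 1 if cfg.spatial_mode == "collapsed" else cfg.in_channels
    shapes: list[LayerShape] = []
    for d in depths:
        t = math.ceil(t / 2)
        if t < 1:
            raise ValueError("time dimension collapsed to zero")
        shapes.append(LayerShape(batch=batch, depth=d, spatial=spatial, time=t))
    return shapes


def prepare_input(epochs: EpochSet, input_time: int, mode: str = "decimate") -> np.ndarray:
    """Map (trials, channels, samples) epochs onto the CNN input window."""
    T = epochs.n_samples
    if mode == "crop":
        if T < input_time:
            raise ValueError("epochs shorter than the requested input window")
        return epochs.data[:, :, :input_time]
    if mode == "decimate":
        if T == input_time:
            return epochs.data
        return sps.resample(epochs.data, input_time, axis=-1)
    raise ValueError("input_map must be 'crop' or 'decimate'")


class CNNBiLSTM(nn.Module):
    """The trainable network realizing a BackboneConfig.

    forward(x, labels=None) -> (logits, aux_loss, attention_weights);
    aux_loss is the margin-attention hinge surrogate (zero tensor unless
    attention == 'svm_margin' and labels are given).
    """

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        depths = cfg.depth_schedule()
        in_depth = cfg.in_channels if cfg.spatial_mode == "collapsed" else 1
        spatial = 1 if cfg.spatial_mode == "collapsed" else cfg.in_channels
        self.convs, self.bns = [], []
        for d in depths:
            self.convs.append(nn.ConvTemporal(in_depth, d, cfg.kernel, rng))
            self.bns.append(nn.BatchNorm(d) if cfg.batch_norm else None)
            in_depth = d
        self.feat_dim = depths[-1] * spatial
        h = cfg.lstm_hidden
        self.lstm = nn.BiLSTM(self.feat_dim, h, rng)
        d_seq = 2 * h if cfg.lstm_bidirectional else h
        self.attn_kind = cfg.attention
        if cfg.attention == "multi_head":
            self.mha = nn.MultiHeadSelfAttention(d_seq, cfg.n_heads, rng)
        elif cfg.attention in ("softmax", "svm_margin"):
            self.margin_attn = MarginAttentionLayer(
                d_model=d_seq, d_phi=cfg.attn_dim, rng=rng, C=cfg.margin_C,
                n_heads=cfg.n_heads,
                mode="softmax" if cfg.attention == "softmax" else "svm_margin")
        self.head = nn.MLP(d_seq, [cfg.head_hidden], 2, rng,
                           activation=cfg.activation)

    def _cnn_sequence(self, x: np.ndarray) -> nn.Tensor:
        B, C, T = x.shape
        if self.cfg.spatial_mode == "collapsed":
            t = nn.Tensor(x.reshape(B, C, 1, T))
        else:
            t = nn.Tensor(x.reshape(B, 1, C, T))
        for conv, bn in zip(self.convs, self.bns):
            t = conv(t)
            if bn is not None:
                t = bn(t)
            t = t.relu()
        B_, D, H, Tt = t.shape
        # time becomes the sequence axis; depth (x spatial) the feature vector
        return t.transpose(0, 3, 1, 2).reshape(B_, Tt, D * H)

    def forward(self, x: np.ndarray, labels: np.ndarray | None = None):
        seq = self._cnn_sequence(np.asarray(x, dtype=np.float64))
        aux = nn.Tensor(0.0)
        weights = None
        if self.attn_kind == "none":
            pooled = self.lstm.last_hidden(seq)
        elif self.attn_kind == "multi_head":
            hs = self.lstm.sequence(seq)
            att, w = self.mha(hs, return_weights=True)
            pooled = att.mean(axis=1)
            weights = w.data.mean(axis=1)  # average heads -> (batch, T, T)
        else:
            hs = self.lstm.sequence(seq)
            pooled, w, aux = self.margin_attn(hs, labels=labels)
            weights = w.data
        logits = self.head(pooled)
        return logits, aux, weights

    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            logits, _, _ = self.forward(x[i:i + batch_size])
            outs.append(logits.data)
        self.train()
        return np.concatenate(outs, axis=0)

    def pooled_features(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Attention-pooled (or last-hidden) feature vectors, for diagnostics."""
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            seq = self._cnn_sequence(np.asarray(x[i:i + batch_size], dtype=np.float64))
            if self.attn_kind == "none":
                pooled = self.lstm.last_hidden(seq)
            elif self.attn_kind == "multi_head":
                hs = self.lstm.sequence(seq)
                pooled = self.mha(hs).mean(axis=1)
            else:
                hs = self.lstm.sequence(seq)
                pooled, _, _ = self.margin_attn(hs)
            outs.append(pooled.data)
        self.train()
        return np.concatenate(outs, axis=0)


def build_backbone(cfg: BackboneConfig, seed: int = 0) -> CNNBiLSTM:
    """Construct the network and verify it against the analytic shape trace."""
    rng = np.random.default_rng(seed)
    model = CNNBiLSTM(cfg, rng)
    trace = shape_trace(cfg)
    expected = trace[-1].depth * trace[-1].spatial
    if model.feat_dim != expected:
        raise RuntimeError(
            f"LSTM feature dimension {model.feat_dim} != trace {expected}")
    return model
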