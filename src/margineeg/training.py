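"""Shared training loop: AdamW, mini-batches, metric-based early stopping.

Used by both the CNN+BiLSTM backbone and the transformer variant.  Models must
expose ``forward(x, labels) -> (logits, aux_loss, weights)``,
``predict_logits``, ``state_arrays`` and ``load_state_arrays``.

Labels are {-1, +1} throughout the package; they are mapped to class indices
(0, 1) only at the cross-entropy boundary.  Ties in predicted logits break
toward the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["TrainConfig", "TrainHistory", "train_with_early_stopping",
           "logits_to_labels"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-2
    epochs: int = 50
    batch_size: int = 128
    patience: int = 10
    min_delta: float = 0.0
    lambda_aux: float = 0.1
    metric: str = "accuracy"     # maximized; "loss" is monitored negated
    seed: int = 0


@dataclass
class TrainHistory:
    train_loss: list
    val_loss: list
    val_accuracy: list
    best_epoch: int
    stopped_epoch: int

    def as_dict(self) -> dict:
        return {"train_loss": self.train_loss, "val_loss": self.val_loss,
                "val_accuracy": self.val_accuracy,
                "best_epoch": self.best_epoch, "stopped_epoch": self.stopped_epoch}


def logits_to_labels(logits: np.ndarray) -> np.ndarray:
    """argmax over 2 logits -> {-1,+1}; exact ties go to the negative class."""
    return np.where(logits[:, 1] > logits[:, 0], 1, -1)


def _val_metrics(model, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = model.predict_logits(x)
    cls = ((y + 1) // 2).astype(int)
    shifted = logits - logits.max(axis=1, keepdims=True)
    logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    loss = float(-logp[np.arange(len(cls)), cls].mean())
    acc = float((logits_to_labels(logits) == y).mean())
    return loss, acc


def train_with_early_stopping(model, train_x: np.ndarray, train_y: np.ndarray,
                              val_x: np.ndarray, val_y: np.ndarray,
                              cfg: TrainConfig = TrainConfig()) -> TrainHistory:
    """Train with AdamW; stop when the monitored metric ceases to improve.

    The best value is initialized to -infinity (metrics are maximized;
    validation loss is monitored as its negative), and the best checkpoint is
    restored before returning.  With patience=0 training stops at the first
    non-improving epoch.
    """
    if len(val_x) == 0:
        raise ValueError("validation set must be non-empty for early stopping")
    if len(train_x) == 0:
        raise ValueError("training set must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    n = len(train_x)
    cls = ((train_y + 1) // 2).astype(int)

    best = -np.inf
    best_state = model.state_arrays()
    best_epoch = -1
    since_improve = 0
    hist = TrainHistory([], [], [], best_epoch=0, stopped_epoch=0)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        model.train()
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            logits, aux, _ = model.forward(train_x[idx], labels=train_y[idx])
            loss = nn.cross_entropy(logits, cls[idx]) + cfg.lambda_aux * aux
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += float(loss.data) * len(idx)
        hist.train_loss.append(ep_loss / n)
        vloss, vacc = _val_metrics(model, val_x, val_y)
        hist.val_loss.append(vloss)
        hist.val_accuracy.append(vacc)
        monitored = vacc if cfg.metric == "accuracy" else -vloss
        if monitored > best + cfg.min_delta:
            best = monitored
            best_state = model.state_arrays()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve > cfg.patience:
                break
    model.load_state_arrays(best_state)
    hist.best_epoch = best_epoch
    hist.stopped_epoch = epoch
    return hist
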