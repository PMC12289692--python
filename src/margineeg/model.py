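"""Model/Results interface tying the pipeline together.

`EEGDecoder` is built from an EpochSet (or raw recordings) plus architecture
configs; `.fit()` trains the network and returns a `DecoderResults` carrying
the fitted parameters, training history, diagnostics and a `summary()` table.
`run_loso` and `run_ablation` drive subject-independent evaluation on top of
these two objects.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .backbone import BackboneConfig, build_backbone, prepare_input
from .evaluate import (MetricsReport, class_separation, classification_metrics,
                       loso_folds, stratified_split)
from .preprocess import EpochSet, FilterSpec, highpass_filter, reject_trials, \
    segment_epochs
from .synth import RawRecording
from .training import TrainConfig, logits_to_labels, train_with_early_stopping
from .transformer import TransformerConfig, build_transformer, crop_series

__all__ = ["EEGDecoder", "DecoderResults", "concat_epochs",
           "preprocess_dataset", "run_loso", "run_ablation", "ABLATION_VARIANTS"]


def concat_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Stack trials of several subjects; channel counts must agree."""
    if not epoch_sets:
        raise ValueError("no epoch sets given")
    chans = {e.n_channels for e in epoch_sets}
    if len(chans) > 1:
        raise ValueError(f"channel counts differ across subjects: {sorted(chans)}")
    return EpochSet(
        data=np.concatenate([e.data for e in epoch_sets]),
        labels=np.concatenate([e.labels for e in epoch_sets]),
        fs=epoch_sets[0].fs, subject_id=-1,
        kept_trial_idx=np.concatenate([e.kept_trial_idx for e in epoch_sets]),
        channel_names=epoch_sets[0].channel_names)


def preprocess_dataset(recordings: list[RawRecording],
                       spec: FilterSpec = FilterSpec(),
                       trial_len: float = 4.0,
                       reject: bool = True) -> list[EpochSet]:
    """Filter -> segment -> trial rejection for each subject.

    Channel rejection is skipped here: dropping different electrodes per
    subject would misalign the channel axis across the LOSO folds.
    """
    out = []
    for rec in recordings:
        ep = segment_epochs(highpass_filter(rec, spec), trial_len=trial_len)
        if reject:
            ep, _ = reject_trials(ep)
        out.append(ep)
    return out


class EEGDecoder:
    """A decoding model bound to training data.

    arch 'cnn_lstm' uses the channels-as-depth CNN + BiLSTM backbone (with
    optional attention pooling per BackboneConfig.attention); 'transformer'
    trains on 45-sample crops and predicts trials by averaging crop logits.
    """

    def __init__(self, epochs: EpochSet, arch: str = "cnn_lstm",
                 backbone: BackboneConfig | None = None,
                 transformer: TransformerConfig | None = None,
                 train: TrainConfig | None = None):
        if arch not in ("cnn_lstm", "transformer"):
            raise ValueError(f"unknown arch {arch!r}")
        if epochs.n_trials == 0:
            raise ValueError("cannot build a model from an empty EpochSet")
        self.epochs = epochs
        self.arch = arch
        self.backbone = backbone or BackboneConfig(in_channels=epochs.n_channels)
        self.transformer = transformer or TransformerConfig()
        self.train_cfg = train or TrainConfig()
        if arch == "cnn_lstm" and self.backbone.in_channels != epochs.n_channels:
            raise ValueError("backbone.in_channels must match the epoch data")

    @classmethod
    def from_recordings(cls, recordings: list[RawRecording],
                        spec: FilterSpec = FilterSpec(),
                        trial_len: float = 4.0, **kwargs) -> "EEGDecoder":
        eps = preprocess_dataset(recordings, spec=spec, trial_len=trial_len)
        return cls(concat_epochs(eps), **kwargs)

    # ------------------------------------------------------------------ data
    def _trial_inputs(self, epochs: EpochSet) -> np.ndarray:
        if self.arch == "cnn_lstm":
            return prepare_input(epochs, self.backbone.input_time,
                                 self.backbone.input_map)
        return epochs.data

    def fit(self, val_epochs: EpochSet | None = None,
            val_fraction: float = 0.15, seed: int = 0) -> "DecoderResults":
        """Train with early stopping; returns the fitted Results object.

        If no validation EpochSet is given, a label-stratified fraction of
        the training trials is held out.
        """
        rng = np.random.default_rng(seed)
        epochs = self.epochs
        if val_epochs is None:
            tr_idx, va_idx = stratified_split(epochs.labels, val_fraction, rng)
            tr = EpochSet(epochs.data[tr_idx], epochs.labels[tr_idx], epochs.fs,
                          channel_names=epochs.channel_names)
            va = EpochSet(epochs.data[va_idx], epochs.labels[va_idx], epochs.fs,
                          channel_names=epochs.channel_names)
        else:
            tr, va = epochs, val_epochs

        x_tr = self._trial_inputs(tr)
        scale_mu = float(x_tr.mean())
        scale_sd = float(x_tr.std()) or 1.0

        cfg = replace(self.train_cfg, seed=seed)
        if self.arch == "cnn_lstm":
            model = build_backbone(self.backbone, seed=seed)
            xt = (x_tr - scale_mu) / scale_sd
            xv = (self._trial_inputs(va) - scale_mu) / scale_sd
            hist = train_with_early_stopping(model, xt, tr.labels, xv, va.labels, cfg)
        else:
            crops_tr = crop_series(tr, self.transformer.crop_len)
            crops_va = crop_series(va, self.transformer.crop_len)
            model = build_transformer(tr.n_channels, self.transformer, seed=seed)
            xt = (crops_tr.data - scale_mu) / scale_sd
            xv = (crops_va.data - scale_mu) / scale_sd
            hist = train_with_early_stopping(model, xt, crops_tr.labels,
                                             xv, crops_va.labels, cfg)
        return DecoderResults(decoder=self, model=model, history=hist,
                              scale=(scale_mu, scale_sd), seed=seed,
                              val_epochs=va)


@dataclass
class DecoderResults:
    decoder: EEGDecoder
    model: object
    history: object
    scale: tuple[float, float]
    seed: int
    val_epochs: EpochSet | None = None

    # ------------------------------------------------------------- inference
    def _scaled(self, x: np.ndarray) -> np.ndarray:
        mu, sd = self.scale
        return (x - mu) / sd

    def predict_logits(self, epochs: EpochSet) -> np.ndarray:
        if self.decoder.arch == "cnn_lstm":
            x = self._scaled(self.decoder._trial_inputs(epochs))
            return self.model.predict_logits(x)
        crops = crop_series(epochs, self.decoder.transformer.crop_len)
        logits = self.model.predict_logits(self._scaled(crops.data))
        # average crop logits per source trial
        out = np.zeros((epochs.n_trials, 2))
        for t in range(epochs.n_trials):
            out[t] = logits[crops.trial_index == t].mean(axis=0)
        return out

    def predict(self, epochs: EpochSet) -> np.ndarray:
        return logits_to_labels(self.predict_logits(epochs))

    def features(self, epochs: EpochSet) -> np.ndarray:
        """Attention-pooled feature vectors (the class-separation diagnostic)."""
        if self.decoder.arch == "cnn_lstm":
            x = self._scaled(self.decoder._trial_inputs(epochs))
            return self.model.pooled_features(x)
        crops = crop_series(epochs, self.decoder.transformer.crop_len)
        feats = self.model.pooled_features(self._scaled(crops.data))
        out = np.zeros((epochs.n_trials, feats.shape[1]))
        for t in range(epochs.n_trials):
            out[t] = feats[crops.trial_index == t].mean(axis=0)
        return out

    def attention(self, epochs: EpochSet) -> np.ndarray | None:
        """Per-trial attention weights over key positions (rows sum to 1)."""
        if self.decoder.arch != "cnn_lstm" or \
                self.decoder.backbone.attention == "none":
            return None
        x = self._scaled(self.decoder._trial_inputs(epochs))
        self.model.eval()
        _, _, w = self.model.forward(x)
        self.model.train()
        if w is None:
            return None
        if w.ndim == 3:  # multi-head: average query positions
            w = w.mean(axis=1)
        return w / w.sum(axis=1, keepdims=True)

    def score(self, epochs: EpochSet) -> MetricsReport:
        pred = self.predict(epochs)
        acc, f1, sens = classification_metrics(epochs.labels, pred)
        try:
            sep = class_separation(self.features(epochs), epochs.labels)
        except ValueError:
            sep = np.nan
        return MetricsReport(accuracy=acc, f1=f1, sensitivity=sens,
                             class_separation=sep, seed=self.seed)

    def summary(self) -> str:
        buf = _io.StringIO()
        d = self.decoder
        n_params = sum(p.data.size for p in self.model.parameters())
        buf.write("EEGDecoder results\n")
        buf.write("=" * 50 + "\n")
        buf.write(f"architecture:      {d.arch}\n")
        if d.arch == "cnn_lstm":
            b = d.backbone
            buf.write(f"attention:         {b.attention}\n")
            buf.write(f"depth schedule:    {b.depth_schedule()}\n")
            buf.write(f"kernel / lstm:     (1,{b.kernel}) / {b.lstm_hidden}\n")
        else:
            t = d.transformer
            buf.write(f"attention:         {t.attention_kind}\n")
            buf.write(f"crops/resize/patch:{t.crop_len}/{t.resize_len}/{t.patch_size}\n")
        buf.write(f"parameters:        {n_params}\n")
        buf.write(f"training trials:   {d.epochs.n_trials}\n")
        buf.write(f"seed:              {self.seed}\n")
        h = self.history
        buf.write(f"epochs run:        {h.stopped_epoch + 1} (best {h.best_epoch})\n")
        buf.write(f"best val accuracy: {max(h.val_accuracy):.3f}\n")
        if self.val_epochs is not None:
            rep = self.score(self.val_epochs)
            buf.write(f"val F1 / sens:     {rep.f1:.3f} / {rep.sensitivity:.3f}\n")
            buf.write(f"val class sep (J): {rep.class_separation:.3f}\n")
        return buf.getvalue()


# -------------------------------------------------------------------- LOSO

def run_loso(epoch_sets: list[EpochSet], arch: str = "cnn_lstm",
             backbone: BackboneConfig | None = None,
             transformer: TransformerConfig | None = None,
             train: TrainConfig | None = None,
             val_fraction: float = 0.15, seed: int = 0):
    """Leave-one-subject-out evaluation.

    Each fold trains on all other subjects (with a stratified validation
    fraction of their trials) and tests on the held-out subject.  Returns a
    MetricsReport (metric means, per-subject table) plus the pooled test
    predictions for significance testing.
    """
    by_subject = {e.subject_id: e for e in epoch_sets}
    folds = loso_folds(by_subject.keys())
    rows, y_true_all, y_pred_all = [], [], []
    for k, fold in enumerate(folds):
        train_ep = concat_epochs([by_subject[s] for s in fold.train_subjects])
        test_ep = by_subject[fold.test_subject]
        # leakage guard: the held-out subject's trials must not be trainable
        assert fold.test_subject not in fold.train_subjects
        dec = EEGDecoder(train_ep, arch=arch, backbone=backbone,
                         transformer=transformer, train=train)
        res = dec.fit(val_fraction=val_fraction, seed=seed + k)
        rep = res.score(test_ep)
        pred = res.predict(test_ep)
        y_true_all.append(test_ep.labels)
        y_pred_all.append(pred)
        rows.append({"subject": fold.test_subject, "accuracy": rep.accuracy,
                     "f1": rep.f1, "sensitivity": rep.sensitivity,
                     "class_separation": rep.class_separation,
                     "n_test": test_ep.n_trials})
    table = pd.DataFrame(rows)
    report = MetricsReport(accuracy=float(table["accuracy"].mean()),
                           f1=float(table["f1"].mean()),
                           sensitivity=float(table["sensitivity"].mean()),
                           class_separation=float(table["class_separation"].mean()),
                           per_subject=table, seed=seed)
    return report, np.concatenate(y_true_all), np.concatenate(y_pred_all)


# ----------------------------------------------------------------- ablation

ABLATION_VARIANTS = ("CNN + LSTM", "+ Multi-head attention",
                     "+ Transformer", "+ SVM-enhanced attention")


def run_ablation(epochs: EpochSet, seeds: list[int],
                 backbone: BackboneConfig | None = None,
                 transformer: TransformerConfig | None = None,
                 train: TrainConfig | None = None,
                 split: tuple[float, float, float] = (0.70, 0.15, 0.15)
                 ) -> pd.DataFrame:
    """Four-variant ablation under identical budgets and splits.

    Variants: plain CNN+LSTM; CNN+LSTM with multi-head attention pooling; the
    transformer encoder; CNN+LSTM with margin-optimized (SVM-enhanced)
    attention.  Each seed redraws the stratified 70/15/15 split and the
    initialization; the table reports mean F1, Fisher class separation and
    sensitivity over seeds, one row per variant.
    """
    backbone = backbone or BackboneConfig(in_channels=epochs.n_channels)
    transformer = transformer or TransformerConfig()
    acc = {v: {"f1": [], "class_separation": [], "sensitivity": []}
           for v in ABLATION_VARIANTS}
    for seed in seeds:
        rng = np.random.default_rng(seed)
        rest, te_idx = stratified_split(epochs.labels, split[2], rng)
        va_frac = split[1] / (split[0] + split[1])
        sub = epochs.labels[rest]
        tr_rel, va_rel = stratified_split(sub, va_frac, rng)
        tr_idx, va_idx = rest[tr_rel], rest[va_rel]

        def subset(idx):
            return EpochSet(epochs.data[idx], epochs.labels[idx], epochs.fs,
                            channel_names=epochs.channel_names)

        tr, va, te = subset(tr_idx), subset(va_idx), subset(te_idx)
        variants = {
            "CNN + LSTM": dict(arch="cnn_lstm",
                               backbone=replace(backbone, attention="none")),
            "+ Multi-head attention": dict(
                arch="cnn_lstm",
                backbone=replace(backbone, attention="multi_head", n_heads=2)),
            "+ Transformer": dict(arch="transformer"),
            "+ SVM-enhanced attention": dict(
                arch="cnn_lstm",
                backbone=replace(backbone, attention="svm_margin")),
        }
        for name, kw in variants.items():
            dec = EEGDecoder(tr, transformer=transformer, train=train, **kw)
            res = dec.fit(val_epochs=va, seed=seed)
            rep = res.score(te)
            acc[name]["f1"].append(rep.f1)
            acc[name]["class_separation"].append(rep.class_separation)
            acc[name]["sensitivity"].append(rep.sensitivity)
    rows = [{"variant": v,
             "f1": float(np.mean(acc[v]["f1"])),
             "class_separation": float(np.mean(acc[v]["class_separation"])),
             "sensitivity": float(np.mean(acc[v]["sensitivity"]))}
            for v in ABLATION_VARIANTS]
    return pd.DataFrame(rows).set_index("variant")
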