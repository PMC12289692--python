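"""Cropping, patch encoding, encoder blocks and early stopping."""

import numpy as np
import pytest

from margineeg import EpochSet, TransformerConfig, crop_series, nn, resize_crops
from margineeg.training import TrainConfig, train_with_early_stopping
from margineeg.transformer import PatchEncoder, TransformerBlock, build_transformer


def make_epochs(n_trials=4, n_channels=3, n_samples=1000, fs=250.0, rng=None):
    rng = rng or np.random.default_rng(0)
    labels = np.where(np.arange(n_trials) % 2 == 0, 1, -1)
    return EpochSet(data=rng.normal(size=(n_trials, n_channels, n_samples)),
                    labels=labels, fs=fs)


class TestCrops:
    def test_1000_samples_give_22_crops_per_trial(self):
        ep = make_epochs(n_trials=3, n_samples=1000)
        crops = crop_series(ep, 45)
        assert crops.n_crops == 3 * 22  # floor(1000/45), 10 samples dropped
        assert crops.data.shape[-1] == 45

    def test_crop_equal_to_epoch_is_identity(self):
        ep = make_epochs(n_trials=2, n_samples=90)
        crops = crop_series(ep, 90)
        assert crops.n_crops == 2
        np.testing.assert_array_equal(crops.data, ep.data)

    def test_labels_propagate_to_all_crops(self):
        ep = make_epochs(n_trials=4, n_samples=200)
        crops = crop_series(ep, 45)
        for t in range(4):
            assert np.all(crops.labels[crops.trial_index == t] == ep.labels[t])

    def test_crop_longer_than_epoch_rejected(self):
        with pytest.raises(ValueError):
            crop_series(make_epochs(n_samples=40), 45)

    def test_sample_conservation(self):
        ep = make_epochs(n_trials=5, n_samples=997)
        crops = crop_series(ep, 45)
        assert crops.n_crops * 45 <= 5 * 997

    def test_resize_preserves_endpoints_and_linearity(self):
        x = np.linspace(0.0, 1.0, 45)[None, None, :]
        y = resize_crops(x, 72)
        # linear ramp stays a linear ramp under linear interpolation
        np.testing.assert_allclose(y[0, 0], np.linspace(0.0, 1.0, 72), atol=1e-12)


class TestEncoder:
    def test_token_count(self, rng):
        cfg = TransformerConfig(patch_size=8, resize_len=72)
        enc = PatchEncoder(n_channels=3, cfg=cfg, rng=rng)
        tokens = enc(np.zeros((2, 3, 72)))
        assert tokens.shape == (2, 9, cfg.projection_dim)
        assert cfg.n_tokens * cfg.patch_size == cfg.resize_len

    def test_zero_crop_tokens_equal_positional_embeddings(self, rng):
        cfg = TransformerConfig()
        enc = PatchEncoder(n_channels=2, cfg=cfg, rng=rng)
        tokens = enc(np.zeros((1, 2, 72)))
        np.testing.assert_allclose(tokens.data[0], enc.pos.data, atol=1e-12)

    def test_indivisible_patch_size_rejected(self):
        with pytest.raises(ValueError):
            TransformerConfig(resize_len=72, patch_size=7)

    @pytest.mark.parametrize("kind", ["multi_head", "svm_margin"])
    def test_zeroed_residual_block_is_identity(self, kind, rng):
        cfg = TransformerConfig(attention_kind=kind)
        blk = TransformerBlock(cfg, rng, zero_residual=True)
        x = nn.Tensor(rng.normal(size=(2, 9, cfg.projection_dim)))
        out, _ = blk(x)
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_block_preserves_shape_and_aux_flows(self, rng):
        cfg = TransformerConfig(attention_kind="svm_margin")
        blk = TransformerBlock(cfg, rng)
        x = nn.Tensor(rng.normal(size=(4, 9, cfg.projection_dim)))
        out, aux = blk(x, labels=np.array([1, -1, 1, -1]))
        assert out.shape == x.shape
        assert float(aux.data) > 0.0
        out2, aux2 = blk(x)  # inference: no labels -> aux 0
        assert float(aux2.data) == 0.0

    def test_margin_training_reduces_hinge_aux(self):
        """On synthetic crops the auxiliary hinge loss trends downward."""
        rng = np.random.default_rng(4)
        n = 120
        y = np.where(np.arange(n) % 2 == 0, 1, -1)
        x = rng.normal(size=(n, 2, 45)) + (0.8 * y)[:, None, None]
        cfg = TransformerConfig(attention_kind="svm_margin", n_blocks=1)
        model = build_transformer(2, cfg, seed=0)
        opt = nn.AdamW(model.parameters(), lr=3e-3)
        cls = ((y + 1) // 2).astype(int)
        aux_per_epoch = []
        for _ in range(12):
            logits, aux, _ = model.forward(x, labels=y)
            loss = nn.cross_entropy(logits, cls) + 0.5 * aux
            opt.zero_grad()
            loss.backward()
            opt.step()
            aux_per_epoch.append(float(aux.data))
        assert aux_per_epoch[-1] < aux_per_epoch[0]


class _ScriptedModel:
    """Minimal model stub whose validation accuracy follows a script."""

    def __init__(self, script):
        self.script = list(script)
        self.calls = 0
        self.p = nn.Tensor(np.zeros(1), requires_grad=True)

    def parameters(self):
        return [self.p]

    def state_arrays(self):
        return {"p0": self.p.data.copy(), "call": np.array([self.calls])}

    def load_state_arrays(self, s):
        self.restored_call = int(s["call"][0])

    def train(self):
        pass

    def eval(self):
        pass

    def forward(self, x, labels=None):
        logits = nn.Tensor(np.zeros((len(x), 2)), requires_grad=False) + self.p
        return logits * nn.Tensor(np.ones(1)), nn.Tensor(0.0), None

    def predict_logits(self, x):
        acc = self.script[min(self.calls, len(self.script) - 1)]
        self.calls += 1
        n = len(x)
        n_right = int(round(acc * n))
        logits = np.zeros((n, 2))
        logits[:n_right, 1] = 1.0   # correct for +1 labels
        logits[n_right:, 0] = 1.0
        return logits


class TestEarlyStopping:
    def _run(self, script, patience, epochs=10):
        model = _ScriptedModel(script)
        x = np.zeros((20, 1, 8))
        y = np.ones(20, dtype=int)  # all +1: accuracy = fraction predicted +1
        hist = train_with_early_stopping(
            model, x, y, x, y,
            TrainConfig(epochs=epochs, patience=patience, batch_size=4, lr=0.0))
        return hist

    def test_patience_zero_stops_at_first_plateau(self):
        hist = self._run([0.5, 0.5, 1.0], patience=0)
        assert hist.stopped_epoch == 1  # epoch 1 did not improve on epoch 0
        assert hist.best_epoch == 0

    def test_strict_improvement_runs_full_budget(self):
        hist = self._run([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
                         patience=0, epochs=10)
        assert hist.stopped_epoch == 9
        assert hist.best_epoch == 9

    def test_best_checkpoint_restored(self):
        model = _ScriptedModel([0.5, 1.0, 0.25, 0.25, 0.25])
        x = np.zeros((4, 1, 8))
        y = np.ones(4, dtype=int)
        train_with_early_stopping(
            model, x, y, x, y,
            TrainConfig(epochs=5, patience=1, batch_size=4, lr=0.0))
        # snapshot taken right after the acc-1.0 validation (second call)
        assert model.restored_call == 2

    def test_empty_validation_rejected(self):
        model = _ScriptedModel([1.0])
        with pytest.raises(ValueError):
            train_with_early_stopping(model, np.zeros((2, 1, 4)), np.ones(2),
                                      np.zeros((0, 1, 4)), np.ones(0),
                                      TrainConfig(epochs=1))

    def test_seeded_run_is_deterministic(self, small_epochs):
        from margineeg import EEGDecoder, BackboneConfig
        ep = small_epochs[0]
        kw = dict(
            backbone=BackboneConfig(in_channels=ep.n_channels, n_layers=2,
                                    lstm_hidden=8, input_time=64,
                                    head_hidden=8, attention="svm_margin"),
            train=TrainConfig(epochs=3, batch_size=32, patience=3))
        h1 = EEGDecoder(ep, **kw).fit(seed=5).history
        h2 = EEGDecoder(ep, **kw).fit(seed=5).history
        assert h1.train_loss == h2.train_loss
        assert h1.val_accuracy == h2.val_accuracy
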