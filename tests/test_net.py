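"""Network architecture, gradients, constraints and the training loop."""

import numpy as np
import pytest
from scipy.signal import correlate

from mdeeg.containers import DomainTensor
from mdeeg.crops import CropSet
from mdeeg.net import (
    MDCNN,
    ModelConfig,
    TrainConfig,
    conv_feature_shape,
    pooled_length,
    predict,
    train,
)
from mdeeg.net import ops
from mdeeg.net.model import load_model, save_model
from mdeeg.net.optim import Adam


def tiny_config(**overrides):
    defaults = dict(
        n_channels=4, n_samples=100, n_classes=2, temporal_filters=6,
        temporal_kernel=11, spatial_filters=6, pool_kernel=20, pool_stride=10,
        feature_dim=8, dropout=0.5, seed=0,
    )
    defaults.update(overrides)
    return ModelConfig(**defaults)


def bandpower_crops(rng, n_per_class=60, n_channels=4, n_samples=100, fs=100.0):
    """Two classes distinguished by which channel carries a strong 10 Hz tone.

    A linear classifier on per-channel variance separates this perfectly, so
    the network is expected to as well.
    """
    t = np.arange(n_samples) / fs
    data, labels = [], []
    for cls in (0, 1):
        for _ in range(n_per_class):
            x = 0.3 * rng.standard_normal((n_channels, n_samples))
            phase = rng.uniform(0, 2 * np.pi)
            x[cls] += 2.0 * np.sin(2 * np.pi * 10.0 * t + phase)
            data.append(x)
            labels.append(cls)
    order = rng.permutation(len(labels))
    data = np.stack(data)[order]
    labels = np.asarray(labels)[order]
    domains = {tag: data.copy() for tag in ("time", "spatial", "phase")}
    return CropSet(domains=domains, labels=labels,
                   trial_index=np.arange(labels.size), window_seconds=1.0,
                   step_seconds=1.0, fs=fs)


class TestArchitecture:
    def test_feature_map_shape_for_standard_input(self):
        cfg = ModelConfig(n_channels=31, n_samples=1000, n_classes=3)
        assert conv_feature_shape(cfg) == (40, 1, 976)

    def test_pooled_length_for_standard_input(self):
        cfg = ModelConfig(n_channels=31, n_samples=1000, n_classes=3)
        assert pooled_length(cfg) == (976 - 75) // 15 + 1 == 61

    def test_concatenated_feature_width(self):
        cfg = tiny_config()
        model = MDCNN(cfg)
        assert model.params["multi.head_w"].shape[1] == 3 * cfg.feature_dim

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(temporal_kernel=200)
        with pytest.raises(ValueError):
            tiny_config(pool_kernel=95)  # longer than the 90-sample conv map
        with pytest.raises(ValueError):
            tiny_config(loss_weights=(0.0, 0.0, 0.0, 0.0))

    def test_composed_conv_equals_two_stage_reference(self, rng):
        x = rng.standard_normal((2, 3, 40))
        kt = rng.standard_normal((4, 7))
        ws = rng.standard_normal((5, 4, 3))
        y, _ = ops.composed_conv(x, kt, ws)
        ref = np.zeros_like(y)
        for b in range(2):
            for o in range(5):
                ref[b, o] = sum(
                    ws[o, m, c] * correlate(x[b, c], kt[m], mode="valid")
                    for m in range(4) for c in range(3)
                )
        np.testing.assert_allclose(y, ref, atol=1e-10)

    def test_branch_permutation_symmetry(self, rng):
        # rotating the three input domains together with the branch weights
        # (and the fused head's blocks) leaves the multi output unchanged
        cfg = tiny_config(dtype="float64")
        model = MDCNN(cfg)
        inputs = {br: rng.standard_normal((5, 4, 100)) for br in cfg.branches}
        ref_logits, _ = model.forward(inputs, train=False)

        rot = dict(zip(cfg.branches, cfg.branches[1:] + cfg.branches[:1]))
        permuted = MDCNN(cfg)
        d = cfg.feature_dim
        pos = {br: i for i, br in enumerate(cfg.branches)}
        for src, dst in rot.items():
            for suffix in ("k_temporal", "w_spatial", "bn_gamma", "bn_beta",
                           "fc_w", "fc_b", "head_w", "head_b"):
                permuted.params[f"{dst}.{suffix}"] = model.params[f"{src}.{suffix}"].copy()
            permuted.running[dst] = {k: v.copy() for k, v in model.running[src].items()}
            permuted.params["multi.head_w"][:, pos[dst] * d : (pos[dst] + 1) * d] = \
                model.params["multi.head_w"][:, pos[src] * d : (pos[src] + 1) * d]
        permuted.params["multi.head_b"] = model.params["multi.head_b"].copy()
        rotated_inputs = {rot[src]: inputs[src] for src in cfg.branches}
        out_logits, _ = permuted.forward(rotated_inputs, train=False)
        np.testing.assert_allclose(out_logits["multi"], ref_logits["multi"], atol=1e-12)


class TestGradients:
    def test_full_model_gradient_check(self, rng):
        cfg = tiny_config(dropout=0.0, n_classes=3, dtype="float64")
        model = MDCNN(cfg)
        inputs = {br: rng.standard_normal((4, 4, 100)) for br in cfg.branches}
        labels = np.array([0, 1, 2, 1])
        _, _, grads = model.loss_and_grads(inputs, labels, train=True)
        eps = 1e-6
        for name, p in model.params.items():
            for _ in range(2):
                idx = tuple(rng.integers(0, s) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                l1, _, _ = model.loss_and_grads(inputs, labels, train=True)
                p[idx] = old - eps
                l0, _, _ = model.loss_and_grads(inputs, labels, train=True)
                p[idx] = old
                numeric = (l1 - l0) / (2 * eps)
                assert grads[name][idx] == pytest.approx(numeric, rel=1e-4, abs=1e-7), name

    def test_zero_weight_branch_heads_get_no_gradient(self, rng):
        cfg = tiny_config(dropout=0.0, loss_weights=(0.0, 0.0, 0.0, 1.0),
                          dtype="float64")
        model = MDCNN(cfg)
        inputs = {br: rng.standard_normal((4, 4, 100)) for br in cfg.branches}
        _, _, grads = model.loss_and_grads(inputs, np.array([0, 1, 0, 1]), train=True)
        for br in cfg.branches:
            np.testing.assert_array_equal(grads[f"{br}.head_w"], 0.0)
        assert np.abs(grads["multi.head_w"]).max() > 0


class TestForwardContracts:
    def test_probabilities_sum_to_one(self, rng):
        model = MDCNN(tiny_config())
        inputs = {br: rng.standard_normal((7, 4, 100)) for br in ("time", "spatial", "phase")}
        probs = model.predict_proba(inputs)
        for head, p in probs.items():
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_output_layers_give_uniform_probs(self, rng):
        cfg = tiny_config(n_classes=4)
        model = MDCNN(cfg)
        for name in list(model.params):
            if "head" in name:
                model.params[name][:] = 0.0
        inputs = {br: rng.standard_normal((5, 4, 100)) for br in cfg.branches}
        probs = model.predict_proba(inputs)
        for p in probs.values():
            np.testing.assert_allclose(p, 0.25, atol=1e-7)

    def test_square_log_stack_survives_flat_crops(self):
        cfg = tiny_config(dropout=0.0)
        model = MDCNN(cfg)
        inputs = {br: np.zeros((3, 4, 100)) for br in cfg.branches}
        probs = model.predict_proba(inputs)
        for p in probs.values():
            assert np.isfinite(p).all()

    def test_shape_mismatch_rejected(self, rng):
        model = MDCNN(tiny_config())
        bad = {br: rng.standard_normal((2, 4, 64)) for br in ("time", "spatial", "phase")}
        with pytest.raises(ValueError, match="input shape"):
            model.forward(bad)

    def test_single_branch_reduction(self, rng):
        # one branch + fused head over its features: a standalone
        # single-domain convolutional classifier
        cfg = tiny_config(branches=("time",))
        model = MDCNN(cfg)
        probs = model.predict_proba({"time": rng.standard_normal((6, 4, 100))})
        assert set(probs) == {"time", "multi"}
        assert probs["time"].shape == (6, 2)


class TestTraining:
    def test_separable_crops_reach_high_accuracy(self, rng):
        from sklearn.linear_model import LogisticRegression

        crops = bandpower_crops(rng)
        # independent separability oracle: variance features are enough
        feats = crops.domains["time"].var(axis=2)
        oracle = LogisticRegression().fit(feats, crops.labels)
        assert oracle.score(feats, crops.labels) == 1.0

        cfg = tiny_config(seed=1)
        model = MDCNN(cfg)
        tcfg = TrainConfig(epochs=30, batch_size=16, seed=1)
        train(model, crops, crops, tcfg)
        preds = predict(model, crops)
        acc = (preds.probs["multi"].argmax(axis=1) == crops.labels).mean()
        assert acc >= 0.95

    def test_maxnorm_constraint_holds_after_steps(self, rng):
        cfg = tiny_config()
        model = MDCNN(cfg)
        opt = Adam(model.params.keys(), lr=0.05)  # large steps to stress the bound
        inputs = {br: rng.standard_normal((8, 4, 100)) for br in cfg.branches}
        labels = rng.integers(0, 2, 8)
        for _ in range(5):
            _, _, grads = model.loss_and_grads(inputs, labels, rng=rng)
            opt.step(model.params, grads)
            model.constrain()
        for name, w in model.params.items():
            if name.endswith(("_b", "bn_gamma", "bn_beta")):
                continue
            radius = cfg.maxnorm_conv if "k_temporal" in name or "w_spatial" in name \
                else cfg.maxnorm_fc
            norms = np.linalg.norm(w.reshape(w.shape[0], -1), axis=1)
            assert (norms <= radius + 1e-5).all(), name

    def test_training_is_deterministic_under_seed(self, rng):
        crops = bandpower_crops(rng, n_per_class=20)
        results = []
        for _ in range(2):
            model = MDCNN(tiny_config(seed=3))
            train(model, crops, crops, TrainConfig(epochs=3, batch_size=16, seed=3))
            results.append({k: v.copy() for k, v in model.params.items()})
        for k in results[0]:
            np.testing.assert_array_equal(results[0][k], results[1][k])

    def test_checkpoint_restores_best_monitored_weights(self, rng):
        crops = bandpower_crops(rng, n_per_class=20)
        model = MDCNN(tiny_config(seed=2))
        history = train(model, crops, crops, TrainConfig(epochs=5, batch_size=16, seed=2))
        monitored = [r["monitored_loss"] for r in history.records]
        assert history.best_monitored == min(monitored)
        assert model.eval_loss(
            {k: v for k, v in crops.domains.items()}, crops.labels
        ) == pytest.approx(history.best_monitored, rel=1e-6)

    def test_predictions_preserve_trial_map(self, rng):
        crops = bandpower_crops(rng, n_per_class=10)
        model = MDCNN(tiny_config())
        preds = predict(model, crops)
        np.testing.assert_array_equal(preds.trial_index, crops.trial_index)
        assert set(preds.heads) == {"time", "spatial", "phase", "multi"}

    def test_model_checkpoint_roundtrip(self, tmp_path, rng):
        model = MDCNN(tiny_config(seed=5))
        inputs = {br: rng.standard_normal((3, 4, 100)) for br in ("time", "spatial", "phase")}
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        ref = model.predict_proba(inputs)
        out = back.predict_proba(inputs)
        for head in ref:
            np.testing.assert_array_equal(ref[head], out[head])
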