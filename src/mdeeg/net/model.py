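"""The multi-domain convolutional network.

Three parallel branches — one per input domain (time, CSP-spatial,
Hilbert-phase) — share a ShallowConvNet-style backbone: temporal
convolution (40 kernels of 1×25), spatial convolution across all channels
(40 kernels of N×1, mixing the temporal maps), batch normalization, a
square activation, average pooling (1×75 kernel, 1×15 stride), a log
activation, dropout (0.5) and a fully connected projection to D features.
Each branch carries its own softmax classification head; the three feature
vectors are also concatenated and passed through a final fused softmax
head ("multi").  All four heads are trained jointly with weighted
cross-entropy; a maxnorm constraint caps the norm of every convolutional
and fully connected weight vector after each optimizer step.

Disabling two branches and the fused head reduces the model to a
standalone single-domain ShallowConvNet classifier.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import ops

BRANCHES = ("time", "spatial", "phase")
HEADS = BRANCHES + ("multi",)


@dataclass
class ModelConfig:
    n_channels: int
    n_samples: int
    n_classes: int
    temporal_filters: int = 40
    temporal_kernel: int = 25
    spatial_filters: int = 40
    pool_kernel: int = 75
    pool_stride: int = 15
    dropout: float = 0.5
    feature_dim: int = 40          # D, width of each branch's FC projection
    maxnorm_conv: float = 2.0
    maxnorm_fc: float = 0.5
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    branches: tuple[str, ...] = BRANCHES
    dtype: str = "float32"   # compute precision; float64 for gradient checking
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temporal_kernel > self.n_samples:
            raise ValueError("temporal kernel longer than the input window")
        if self.pool_kernel > self.conv_length:
            raise ValueError("pool kernel longer than the post-convolution map")
        lw = np.asarray(self.loss_weights, dtype=float)
        if lw.shape != (4,) or (lw < 0).any() or not lw.any():
            raise ValueError("loss_weights must be 4 non-negative values, not all zero")
        if not set(self.branches) <= set(BRANCHES):
            raise ValueError(f"branches must be drawn from {BRANCHES}")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")

    @property
    def conv_length(self) -> int:
        return self.n_samples - self.temporal_kernel + 1

    @property
    def pooled(self) -> int:
        return (self.conv_length - self.pool_kernel) // self.pool_stride + 1


def conv_feature_shape(cfg: ModelConfig) -> tuple[int, int, int]:
    """Feature-map shape after the two convolution layers: (F, 1, T-K+1)."""
    return (cfg.spatial_filters, 1, cfg.conv_length)


def pooled_length(cfg: ModelConfig) -> int:
    """Temporal length after average pooling."""
    return cfg.pooled


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class MDCNN:
    """Parameter container + forward/backward for the multi-domain network.

    Parameters live in ``self.params`` (name → array in ``cfg.dtype``); batch-norm
    running statistics in ``self.running``.  ``loss_and_grads`` computes the
    joint 4-head loss and its full gradient; ``predict_proba`` runs the
    network in evaluation mode.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, np.ndarray] = {}
        f1, f2 = cfg.temporal_filters, cfg.spatial_filters
        c, k, d, m = cfg.n_channels, cfg.temporal_kernel, cfg.feature_dim, cfg.n_classes
        flat = f2 * cfg.pooled
        self.running: dict[str, dict[str, np.ndarray]] = {}
        for br in cfg.branches:
            dt = self.dtype
            p[f"{br}.k_temporal"] = _glorot(rng, (f1, k), k, f1 * k, dt)
            p[f"{br}.w_spatial"] = _glorot(rng, (f2, f1, c), f1 * c, f2, dt)
            p[f"{br}.bn_gamma"] = np.ones(f2, dt)
            p[f"{br}.bn_beta"] = np.zeros(f2, dt)
            p[f"{br}.fc_w"] = _glorot(rng, (d, flat), flat, d, dt)
            p[f"{br}.fc_b"] = np.zeros(d, dt)
            p[f"{br}.head_w"] = _glorot(rng, (m, d), d, m, dt)
            p[f"{br}.head_b"] = np.zeros(m, dt)
            self.running[br] = {"mean": np.zeros(f2, dt), "var": np.ones(f2, dt)}
        p["multi.head_w"] = _glorot(rng, (m, d * len(cfg.branches)), d * len(cfg.branches), m, dt)
        p["multi.head_b"] = np.zeros(m, dt)
        self.params = p

    # -- forward -----------------------------------------------------------

    def _branch_forward(self, br: str, x: np.ndarray, train: bool,
                        rng: np.random.Generator | None):
        cfg, p = self.cfg, self.params
        h, c_conv = ops.composed_conv(x, p[f"{br}.k_temporal"], p[f"{br}.w_spatial"])
        h, c_bn = ops.batchnorm(h, p[f"{br}.bn_gamma"], p[f"{br}.bn_beta"],
                                self.running[br], train)
        h, c_sq = ops.square(h)
        h, c_pool = ops.avgpool1d(h, cfg.pool_kernel, cfg.pool_stride)
        h, c_log = ops.log_act(h)
        h, c_drop = ops.dropout(h, cfg.dropout, train, rng)
        flat = h.reshape(h.shape[0], -1)
        feats, c_fc = ops.linear(flat, p[f"{br}.fc_w"], p[f"{br}.fc_b"])
        logits, c_head = ops.linear(feats, p[f"{br}.head_w"], p[f"{br}.head_b"])
        cache = (c_conv, c_bn, c_sq, c_pool, c_log, c_drop, h.shape, c_fc, c_head)
        return feats, logits, cache

    def forward(self, inputs: dict[str, np.ndarray], train: bool = False,
                rng: np.random.Generator | None = None):
        """Return per-head logits and the backward cache.

        ``inputs`` maps each active branch name to a (B, C, T) array.
        """
        cfg = self.cfg
        if train and rng is None:
            rng = np.random.default_rng(cfg.seed)
        feats, logits, caches = {}, {}, {}
        for br in cfg.branches:
            x = np.ascontiguousarray(inputs[br], dtype=self.dtype)
            if x.shape[1:] != (cfg.n_channels, cfg.n_samples):
                raise ValueError(
                    f"branch {br!r} input shape {x.shape[1:]} does not match "
                    f"({cfg.n_channels}, {cfg.n_samples})"
                )
            feats[br], logits[br], caches[br] = self._branch_forward(br, x, train, rng)
        concat = np.concatenate([feats[br] for br in cfg.branches], axis=1)
        logits["multi"], c_multi = ops.linear(
            concat, self.params["multi.head_w"], self.params["multi.head_b"]
        )
        return logits, (caches, c_multi)

    # -- backward ----------------------------------------------------------

    def _branch_backward(self, br: str, g_feats: np.ndarray, g_logits: np.ndarray,
                         cache, grads: dict[str, np.ndarray]) -> None:
        c_conv, c_bn, c_sq, c_pool, c_log, c_drop, pre_flat_shape, c_fc, c_head = cache
        g_feats = g_feats.copy()
        gf, grads[f"{br}.head_w"], grads[f"{br}.head_b"] = ops.linear_backward(g_logits, c_head)
        g_feats += gf
        g, grads[f"{br}.fc_w"], grads[f"{br}.fc_b"] = ops.linear_backward(g_feats, c_fc)
        g = g.reshape(pre_flat_shape)
        g = ops.dropout_backward(g, c_drop)
        g = ops.log_act_backward(g, c_log)
        g = ops.avgpool1d_backward(g, c_pool)
        g = ops.square_backward(g, c_sq)
        g, grads[f"{br}.bn_gamma"], grads[f"{br}.bn_beta"] = ops.batchnorm_backward(g, c_bn)
        _, grads[f"{br}.k_temporal"], grads[f"{br}.w_spatial"] = ops.composed_conv_backward(g, c_conv)

    def loss_and_grads(self, inputs: dict[str, np.ndarray], labels: np.ndarray,
                       rng: np.random.Generator | None = None, train: bool = True):
        """Joint weighted 4-head cross-entropy, per-head losses and gradients."""
        cfg = self.cfg
        logits, (caches, c_multi) = self.forward(inputs, train=train, rng=rng)
        lw = dict(zip(HEADS, cfg.loss_weights))
        head_losses, g_logits = {}, {}
        total = 0.0
        for head in cfg.branches + ("multi",):
            loss, grad, _ = ops.softmax_xent(logits[head], labels)
            head_losses[head] = loss
            g_logits[head] = grad * lw[head]
            total += lw[head] * loss
        grads = {k: None for k in self.params}
        g_concat, grads["multi.head_w"], grads["multi.head_b"] = ops.linear_backward(
            g_logits["multi"], c_multi
        )
        d = cfg.feature_dim
        for i, br in enumerate(cfg.branches):
            self._branch_backward(br, g_concat[:, i * d : (i + 1) * d],
                                  g_logits[br], caches[br], grads)
        return total, head_losses, grads

    # -- inference / utilities ---------------------------------------------

    def predict_proba(self, inputs: dict[str, np.ndarray], batch_size: int = 256):
        """Per-head softmax probabilities in evaluation mode."""
        n = next(iter(inputs.values())).shape[0]
        out: dict[str, list[np.ndarray]] = {h: [] for h in self.cfg.branches + ("multi",)}
        for lo in range(0, n, batch_size):
            batch = {k: v[lo : lo + batch_size] for k, v in inputs.items()}
            logits, _ = self.forward(batch, train=False)
            for h, lg in logits.items():
                out[h].append(ops.softmax(lg))
        return {h: np.concatenate(v) for h, v in out.items()}

    def eval_loss(self, inputs, labels, batch_size: int = 256) -> float:
        """Weighted 4-head loss in evaluation mode (no dropout, running BN)."""
        n = labels.shape[0]
        lw = dict(zip(HEADS, self.cfg.loss_weights))
        total, seen = 0.0, 0
        for lo in range(0, n, batch_size):
            batch = {k: v[lo : lo + batch_size] for k, v in inputs.items()}
            yb = labels[lo : lo + batch_size]
            logits, _ = self.forward(batch, train=False)
            bl = sum(lw[h] * ops.softmax_xent(logits[h], yb)[0] for h in logits)
            total += bl * yb.size
            seen += yb.size
        return total / seen

    def constrain(self) -> None:
        """Project weight vectors onto their maxnorm balls (in place)."""
        cfg = self.cfg
        for name, w in self.params.items():
            if name.endswith((".bn_gamma", ".bn_beta", "_b")):
                continue
            if name.endswith(".k_temporal"):
                radius, vecs = cfg.maxnorm_conv, w.reshape(w.shape[0], -1)
            elif name.endswith(".w_spatial"):
                radius, vecs = cfg.maxnorm_conv, w.reshape(w.shape[0], -1)
            else:  # fully connected rows
                radius, vecs = cfg.maxnorm_fc, w.reshape(w.shape[0], -1)
            norms = np.linalg.norm(vecs, axis=1, keepdims=True)
            np.multiply(vecs, np.minimum(1.0, radius / np.maximum(norms, 1e-12)),
                        out=vecs)

    def copy_state(self):
        return (copy.deepcopy(self.params), copy.deepcopy(self.running))

    def load_state(self, state) -> None:
        params, running = state
        self.params = copy.deepcopy(params)
        self.running = copy.deepcopy(running)


def save_model(model: MDCNN, path) -> None:
    """Checkpoint weights + running stats with the embedded ModelConfig."""
    import dataclasses
    import json

    arrays = {f"param/{k}": v for k, v in model.params.items()}
    for br, run in model.running.items():
        arrays[f"running/{br}/mean"] = run["mean"]
        arrays[f"running/{br}/var"] = run["var"]
    cfg = dataclasses.asdict(model.cfg)
    arrays["config"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_model(path) -> MDCNN:
    import json

    with np.load(path) as npz:
        cfg_dict = json.loads(bytes(npz["config"]))
        for key in ("loss_weights", "branches"):
            cfg_dict[key] = tuple(cfg_dict[key])
        model = MDCNN(ModelConfig(**cfg_dict))
        for k in model.params:
            model.params[k] = npz[f"param/{k}"].copy()
        for br in model.running:
            model.running[br] = {
                "mean": npz[f"running/{br}/mean"].copy(),
                "var": npz[f"running/{br}/var"].copy(),
            }
    return model
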