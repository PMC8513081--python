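"""Training loop and prediction for the multi-domain network.

Training follows the cropped-training recipe: shuffled mini-batches of
crops, Adam, joint weighted cross-entropy over the four heads, a maxnorm
projection after every step, plateau LR decay, and checkpointing of the
weights at the lowest monitored loss.  The monitored loss is, by default,
the loss on the held-out evaluation crops ("monitor_test_loss", the
protocol the model was originally tuned with); "monitor_val_loss" instead
carves an inner validation split out of the training trials, which is the
leakage-free alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..crops import CropSet
from .model import MDCNN
from .optim import Adam, ReduceLROnPlateau


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    initial_lr: float = 1e-3
    lr_reduce_factor: float = 0.5
    lr_patience: int = 10
    checkpoint_criterion: str = "monitor_test_loss"  # or "monitor_val_loss"
    val_fraction: float = 0.2  # inner split, monitor_val_loss only
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 < self.lr_reduce_factor < 1:
            raise ValueError("lr_reduce_factor must lie in (0, 1)")
        if self.checkpoint_criterion not in ("monitor_test_loss", "monitor_val_loss"):
            raise ValueError(f"unknown checkpoint criterion {self.checkpoint_criterion!r}")


@dataclass
class PredictionSet:
    """Per-crop class probabilities for every head, plus the crop→trial map."""

    probs: dict[str, np.ndarray]  # head -> (n_crops, n_classes)
    trial_index: np.ndarray
    labels: np.ndarray            # per-crop labels

    @property
    def heads(self) -> list[str]:
        return list(self.probs)


@dataclass
class History:
    """Per-epoch training record."""

    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_monitored: float = float("inf")

    def to_rows(self) -> list[dict]:
        return list(self.records)


def _crop_inputs(crops: CropSet, branches) -> dict[str, np.ndarray]:
    missing = [b for b in branches if b not in crops.domains]
    if missing:
        raise ValueError(f"crop set lacks domains {missing}")
    return {b: crops.domains[b] for b in branches}


def _split_by_trial(crops: CropSet, val_fraction: float, rng: np.random.Generator):
    """Inner stratified trial-level split so sibling crops never straddle it."""
    trials = np.unique(crops.trial_index)
    trial_labels = np.array(
        [crops.labels[crops.trial_index == t][0] for t in trials]
    )
    val_trials = []
    for cls in np.unique(trial_labels):
        cls_trials = trials[trial_labels == cls]
        n_val = max(1, int(round(val_fraction * cls_trials.size)))
        val_trials.extend(rng.permutation(cls_trials)[:n_val])
    val_mask = np.isin(crops.trial_index, val_trials)
    return ~val_mask, val_mask


def train(model: MDCNN, train_crops: CropSet, eval_crops: CropSet,
          tcfg: TrainConfig) -> History:
    """Fit the model in place; returns the history, weights at best checkpoint."""
    branches = model.cfg.branches
    rng = np.random.default_rng(tcfg.seed)
    inputs = _crop_inputs(train_crops, branches)
    labels = train_crops.labels

    if tcfg.checkpoint_criterion == "monitor_val_loss":
        fit_mask, mon_mask = _split_by_trial(train_crops, tcfg.val_fraction, rng)
        fit_inputs = {k: v[fit_mask] for k, v in inputs.items()}
        fit_labels = labels[fit_mask]
        mon_inputs = {k: v[mon_mask] for k, v in inputs.items()}
        mon_labels = labels[mon_mask]
    else:
        fit_inputs, fit_labels = inputs, labels
        mon_inputs = _crop_inputs(eval_crops, branches)
        mon_labels = eval_crops.labels

    opt = Adam(model.params.keys(), lr=tcfg.initial_lr)
    sched = ReduceLROnPlateau(opt, tcfg.lr_reduce_factor, tcfg.lr_patience)
    history = History()
    best_state = model.copy_state()
    n = fit_labels.size

    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n, tcfg.batch_size):
            idx = order[lo : lo + tcfg.batch_size]
            batch = {k: v[idx] for k, v in fit_inputs.items()}
            loss, _, grads = model.loss_and_grads(batch, fit_labels[idx], rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}, lr {opt.lr:g}"
                )
            opt.step(model.params, grads)
            model.constrain()
            epoch_loss += loss
            n_batches += 1
        monitored = model.eval_loss(mon_inputs, mon_labels)
        sched.step(monitored)
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": epoch_loss / max(n_batches, 1),
            "monitored_loss": monitored,
        }
        probs = model.predict_proba(mon_inputs)
        for head, p in probs.items():
            record[f"acc_{head}"] = float((p.argmax(axis=1) == mon_labels).mean())
        history.records.append(record)
        if monitored < history.best_monitored:
            history.best_monitored = monitored
            history.best_epoch = epoch
            best_state = model.copy_state()
        if tcfg.verbose:
            print(f"epoch {epoch:3d}  lr {opt.lr:.2e}  train {record['train_loss']:.4f}  "
                  f"monitored {monitored:.4f}  acc_multi {record['acc_multi']:.3f}")

    model.load_state(best_state)
    return history


def predict(model: MDCNN, crops: CropSet) -> PredictionSet:
    """Evaluation-mode per-crop probabilities for all four heads."""
    probs = model.predict_proba(_crop_inputs(crops, model.cfg.branches))
    return PredictionSet(probs=probs, trial_index=crops.trial_index.copy(),
                         labels=crops.labels.copy())
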