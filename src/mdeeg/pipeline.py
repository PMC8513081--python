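"""End-to-end driver: preprocessing → domains → crops → network → CV report.

Per cross-validation fold, the CSP projection and the per-domain
normalization statistics are fitted on the training trials only and frozen
before they touch the test trials, so no test information leaks into the
input representations.  Domain transforms are applied to the full trial
first and cropped afterwards, so all crops of a trial share one spatial
projection and one analytic signal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import __version__
from .containers import DomainTensor, EpochSet
from .crops import CropSet, make_crops
from .csp import CspModel, apply_csp, fit_csp
from .evaluate import CvReport, chance_limit, stratified_folds, trial_accuracy
from .net import MDCNN, ModelConfig, TrainConfig, predict, train
from .phase import phase_domain
from .preprocess import FilterSpec, NormStats, apply_filter, normalize, resample


@dataclass
class PipelineConfig:
    """Everything needed to run the full decoding pipeline reproducibly."""

    filters: list[FilterSpec] = field(
        default_factory=lambda: [FilterSpec("bandpass", (4.0, 40.0), order=4)]
    )
    target_fs: float | None = 250.0
    csp_L: int | None = None          # None: keep all filters (no reduction)
    csp_log_sqrt: bool = False
    csp_ridge: float = 0.0
    window_seconds: float = 4.0
    step_seconds: float = 0.1
    model: dict = field(default_factory=dict)   # ModelConfig overrides
    train: TrainConfig = field(default_factory=TrainConfig)
    cv_k: int = 10
    seed: int = 0
    normalize: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filters"] = [f.to_dict() for f in self.filters]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "filters" in d:
            d["filters"] = [FilterSpec.from_dict(f) for f in d["filters"]]
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "window_seconds" in d:
            d["window_seconds"] = float(d["window_seconds"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def preprocess_epochs(epochs: EpochSet, cfg: PipelineConfig) -> EpochSet:
    """Apply the configured filter chain, then downsample."""
    for spec in cfg.filters:
        epochs = apply_filter(epochs, spec)
    if cfg.target_fs is not None and cfg.target_fs < epochs.fs:
        epochs = resample(epochs, cfg.target_fs)
    return epochs


def build_domains(
    epochs: EpochSet,
    csp_model: CspModel,
    cfg: PipelineConfig,
    stats: dict[str, NormStats] | None = None,
) -> tuple[dict[str, DomainTensor], dict[str, NormStats]]:
    """Time/spatial/phase tensors with (optionally frozen) normalization.

    Pass ``stats=None`` on training data to fit normalization statistics;
    pass the returned stats to transform held-out data identically.
    """
    domains = {
        "time": DomainTensor(epochs.data.copy(), "time", epochs.fs),
        "spatial": apply_csp(csp_model, epochs, L=cfg.csp_L),
        "phase": phase_domain(epochs),
    }
    fitted: dict[str, NormStats] = {}
    if cfg.normalize:
        for name, tensor in domains.items():
            domains[name], fitted[name] = normalize(
                tensor, None if stats is None else stats[name]
            )
    return domains, fitted


def _crop(domains: dict[str, DomainTensor], labels, cfg: PipelineConfig) -> CropSet:
    return make_crops(domains, labels, cfg.window_seconds, cfg.step_seconds)


def _model_config(epochs: EpochSet, cfg: PipelineConfig, seed: int) -> ModelConfig:
    n_samples = int(round(cfg.window_seconds * epochs.fs))
    return ModelConfig(
        n_channels=epochs.n_channels,
        n_samples=n_samples,
        n_classes=epochs.n_classes,
        seed=seed,
        **cfg.model,
    )


def run_fold(
    train_set: EpochSet,
    test_set: EpochSet,
    cfg: PipelineConfig,
    seed: int,
) -> tuple[dict[str, float], list[dict]]:
    """Fit representations and the network on ``train_set``, score ``test_set``.

    Returns per-head trial accuracies (%) and the epoch-level history rows.
    """
    csp_model = fit_csp(train_set, ridge=cfg.csp_ridge, log_sqrt=cfg.csp_log_sqrt)
    train_domains, stats = build_domains(train_set, csp_model, cfg, stats=None)
    test_domains, _ = build_domains(test_set, csp_model, cfg, stats=stats or None)

    train_crops = _crop(train_domains, train_set.labels, cfg)
    test_crops = _crop(test_domains, test_set.labels, cfg)

    model = MDCNN(_model_config(train_set, cfg, seed))
    tcfg = replace(cfg.train, seed=seed)
    history = train(model, train_crops, test_crops, tcfg)
    preds = predict(model, test_crops)
    accs = {head: trial_accuracy(preds, head) for head in preds.heads}
    return accs, history.to_rows()


def run_pipeline(epochs: EpochSet, cfg: PipelineConfig, out_dir=None) -> CvReport:
    """Stratified k-fold cross-validation of the full pipeline."""
    pre = preprocess_epochs(epochs, cfg)
    assignment = stratified_folds(pre.labels, k=cfg.cv_k, seed=cfg.seed)
    heads = ("time", "spatial", "phase", "multi")
    fold_acc: dict[str, list[float]] = {h: [] for h in heads}
    histories = []
    for fold in range(cfg.cv_k):
        test_idx = np.nonzero(assignment == fold)[0]
        train_idx = np.nonzero(assignment != fold)[0]
        accs, history = run_fold(
            pre.select(train_idx), pre.select(test_idx), cfg, seed=cfg.seed + fold
        )
        for h in heads:
            fold_acc[h].append(accs[h])
        histories.append(history)

    report = CvReport(
        fold_acc=fold_acc,
        chance=chance_limit(pre.n_trials, pre.n_classes),
        n_trials=pre.n_trials,
        n_classes=pre.n_classes,
        fold_assignment=assignment,
        seed=cfg.seed,
        extra={"config_hash": cfg.config_hash(), "version": __version__},
    )
    if out_dir is not None:
        _write_artifacts(report, histories, cfg, out_dir)
    return report


def run_holdout(
    train_set: EpochSet, test_set: EpochSet, cfg: PipelineConfig, seed: int | None = None
) -> dict[str, float]:
    """Single preprocessed train/test split; cheap accuracy estimate."""
    pre_train = preprocess_epochs(train_set, cfg)
    pre_test = preprocess_epochs(test_set, cfg)
    accs, _ = run_fold(pre_train, pre_test, cfg, seed=cfg.seed if seed is None else seed)
    return accs


def _write_artifacts(report: CvReport, histories, cfg: PipelineConfig, out_dir) -> None:
    import csv
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_json(out / "report.json")
    with open(out / "report.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["fold", "head", "accuracy"])
        writer.writeheader()
        writer.writerows(report.to_rows())
    rows = [dict(r, fold=i) for i, hist in enumerate(histories) for r in hist]
    if rows:
        with open(out / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
            writer.writeheader()
            writer.writerows(rows)
    with open(out / "provenance.json", "w") as fh:
        json.dump(
            {"config": cfg.to_dict(), "config_hash": cfg.config_hash(),
             "seed": cfg.seed, "version": __version__},
            fh, indent=2, default=str,
        )
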