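"""Cross-validation, per-trial accuracy, chance limits and summary statistics.

Accuracy of a cropped-training classifier is scored per trial: the softmax
rows of a trial's crops are averaged and the argmax compared with the
label.  Because small test sets let a random classifier stray well above
the nominal 1/M rate, significance is judged against the binomial upper
confidence limit of chance-level accuracy (Müller-Putz-style): with
``p0 = 1/M`` and n trials, the threshold is the smallest count
``m = ceil(n·p0 + z_{1−α/2}·sqrt(n·p0·(1−p0)))`` expressed as a
percentage.  For 90 trials and 3 classes at α = 0.05 this is
100·39/90 = 43.33 %.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .net.train import PredictionSet


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Assign each trial to one of ``k`` stratified folds.

    Per-class counts across folds differ by at most one, and each class's
    remainder trials are dealt to the currently smallest folds, so total
    fold sizes also differ by at most one (e.g. 288 trials over 10 folds
    gives folds of 28 or 29).  Every class must have at least ``k`` trials.
    Returns an integer fold id per trial.
    """
    labels = np.asarray(labels)
    classes, class_counts = np.unique(labels, return_counts=True)
    small = classes[class_counts < k]
    if small.size:
        raise ValueError(f"class(es) {small.tolist()} have fewer than k={k} trials")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=np.int64)
    totals = np.zeros(k, dtype=np.int64)
    for cls in classes:
        idx = rng.permutation(np.nonzero(labels == cls)[0])
        base, extra = divmod(idx.size, k)
        counts = np.full(k, base, dtype=np.int64)
        smallest_first = np.lexsort((np.arange(k), totals))
        counts[smallest_first[:extra]] += 1
        pos = 0
        for fold in range(k):
            assignment[idx[pos : pos + counts[fold]]] = fold
            pos += counts[fold]
        totals += counts
    return assignment


def aggregate_trial_probs(preds: PredictionSet, head: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean softmax row per trial; returns (trial ids, probs, trial labels)."""
    probs = preds.probs[head]
    trials = np.unique(preds.trial_index)
    agg = np.empty((trials.size, probs.shape[1]))
    trial_labels = np.empty(trials.size, dtype=np.int64)
    for i, t in enumerate(trials):
        mask = preds.trial_index == t
        if not mask.any():
            raise ValueError(f"trial {t} has no crops")
        agg[i] = probs[mask].mean(axis=0)
        trial_labels[i] = preds.labels[mask][0]
    return trials, agg, trial_labels


def trial_accuracy(preds: PredictionSet, head: str, per_crop: bool = False) -> float:
    """Percent correct for one head.

    Default is mean-probability voting over each trial's crops (argmax ties
    break to the lowest class index); ``per_crop=True`` scores raw crops.
    """
    if per_crop:
        p = preds.probs[head]
        return 100.0 * float((p.argmax(axis=1) == preds.labels).mean())
    _, agg, trial_labels = aggregate_trial_probs(preds, head)
    return 100.0 * float((agg.argmax(axis=1) == trial_labels).mean())


def chance_limit(n_trials: int, n_classes: int, alpha: float = 0.05,
                 method: str = "normal") -> float:
    """Upper confidence limit of chance accuracy, in percent.

    ``method="normal"``: integer-ceiling count under the binomial normal
    approximation (reproduces 43.33 % for 90 trials / 3 classes).
    ``method="binomial"``: exact binomial tail.
    """
    if n_trials < 1 or n_classes < 2:
        raise ValueError("need n_trials >= 1 and n_classes >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    p0 = 1.0 / n_classes
    if method == "normal":
        z = stats.norm.ppf(1 - alpha / 2)
        m = int(np.ceil(n_trials * p0 + z * np.sqrt(n_trials * p0 * (1 - p0))))
    elif method == "binomial":
        # smallest m with P(X >= m) <= alpha/2 under X ~ Bin(n, p0)
        m = int(stats.binom.isf(alpha / 2, n_trials, p0)) + 1
    else:
        raise ValueError(f"unknown method {method!r}")
    return 100.0 * m / n_trials


def cohens_d(a: np.ndarray, b: np.ndarray, paired: bool = False) -> float:
    """Effect size; pooled-SD variant by default, paired-differences optional."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if paired:
        diff = a - b
        sd = diff.std(ddof=1)
        return 0.0 if sd == 0 else float(abs(diff.mean()) / sd)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    return 0.0 if pooled == 0 else float(abs(a.mean() - b.mean()) / pooled)


def paired_stats(acc_a: np.ndarray, acc_b: np.ndarray,
                 paired_d: bool = False) -> tuple[float, float, float]:
    """Paired t-test plus Cohen's d between two per-subject accuracy vectors."""
    acc_a, acc_b = np.asarray(acc_a, float), np.asarray(acc_b, float)
    if acc_a.shape != acc_b.shape or acc_a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    if np.allclose(acc_a, acc_b):
        return 0.0, 1.0, 0.0
    d = cohens_d(acc_a, acc_b, paired=paired_d)
    diff = acc_a - acc_b
    if diff.std(ddof=1) == 0:
        # constant offset: effect size is well defined, the paired p is not
        import warnings

        warnings.warn("differences have zero variance; paired p-value undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan"), float("nan"), d
    t, p = stats.ttest_rel(acc_a, acc_b)
    return float(t), float(p), d


@dataclass
class CvReport:
    """Per-fold, per-head trial accuracies (%) with summary statistics."""

    fold_acc: dict[str, list[float]]       # head -> one accuracy per fold
    chance: float
    n_trials: int
    n_classes: int
    fold_assignment: np.ndarray
    seed: int
    extra: dict = field(default_factory=dict)

    def mean(self, head: str) -> float:
        return float(np.mean(self.fold_acc[head]))

    def sd(self, head: str) -> float:
        return float(np.std(self.fold_acc[head], ddof=1))

    def summary(self) -> dict:
        return {
            head: {"mean": self.mean(head), "sd": self.sd(head)}
            for head in self.fold_acc
        }

    def to_json(self, path=None) -> str:
        payload = {
            "fold_acc": {h: list(map(float, v)) for h, v in self.fold_acc.items()},
            "summary": self.summary(),
            "chance_limit": self.chance,
            "n_trials": self.n_trials,
            "n_classes": self.n_classes,
            "fold_assignment": self.fold_assignment.tolist(),
            "seed": self.seed,
            "extra": self.extra,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_rows(self) -> list[dict]:
        rows = []
        for head, accs in self.fold_acc.items():
            for fold, acc in enumerate(accs):
                rows.append({"fold": fold, "head": head, "accuracy": acc})
        return rows
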