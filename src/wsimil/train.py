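"""Training protocol and evaluation metrics.

Training iterates one slide (bag) per optimization step with Adam
(lr 2e-4, weight decay 1e-5, betas 0.9/0.999, eps 1e-8 by default) on the
mixed slide/patch objective.  When a training bag holds more than
``max_patches_per_bag`` instances (default 512), a random subset of that
size is drawn for the step; evaluation always uses all patches.  Validation
slide-level cross-entropy is monitored each epoch; training stops once it
fails to improve for ``patience`` consecutive epochs (default 20) and the
checkpoint with the smallest validation loss is returned.  Every source of
randomness (shuffling, subsampling, dropout) derives from the config seed,
so a rerun reproduces the log and checkpoint exactly.

Metrics are the usual confusion-matrix summaries — accuracy, precision,
sensitivity, specificity — plus their balanced headline, the mean of
sensitivity and specificity (mean SS).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bags import FeatureBag
from .losses import LossConfig, slide_loss
from .model import ModelParams, bag_backward, forward

__all__ = [
    "TrainConfig",
    "TrainResult",
    "ConfusionMatrix",
    "MetricsReport",
    "Adam",
    "train",
    "compute_metrics",
    "mean_ss",
    "evaluate",
    "stratified_split",
]


@dataclass
class TrainConfig:
    lr: float = 2e-4
    weight_decay: float = 1e-5
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    patience: int = 20
    max_epochs: int = 200
    seed: int = 0
    max_patches_per_bag: int = 512  # training-time subsample cap

    def validate(self) -> None:
        for name in ("lr", "beta1", "beta2", "adam_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.weight_decay < 0 or self.patience < 0 or self.max_epochs < 1:
            raise ValueError("weight_decay >= 0, patience >= 0, max_epochs >= 1 required")


class Adam:
    """Adam with classic L2 weight decay folded into the gradient."""

    def __init__(self, params: ModelParams, cfg: TrainConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays().items()}

    def step(self, params: ModelParams, grads: dict) -> None:
        c = self.cfg
        self.t += 1
        arrays = params.arrays()
        for k, w in arrays.items():
            g = grads[k] + c.weight_decay * w
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            w -= c.lr * mhat / (np.sqrt(vhat) + c.adam_eps)


@dataclass
class TrainResult:
    best_params: ModelParams
    best_epoch: int
    best_val_loss: float
    log: list[dict] = field(default_factory=list)  # epoch, train_loss, val_loss


def _val_loss(bags: list[FeatureBag], params: ModelParams) -> float:
    losses = [slide_loss(forward(b, params).s_slide, b.label) for b in bags]
    return float(np.mean(losses))


def train(
    train_bags: list[FeatureBag],
    val_bags: list[FeatureBag],
    params: ModelParams,
    loss_cfg: LossConfig | None = None,
    cfg: TrainConfig | None = None,
) -> TrainResult:
    """Fit the attention-MIL model; return the best checkpoint and log."""
    loss_cfg = loss_cfg or LossConfig()
    cfg = cfg or TrainConfig()
    cfg.validate()
    loss_cfg.validate()
    if not train_bags or not val_bags:
        raise ValueError("train and validation splits must be nonempty")
    params = params.copy()
    opt = Adam(params, cfg)
    best = TrainResult(best_params=params.copy(), best_epoch=-1, best_val_loss=np.inf)
    since_best = 0
    for epoch in range(cfg.max_epochs):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(epoch,)))
        order = rng.permutation(len(train_bags))
        epoch_losses = []
        for bi in order:
            bag = train_bags[bi]
            Z = bag.features
            if Z.shape[0] > cfg.max_patches_per_bag:
                keep = rng.choice(Z.shape[0], size=cfg.max_patches_per_bag, replace=False)
                Z = Z[np.sort(keep)]
            total, _, _, grads = bag_backward(Z, bag.label, params, loss_cfg,
                                              train=True, rng=rng)
            if not math.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, bag {bag.slide_id}: {total}"
                )
            opt.step(params, grads)
            epoch_losses.append(total)
        vl = _val_loss(val_bags, params)
        best.log.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                         "val_loss": vl})
        if vl < best.best_val_loss:
            best.best_val_loss = vl
            best.best_epoch = epoch
            best.best_params = params.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best > cfg.patience:
                break
    return best


@dataclass
class ConfusionMatrix:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    mean_ss: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_ss": self.mean_ss,
        }


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def mean_ss(sensitivity: float, specificity: float) -> float:
    """Balanced summary: arithmetic mean of sensitivity and specificity."""
    return (sensitivity + specificity) / 2.0


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and mean SS from counts.

    A metric with a zero denominator is reported as NaN with a warning,
    never silently as 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    return MetricsReport(
        accuracy=_ratio(cm.tp + cm.tn, cm.total, "accuracy"),
        precision=_ratio(cm.tp, cm.tp + cm.fp, "precision"),
        sensitivity=sens,
        specificity=spec,
        mean_ss=mean_ss(sens, spec),
    )


def evaluate(params: ModelParams, test_bags: list[FeatureBag],
             positive_class: int = 1):
    """Score held-out bags: argmax prediction, confusion matrix, metrics.

    Returns ``(MetricsReport, predictions, ConfusionMatrix)`` where
    ``predictions`` is one dict per slide (slide_id, per-class probability,
    predicted and true label).
    """
    if not test_bags:
        raise ValueError("test split is empty")
    cm = ConfusionMatrix()
    preds = []
    for bag in test_bags:
        if bag.label < 0:
            raise ValueError(f"bag {bag.slide_id} has no label")
        fwd = forward(bag, params)
        pred = int(np.argmax(fwd.probs))
        preds.append({"slide_id": bag.slide_id, "probs": fwd.probs.tolist(),
                      "pred": pred, "label": bag.label})
        is_pos = bag.label == positive_class
        if pred == positive_class:
            cm.tp += is_pos
            cm.fp += not is_pos
        else:
            cm.fn += is_pos
            cm.tn += not is_pos
    return compute_metrics(cm), preds, cm


def stratified_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 0):
    """Label-stratified train/val/test index split (disjoint, exhaustive)."""
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    out = [[], [], []]
    for lab in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == lab))
        n = len(idx)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        out[0].extend(idx[:n_tr])
        out[1].extend(idx[n_tr : n_tr + n_va])
        out[2].extend(idx[n_tr + n_va :])
    return tuple(sorted(part) for part in out)
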