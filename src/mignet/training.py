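"""Training loop with periodic adjacency updates, and the evaluation protocols.

Training minimizes cross-entropy with Adam (learning rate 0.01, L2 weight
decay 1e-4 by default) for a configured number of epochs. Every
``update_period`` epochs the adjacency P is refreshed from the running
mean of the layer-3 node embeddings over the just-finished epoch, so after
``n`` completed epochs exactly ``floor(n / update_period)`` updates have
occurred.

Two evaluation protocols are provided, each repeated five times with fresh
seeded randomness and reported as the mean of the per-repeat accuracies:

* within-subject — one subject's trials are split 8:2 (stratified, at the
  trial level, *before* windowing), the decoder is trained on the training
  windows and scored on the held-out windows;
* cross-subject — disjoint random subject sets (20 train / 5 test by
  default) with pooled windows, measuring generalization to unseen people.

Accuracy is per *segment* (windowed fragment); a trial-level majority-vote
accuracy is reported alongside as a supplementary metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from autograd import value_and_grad

from . import graph as G
from .data import EEGSegment, Trial, segments_to_arrays, split_trials, window_trials
from .model import MotorImageryDecoder
from .nn import Adam

__all__ = ["TrainConfig", "EvalReport", "count_updates", "train",
           "segment_accuracy", "eval_within_subject", "eval_cross_subject"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; defaults follow the full-scale protocol
    (lr 0.01, decay 1e-4, 800 epochs, adjacency refresh every 10 epochs)."""

    lr: float = 0.01
    weight_decay: float = 1e-4
    epochs: int = 800
    batch_size: int = 64
    update_period: int = 10
    seed: int = 0
    lr_decay_schedule: bool = False  # alternative reading: per-epoch multiplicative decay

    def __post_init__(self) -> None:
        if min(self.lr, self.epochs, self.batch_size, self.update_period) <= 0:
            raise ValueError("lr, epochs, batch_size, update_period must be positive")
        if self.update_period > self.epochs:
            raise ValueError("update_period must not exceed epochs")


@dataclass
class EvalReport:
    """Per-repeat and mean accuracies for one evaluation protocol."""

    protocol: str                      # "within" or "cross"
    per_repeat_acc: list[float]
    mean_acc: float
    per_class_confusion: np.ndarray    # summed over repeats, rows = true class
    trial_majority_acc: list[float] = field(default_factory=list)  # supplementary
    adjacency_history_ref: str | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "protocol": self.protocol,
            "per_repeat_acc": self.per_repeat_acc,
            "mean_acc": self.mean_acc,
            "per_class_confusion": np.asarray(self.per_class_confusion).tolist(),
            "trial_majority_acc": self.trial_majority_acc,
            "adjacency_history_ref": self.adjacency_history_ref,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def count_updates(completed_epochs: int, update_period: int) -> int:
    """Adjacency updates after ``completed_epochs`` epochs (one per full period)."""
    return completed_epochs // update_period


def train(
    model: MotorImageryDecoder,
    segments: Sequence[EEGSegment],
    cfg: TrainConfig,
    test_segments: Sequence[EEGSegment] | None = None,
) -> dict:
    """Fit the decoder in place; returns a history dict of per-epoch metrics.

    The adjacency state on ``model`` is updated every ``cfg.update_period``
    epochs from the epoch's mean layer-3 embeddings. Raises on NaN loss
    with the epoch and learning rate in the message.
    """
    if len(segments) == 0:
        raise ValueError("no training segments")
    arrays = segments_to_arrays(segments)
    X, y = arrays["data"], arrays["labels"]
    if len(np.unique(y)) < 2:
        raise ValueError("training labels cover fewer than 2 classes")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: dict[str, list] = {"epoch": [], "loss": [], "train_acc": [], "test_acc": []}
    n = len(X)
    test_arrays = segments_to_arrays(test_segments) if test_segments else None

    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_decay_schedule:
            opt.lr = cfg.lr / (1.0 + cfg.weight_decay * (epoch - 1))
        perm = rng.permutation(n)
        losses = []
        correct = 0
        g3_sum = None
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            params = opt.params
            model.params = params

            def batch_loss(p):
                return model.loss(p, xb, yb)

            loss_val, gb = value_and_grad(batch_loss)(params)
            loss_val = float(loss_val)
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch} (lr={opt.lr}); training aborted"
                )
            opt.step(gb)
            losses.append(loss_val)
            logits, stages = model.forward(params, xb, return_stages=True)
            correct += int((np.argmax(np.asarray(logits), -1) == yb).sum())
            batch_g3 = np.asarray(stages["g3"]).sum(axis=0)
            g3_sum = batch_g3 if g3_sum is None else g3_sum + batch_g3
        model.params = opt.params
        model._last_epoch_g3_mean = g3_sum / n  # per-node mean over the epoch

        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)
        if test_arrays is not None:
            acc = segment_accuracy(model, test_arrays["data"], test_arrays["labels"])
            history["test_acc"].append(acc)
        else:
            history["test_acc"].append(np.nan)

        if epoch % cfg.update_period == 0:
            G.update_adjacency(model.adjacency, model._last_epoch_g3_mean, model.config.gat)
            logger.info("epoch %d: adjacency update #%d (every %d epochs)",
                        epoch, model.adjacency.update_count, cfg.update_period)
        assert model.adjacency.update_count == count_updates(epoch, cfg.update_period)
    return history


def segment_accuracy(model: MotorImageryDecoder, X: np.ndarray, y: np.ndarray,
                     batch_size: int = 256) -> float:
    """Fraction of segments whose predicted class matches the label."""
    preds = []
    for start in range(0, len(X), batch_size):
        preds.append(model.predict(X[start : start + batch_size]))
    return float((np.concatenate(preds) == y).mean())


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _majority_vote_acc(y_true, y_pred, trial_ids) -> float:
    accs = []
    for tid in np.unique(trial_ids):
        sel = trial_ids == tid
        votes = np.bincount(y_pred[sel])
        accs.append(float(np.argmax(votes) == y_true[sel][0]))
    return float(np.mean(accs))


def _run_split(
    model_factory: Callable[[int], MotorImageryDecoder],
    train_trials: Sequence[Trial],
    test_trials: Sequence[Trial],
    cfg: TrainConfig,
    repeat_seed: int,
    window: int,
    stride: int,
):
    train_segs = window_trials(train_trials, window, stride)
    test_segs = window_trials(test_trials, window, stride)
    model = model_factory(repeat_seed)
    train(model, train_segs, TrainConfig(**{**asdict(cfg), "seed": repeat_seed}))
    arrays = segments_to_arrays(test_segs)
    preds = []
    for start in range(0, len(arrays["data"]), 256):
        preds.append(model.predict(arrays["data"][start : start + 256]))
    y_pred = np.concatenate(preds)
    y_true = arrays["labels"]
    acc = float((y_pred == y_true).mean())
    cm = _confusion(y_true, y_pred, model.config.n_classes)
    maj = _majority_vote_acc(y_true, y_pred, arrays["trial"])
    return acc, cm, maj, model


def eval_within_subject(
    trials: Sequence[Trial],
    model_factory: Callable[[int], MotorImageryDecoder],
    cfg: TrainConfig,
    ratio: float = 0.8,
    repeats: int = 5,
    window: int = 160,
    stride: int = 20,
) -> EvalReport:
    """Within-subject protocol: stratified 8:2 trial split, then windowing,
    repeated ``repeats`` times with derived seeds; mean segment accuracy."""
    accs, majs = [], []
    cm_total = None
    for r in range(repeats):
        seed_r = cfg.seed + r
        tr, te = split_trials(trials, ratio=ratio, seed=seed_r)
        acc, cm, maj, _ = _run_split(model_factory, tr, te, cfg, seed_r, window, stride)
        accs.append(acc)
        majs.append(maj)
        cm_total = cm if cm_total is None else cm_total + cm
        logger.info("within-subject repeat %d/%d: segment acc %.3f", r + 1, repeats, acc)
    return EvalReport(protocol="within", per_repeat_acc=accs,
                      mean_acc=float(np.mean(accs)), per_class_confusion=cm_total,
                      trial_majority_acc=majs)


def eval_cross_subject(
    trials: Sequence[Trial],
    model_factory: Callable[[int], MotorImageryDecoder],
    cfg: TrainConfig,
    n_train: int = 20,
    n_test: int = 5,
    repeats: int = 5,
    window: int = 160,
    stride: int = 20,
) -> EvalReport:
    """Cross-subject protocol: per repeat, disjoint random subject sets
    (``n_train`` train, ``n_test`` test), pooled windows, segment accuracy."""
    subjects = sorted({t.subject_id for t in trials})
    if len(subjects) < n_train + n_test:
        raise ValueError(
            f"need at least {n_train + n_test} subjects, have {len(subjects)}"
        )
    accs, majs = [], []
    cm_total = None
    for r in range(repeats):
        seed_r = cfg.seed + r
        rng = np.random.default_rng(seed_r)
        chosen = rng.choice(subjects, size=n_train + n_test, replace=False)
        train_subj, test_subj = set(chosen[:n_train]), set(chosen[n_train:])
        tr = [t for t in trials if t.subject_id in train_subj]
        te = [t for t in trials if t.subject_id in test_subj]
        acc, cm, maj, _ = _run_split(model_factory, tr, te, cfg, seed_r, window, stride)
        accs.append(acc)
        majs.append(maj)
        cm_total = cm if cm_total is None else cm_total + cm
        logger.info("cross-subject repeat %d/%d: segment acc %.3f", r + 1, repeats, acc)
    return EvalReport(protocol="cross", per_repeat_acc=accs,
                      mean_acc=float(np.mean(accs)), per_class_confusion=cm_total,
                      trial_majority_acc=majs)
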