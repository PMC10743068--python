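"""Experiment harness: stratified splits, the two training protocols,
validation-F1 model selection, repeated runs, k-fold CV and metrics.

Presets mirror the study protocols: the image-only mRS models train for
300 epochs with Adam (lr 5e-4, weight decay 1e-4, batch 32) and report
mean ± std over 3 runs differing only in weight initialization; the MIP
occlusion models train for 150 epochs (lr 2e-4, weight decay 1e-3,
multiplied by 0.1 every 50 epochs) under 5-fold stratified CV.  The
weights evaluated on the test set are those of the epoch with the best
validation F1 (earliest epoch on ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, StratifiedShuffleSplit

from . import nn


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite."""


@dataclass
class TrainConfig:
    epochs: int = 300
    learning_rate: float = 0.0005
    weight_decay: float = 0.0001
    batch_size: int = 32
    lr_schedule: tuple[float, int] | None = None  # (factor, every_n_epochs)
    n_runs: int = 3
    seed: int = 0

    @classmethod
    def mrs_image_only(cls, **overrides) -> "TrainConfig":
        return replace(cls(), **overrides)

    @classmethod
    def occlusion(cls, **overrides) -> "TrainConfig":
        cfg = cls(epochs=150, learning_rate=0.0002, weight_decay=0.001,
                  batch_size=32, lr_schedule=(0.1, 50), n_runs=1)
        return replace(cfg, **overrides)


@dataclass
class MetricRecord:
    auc: float
    f1: float
    run_or_fold: int = 0
    split: str = "test"

    def __post_init__(self):
        for name, v in (("auc", self.auc), ("f1", self.f1)):
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _largest_remainder(n: int, fractions) -> list[int]:
    quotas = np.asarray(fractions, dtype=float) * n
    base = np.floor(quotas).astype(int)
    rem = quotas - base
    for i in np.argsort(-rem)[: n - base.sum()]:
        base[i] += 1
    return base.tolist()


def stratified_split(labels, fractions=(365 / 465, 40 / 465, 60 / 465),
                     seed: int = 0):
    """Disjoint, exhaustive train/val/test index arrays with per-class counts
    within ±1 of proportional allocation; deterministic given the seed.
    Default fractions reproduce the study's 365/40/60 split of 465 scans."""
    labels = np.asarray(labels)
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    n = len(labels)
    n_train, n_val, n_test = _largest_remainder(n, fractions)
    if counts.min() < 3:
        raise ValueError("a class is too small to appear in every split")
    sss = StratifiedShuffleSplit(n_splits=1, test_size=n_test, random_state=seed)
    rest, test = next(sss.split(np.zeros(n), labels))
    sss2 = StratifiedShuffleSplit(n_splits=1, test_size=n_val, random_state=seed + 1)
    tr, va = next(sss2.split(np.zeros(len(rest)), labels[rest]))
    train, val = rest[tr], rest[va]
    for name, idx in (("train", train), ("val", val), ("test", test)):
        if len(np.unique(labels[idx])) < 2:
            raise ValueError(f"a class is missing from the {name} split")
    return np.sort(train), np.sort(val), np.sort(test)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def evaluate(scores, labels, threshold: float = 0.5, run_or_fold: int = 0,
             split: str = "test") -> MetricRecord:
    """AUC (rank-based, ties ½ credit) and F1 at the given threshold.

    Raises if labels are single-class (AUC undefined); degenerate F1
    denominators yield 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels) or len(scores) < 2:
        raise ValueError("scores and labels must align, length >= 2")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined for single-class labels "
                         f"(F1 at {threshold} would be "
                         f"{f1_score(labels, scores >= threshold, zero_division=0):.3f})")
    auc = float(roc_auc_score(labels, scores))
    preds = (scores >= threshold).astype(int)
    if preds.sum() == 0 or labels.sum() == 0:
        warnings.warn("degenerate F1 denominator; reporting 0", stacklevel=2)
    f1 = float(f1_score(labels, preds, zero_division=0))
    return MetricRecord(auc=auc, f1=f1, run_or_fold=run_or_fold, split=split)


def select_best_epoch(val_f1_history) -> int:
    """Index of the epoch with maximal validation F1; earliest wins ties."""
    hist = np.asarray(val_f1_history, dtype=float)
    return int(np.argmax(hist))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _val_f1(model, inputs, labels, threshold=0.5):
    scores = model.predict_proba(inputs)
    return float(f1_score(np.asarray(labels, dtype=int),
                          (scores >= threshold).astype(int), zero_division=0))


def train(model, train_data, val_data, config: TrainConfig):
    """Optimize BCE with Adam; after each epoch record validation F1 and
    finally restore the weights of the best epoch (earliest on ties).

    ``train_data``/``val_data`` are (inputs, labels); inputs are either one
    stacked array (batched training) or a list of per-sample arrays such as
    variable-length MIL bags (per-sample gradient accumulation).
    Returns (model, history dict).
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    y_train = np.asarray(y_train, dtype=np.float32)
    if len(y_train) == 0 or len(np.asarray(y_val)) == 0:
        raise ValueError("train and val sets must be non-empty")
    batched = isinstance(x_train, np.ndarray)
    n = len(y_train)
    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model, lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    history = {"train_loss": [], "val_f1": [], "lr": []}
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        if config.lr_schedule is not None:
            factor, every = config.lr_schedule
            opt.set_lr(nn.step_decay_lr(config.learning_rate, epoch, factor, every))
        model.train(True)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            if batched:
                probs = model(x_train[idx])
                loss, gprob = nn.bce_loss(probs, y_train[idx])
                model.backward(gprob)
            else:
                loss_sum = 0.0
                for i in idx:
                    prob = model(x_train[i])
                    loss_i, gprob = nn.bce_loss(np.atleast_1d(prob),
                                                y_train[i:i + 1])
                    model.backward(gprob / len(idx))
                    loss_sum += loss_i
                loss = loss_sum / len(idx)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            losses.append(loss)
            opt.step()
        vf1 = _val_f1(model, x_val, y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_f1"].append(vf1)
        history["lr"].append(opt.lr)
        if vf1 > best[0]:
            best = (vf1, model.state())
    if best[1] is not None:
        model.load_state(best[1])
    history["best_epoch"] = select_best_epoch(history["val_f1"])
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# repetition / cross-validation
# ---------------------------------------------------------------------------

def aggregate(records: list[MetricRecord]) -> dict:
    """Mean ± sample std (ddof=1; std 0 for a single record) per metric."""
    aucs = np.array([r.auc for r in records], dtype=float)
    f1s = np.array([r.f1 for r in records], dtype=float)
    std = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return {"auc_mean": float(aucs.mean()), "auc_std": std(aucs),
            "f1_mean": float(f1s.mean()), "f1_std": std(f1s), "n": len(records)}


def repeat_runs(run_fn, n_runs: int = 3, base_seed: int = 0):
    """Run `run_fn(weight_seed) -> MetricRecord` n_runs times with different
    weight-initialization seeds (fixed data split) and aggregate."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records = []
    for r in range(n_runs):
        rec = run_fn(base_seed + 1000 * r)
        records.append(replace(rec, run_or_fold=r))
    return records, aggregate(records)


def kfold_cv(samples, labels, fit_predict, k: int = 10, stratified: bool = True,
             seed: int = 0) -> list[MetricRecord]:
    """k-fold CV: each sample tested exactly once; per-fold AUC/F1 in fold
    order for downstream paired tests.  ``fit_predict(train_idx, test_idx)``
    must return test-set scores."""
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    cls = StratifiedKFold if stratified else KFold
    splitter = cls(n_splits=k, shuffle=True, random_state=seed)
    records = []
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        if len(np.unique(labels[te])) < 2:
            raise ValueError(f"a class is absent from test fold {fold}")
        scores = fit_predict(tr, te)
        records.append(evaluate(scores, labels[te], run_or_fold=fold))
    return records
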