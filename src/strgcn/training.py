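"""Training loop, cross-validation protocol, and classification metrics.

Training minimizes softmax cross-entropy with Adam and a validation-based
early-stopping rule: when validation loss has not improved for ``patience``
consecutive epochs the loop stops and the best-validation weights are
restored.  Evaluation reports confusion counts and the derived accuracy,
recall, precision and F1 percentages, plus an ROC curve from threshold
sweeps on the positive-class probability.  ``run_cv_experiment`` wires the
whole pipeline together: wavelet-coherence connectivity, the shared
noise-floor-screened training graph (or per-epoch graphs), k-fold
cross-validation, per-fold training and testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal
from sklearn.model_selection import (GroupKFold, KFold, StratifiedKFold,
                                     train_test_split)
from sklearn.metrics import auc as _sk_auc, roc_curve as _sk_roc_curve

from .autograd import cross_entropy
from .connectivity import (CWTConfig, epochs_connectivity, log_freqs,
                           screen_noise_floor)
from .graph import build_graph_spec
from .model import ModelConfig, STRGCN, build_variant
from .preprocessing import BANDS, EpochSet
from .simulate import LabeledDataset


@dataclass
class TrainConfig:
    max_epochs: int = 200
    patience: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 32
    validation_fraction: float = 0.1
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1 or self.patience < 1:
            raise ValueError("max_epochs and patience must be >= 1")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Percent-scale classification metrics with the underlying counts."""

    accuracy: float
    recall: float
    precision: float
    f1: float
    confusion: ConfusionCounts
    roc_points: list = field(default_factory=list)
    auc: float = float("nan")
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "recall": self.recall,
            "precision": self.precision, "f1": self.f1, "auc": self.auc,
            "confusion": {"tp": self.confusion.TP, "tn": self.confusion.TN,
                          "fp": self.confusion.FP, "fn": self.confusion.FN},
        }


@dataclass
class FoldSplit:
    k: int
    assignments: np.ndarray
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def kfold_split(n: int, k: int = 10, seed: int = 0,
                stratify_labels=None, groups=None) -> FoldSplit:
    """Random k-fold partition; fold sizes differ by at most one.

    With ``stratify_labels`` per-class proportions are preserved per fold
    (within rounding); with ``groups`` whole groups (e.g. subjects) are kept
    in a single fold.
    """
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside [2, n={n}]")
    assignments = np.empty(n, dtype=int)
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        it = splitter.split(np.zeros(n), groups=np.asarray(groups))
    elif stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(np.zeros(n), np.asarray(stratify_labels))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        it = splitter.split(np.zeros(n))
    for fold, (_, test_idx) in enumerate(it):
        assignments[test_idx] = fold
    return FoldSplit(k=k, assignments=assignments, seed=seed)


class Adam:
    """Adam optimizer over a list of autograd parameters."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.data -= self.lr * ((m / b1c) / (np.sqrt(v / b2c) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _epoch_loss_acc(model: STRGCN, X, P, y) -> tuple[float, float]:
    logits = model.logits(X, P)
    loss = float(cross_entropy(logits, y).data)
    acc = float((logits.data.argmax(axis=1) == y).mean())
    return loss, acc


def train_with_early_stopping(model: STRGCN, train_data, cfg: TrainConfig
                              ) -> dict:
    """Train ``model`` in place; returns a per-epoch history dict.

    ``train_data`` is ``(X, P, y)``: feature maps ``(B, N, T, C)``, per-sample
    propagation operators ``(B, N, N)``, integer labels.  A stratified
    validation split of ``validation_fraction`` is held out internally for
    the stopping signal; the best-validation weights are restored on exit.
    """
    X, P, y = (np.asarray(a) for a in train_data)
    if len(X) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(cfg.seed)
    classes, counts = np.unique(y, return_counts=True)
    n_val = int(round(cfg.validation_fraction * len(X)))
    if cfg.validation_fraction > 0 and n_val >= len(classes) and \
            counts.min() >= 2:
        tr_idx, va_idx = train_test_split(
            np.arange(len(X)), test_size=cfg.validation_fraction,
            random_state=cfg.seed, stratify=y)
    else:  # too little data to hold out: stop on training loss
        tr_idx, va_idx = np.arange(len(X)), np.arange(len(X))
    Xtr, Ptr, ytr = X[tr_idx], P[tr_idx], y[tr_idx]
    Xva, Pva, yva = X[va_idx], P[va_idx], y[va_idx]

    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "train_acc": [], "val_loss": [],
               "val_acc": [], "stopped_epoch": 0, "best_epoch": 0}
    best_loss = np.inf
    best_state = model.state_dict()
    stall = 0
    n_tr = len(Xtr)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n_tr)
        for start in range(0, n_tr, cfg.batch_size):
            idx = order[start: start + cfg.batch_size]
            opt.zero_grad()
            loss = cross_entropy(model.logits(Xtr[idx], Ptr[idx]), ytr[idx])
            if not np.isfinite(loss.data):
                raise ArithmeticError(
                    f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
        tr_loss, tr_acc = _epoch_loss_acc(model, Xtr, Ptr, ytr)
        va_loss, va_acc = _epoch_loss_acc(model, Xva, Pva, yva)
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(va_loss)
        history["val_acc"].append(va_acc)
        history["stopped_epoch"] = epoch
        if va_loss < best_loss - 1e-12:
            best_loss = va_loss
            best_state = model.state_dict()
            history["best_epoch"] = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return history


def metrics_from_confusion(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy/recall/precision/F1 (percent) from confusion counts.

    Undefined ratios (zero denominators) are reported as 0 and flagged.
    """
    if cc.total == 0:
        raise ValueError("empty confusion matrix")
    flags = []
    accuracy = 100.0 * (cc.TP + cc.TN) / cc.total
    if cc.TP + cc.FN > 0:
        recall = 100.0 * cc.TP / (cc.TP + cc.FN)
    else:
        recall = 0.0
        flags.append("recall undefined (no positives)")
    if cc.TP + cc.FP > 0:
        precision = 100.0 * cc.TP / (cc.TP + cc.FP)
    else:
        precision = 0.0
        flags.append("precision undefined (no positive predictions)")
    if 2 * cc.TP + cc.FP + cc.FN > 0:
        f1 = 100.0 * 2 * cc.TP / (2 * cc.TP + cc.FP + cc.FN)
    else:
        f1 = 0.0
        flags.append("f1 undefined")
    return MetricsReport(
        accuracy=round(accuracy, 2), recall=round(recall, 2),
        precision=round(precision, 2), f1=round(f1, 2),
        confusion=cc, flags=flags)


def compute_f1(precision: float, recall: float) -> float:
    """Harmonic mean of percent precision and recall, rounded to 2 dp."""
    for v in (precision, recall):
        if not 0 <= v <= 100:
            raise ValueError("precision/recall must lie in [0, 100]")
    if precision + recall == 0:
        warnings.warn("F1 undefined for P=R=0; reporting 0", RuntimeWarning)
        return 0.0
    return round(2.0 * precision * recall / (precision + recall), 2)


def evaluate(model: STRGCN, test_data, positive_class: int = 1
             ) -> MetricsReport:
    """Confusion-based metrics and ROC of a trained model on held-out data."""
    X, P, y = (np.asarray(a) for a in test_data)
    if len(X) == 0:
        raise ValueError("empty test data")
    probs = model.predict_proba(X, P)
    preds = probs.argmax(axis=1)
    pos = positive_class
    cc = ConfusionCounts(
        TP=int(np.sum((preds == pos) & (y == pos))),
        TN=int(np.sum((preds != pos) & (y != pos))),
        FP=int(np.sum((preds == pos) & (y != pos))),
        FN=int(np.sum((preds != pos) & (y == pos))),
    )
    report = metrics_from_confusion(cc)
    scores = probs[:, pos]
    if len(np.unique(y)) == 2:
        fpr, tpr, _ = _sk_roc_curve(y == pos, scores)
        report.roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        report.auc = float(_sk_auc(fpr, tpr))
    return report


def _decimate_epochs(epochs: np.ndarray, fs: float, work_fs: float
                     ) -> tuple[np.ndarray, float]:
    if work_fs is None or work_fs == fs:
        return epochs, fs
    from fractions import Fraction

    frac = Fraction(work_fs / fs).limit_denominator(1000)
    out = _signal.resample_poly(epochs, frac.numerator, frac.denominator,
                                axis=-1)
    return out, work_fs


def prepare_model_inputs(epochs: np.ndarray, fs: float, band="full",
                         cwt_cfg: CWTConfig | None = None,
                         work_fs: float | None = 128.0
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-epoch feature maps and adjacency stack for the network.

    Epochs are optionally decimated to a working rate and z-scored per
    channel into ``(B, N, T, 1)`` feature maps; each epoch's band-mean
    coherence adjacency (zero diagonal) is returned as ``(B, N, N)``.
    """
    band = BANDS[band] if isinstance(band, str) else band
    epochs, fs = _decimate_epochs(np.asarray(epochs, float), fs, work_fs)
    if cwt_cfg is None:
        cwt_cfg = CWTConfig(freqs=log_freqs(band.lo, band.hi, 16))
    A = epochs_connectivity(epochs, band, cwt_cfg, fs)
    mu = epochs.mean(axis=-1, keepdims=True)
    sd = epochs.std(axis=-1, keepdims=True)
    X = ((epochs - mu) / np.where(sd > 0, sd, 1.0))[..., None]
    return X, A, fs


def training_graph(adjacency: np.ndarray, screen_mads: float | None = 2.0
                   ) -> np.ndarray:
    """Shared propagation operator from a stack of per-epoch adjacencies.

    The per-epoch coherence matrices are averaged (which suppresses the
    estimator's sampling noise), edges indistinguishable from the coherence
    noise floor are screened out, and the renormalized propagation operator
    of the resulting graph is returned.  A single graph shared by all
    samples lets the spatial convolution read each epoch's cross-channel
    correlation directly; per-epoch graphs are available via ``graph_mode``
    in :func:`run_cv_experiment`.
    """
    W = np.asarray(adjacency, float)
    if W.ndim == 3:
        W = W.mean(axis=0)
    if screen_mads is not None:
        W = screen_noise_floor(W, screen_mads)
    return build_graph_spec(W).P


@dataclass
class CVResult:
    fold_reports: list
    mean: dict
    sd: dict
    histories: list
    fold_split: FoldSplit
    classes: list


def run_cv_experiment(dataset: LabeledDataset | EpochSet,
                      model_cfg: ModelConfig | None = None,
                      train_cfg: TrainConfig | None = None,
                      k: int = 10, band="full",
                      cwt_cfg: CWTConfig | None = None,
                      work_fs: float | None = 128.0,
                      positive_label: str = "SZ",
                      variant: str = "STRGCN",
                      graph_mode: str = "average",
                      screen_mads: float | None = 2.0,
                      group_by_subject: bool = False) -> CVResult:
    """k-fold cross-validated classification on labeled epochs.

    Per-epoch connectivity is computed once (each epoch's matrix depends
    only on its own samples); folds are stratified by class (or grouped by
    subject when requested); a fresh model is trained per fold and
    evaluated on the held-out fold.  ``graph_mode='average'`` (default)
    builds one noise-floor-screened propagation operator from the training
    fold's mean connectivity and shares it across samples;
    ``graph_mode='per-epoch'`` gives every sample its own graph.  Fully
    deterministic under fixed seeds.
    """
    if graph_mode not in ("average", "per-epoch"):
        raise ValueError("graph_mode must be 'average' or 'per-epoch'")
    es = dataset.epochs if isinstance(dataset, LabeledDataset) else dataset
    train_cfg = train_cfg or TrainConfig()
    labels = np.asarray(es.labels)
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("dataset must contain at least two classes")
    y = np.searchsorted(classes, labels)
    positive = classes.index(positive_label) if positive_label in classes \
        else 1

    X, A, fs_work = prepare_model_inputs(es.epochs, es.fs, band, cwt_cfg,
                                         work_fs)
    if model_cfg is None:
        model_cfg = ModelConfig(n_nodes=X.shape[1], window_len=X.shape[2],
                                n_classes=len(classes), variant=variant,
                                seed=train_cfg.seed)
    groups = es.subject_ids if group_by_subject else None
    split = kfold_split(len(X), k=k, seed=train_cfg.seed,
                        stratify_labels=None if groups is not None else y,
                        groups=groups)
    reports, histories = [], []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: training data single-class")
        if graph_mode == "average":
            P_shared = training_graph(A[tr], screen_mads)
            P = np.broadcast_to(P_shared, A.shape).copy()
        else:
            P = np.stack([build_graph_spec(a).P for a in A])
        fold_cfg = ModelConfig(**{**model_cfg.__dict__,
                                  "seed": model_cfg.seed + fold})
        model = build_variant(fold_cfg)
        fold_train = TrainConfig(**{**train_cfg.__dict__,
                                    "seed": train_cfg.seed + fold})
        histories.append(train_with_early_stopping(
            model, (X[tr], P[tr], y[tr]), fold_train))
        reports.append(evaluate(model, (X[te], P[te], y[te]), positive))
    keys = ("accuracy", "recall", "precision", "f1")
    mean = {m: float(np.mean([getattr(r, m) for r in reports])) for m in keys}
    sd = {m: float(np.std([getattr(r, m) for r in reports])) for m in keys}
    aucs = [r.auc for r in reports if np.isfinite(r.auc)]
    if aucs:
        mean["auc"] = float(np.mean(aucs))
        sd["auc"] = float(np.std(aucs))
    return CVResult(fold_reports=reports, mean=mean, sd=sd,
                    histories=histories, fold_split=split, classes=classes)
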