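"""Training machinery: splits, folds, early stopping, ensembles, search.

The hexapeptide dataset is split 90/10 stratified by label; the training part
is used in 5-fold cross-validation, each fold yielding one network trained on
the other four folds and monitored on the held-out fold. Monitoring tracks the
area under the ROC curve (AuROCC) on training and validation data each epoch;
the retained weights are those of the epoch with the best validation AuROCC,
with training halted once the validation curve has stopped improving — the
testable surrogate for "the epoch where the training and validation ROC
curves diverge". The five fold models form the deployed mean-consensus
ensemble, and the Youden-J threshold computed on the training split is stored
with it as the default classification cut-off.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .model import (
    DROPOUT_GRID,
    LEARNING_RATE_GRID,
    BATCH_SIZE_GRID,
    EnsembleModel,
    ModelConfig,
    NetworkModel,
    build_network,
)
from .nn import Adam, sigmoid

logger = logging.getLogger(__name__)

DEFAULT_PATIENCE = 5
DEFAULT_MIN_DELTA = 1e-3
DEFAULT_MAX_EPOCHS = 200

__all__ = [
    "SplitSpec",
    "FoldPlan",
    "stratified_split",
    "make_folds",
    "select_stopping_epoch",
    "train_network",
    "train_crossval",
    "hyperparameter_search",
]


@dataclass(frozen=True)
class SplitSpec:
    """A stratified train/test partition of dataset indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    fraction: float
    seed: int
    stratified: bool = True


@dataclass(frozen=True)
class FoldPlan:
    """Stratified assignment of training indices to k cross-validation folds."""

    k: int
    fold_assignments: np.ndarray  # fold id per item, aligned with the labels
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) index arrays for one fold."""
        val = np.flatnonzero(self.fold_assignments == fold)
        train = np.flatnonzero(self.fold_assignments != fold)
        return train, val


def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if y.ndim != 1 or y.size == 0:
        raise ValueError("labels must be a non-empty one-dimensional vector")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    return y.astype(np.int64)


def stratified_split(labels, fraction: float = 0.9, seed: int = 0) -> SplitSpec:
    """Per-class split: round(fraction x class size) items to train
    (round-half-even), the remainder to test. Deterministic under seed."""
    y = _check_labels(labels)
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = round(fraction * idx.size)
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return SplitSpec(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        fraction=fraction,
        seed=seed,
    )


def make_folds(labels, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k folds; per-class fold sizes differ by at most one."""
    y = _check_labels(labels)
    counts = np.bincount(y, minlength=2)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minority class count ({counts.min()})"
        )
    rng = np.random.default_rng(seed)
    assignment = np.empty(y.size, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % k
    return FoldPlan(k=k, fold_assignments=assignment, seed=seed)


def select_stopping_epoch(
    validation_history,
    patience: int = DEFAULT_PATIENCE,
    min_delta: float = DEFAULT_MIN_DELTA,
) -> int:
    """Best-validation epoch (1-based) under patience early stopping.

    Scanning epochs in order, an epoch "improves" when its validation AuROCC
    exceeds the best seen so far by at least ``min_delta`` (strictly, when
    ``min_delta`` is zero). After ``patience`` consecutive non-improving
    epochs the scan stops; the first epoch achieving the best validation
    AuROCC seen up to that point is returned.
    """
    hist = list(validation_history)
    if not hist:
        raise ValueError("empty validation history")
    best = -np.inf
    best_patience = -np.inf
    best_epoch = 1
    bad = 0
    for epoch, v in enumerate(hist, start=1):
        improved = (v - best_patience) >= min_delta if min_delta > 0 else v > best_patience
        if improved:
            best_patience = v
            bad = 0
        else:
            bad += 1
        if v > best:
            best = v
            best_epoch = epoch
        if bad >= patience:
            break
    return best_epoch


def _safe_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    if truth.min() == truth.max():
        return np.nan
    return metrics.roc_curve(scores, truth).auc


def train_network(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: ModelConfig,
    seed: int,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
    min_delta: float = DEFAULT_MIN_DELTA,
    class_weight: bool = False,
) -> NetworkModel:
    """Train one network with per-epoch AuROCC monitoring and early stopping.

    The returned model carries the weights of the best-validation epoch, the
    full train/validation AuROCC history, and the stopping epoch.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    model = build_network(config, seed=seed, n_features=X_train.shape[2])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    opt = Adam(model.net, learning_rate=config.learning_rate)

    if class_weight:
        n_pos = y_train.sum()
        n_neg = y_train.size - n_pos
        w_pos = y_train.size / (2.0 * n_pos)
        w_neg = y_train.size / (2.0 * n_neg)
    history_train: list[float] = []
    history_val: list[float] = []
    best = -np.inf
    best_patience = -np.inf
    best_epoch = 0
    best_weights = model.net.get_weights()
    bad = 0
    n = X_train.shape[0]
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            xb, yb = X_train[batch], y_train[batch]
            model.net.zero_grads()
            logit = model.net.forward_logit(xb, train=True, rng=rng)
            p = sigmoid(logit)
            dlogit = (p - yb) / yb.size
            if class_weight:
                dlogit = dlogit * np.where(yb == 1, w_pos, w_neg)
            model.net.backward(dlogit)
            opt.step()
        auc_train = _safe_auc(model.net.predict_proba(X_train), y_train.astype(int))
        auc_val = _safe_auc(model.net.predict_proba(X_val), np.asarray(y_val).astype(int))
        history_train.append(auc_train)
        history_val.append(auc_val)
        v = -np.inf if np.isnan(auc_val) else auc_val
        improved = (v - best_patience) >= min_delta if min_delta > 0 else v > best_patience
        if improved:
            best_patience = v
            bad = 0
        else:
            bad += 1
        if v > best:
            best = v
            best_epoch = epoch
            best_weights = model.net.get_weights()
        if bad >= patience:
            break
    model.net.set_weights(best_weights)
    model.stopping_epoch = best_epoch
    model.training_history = {"train_auroc": history_train, "val_auroc": history_val}
    return model


def train_crossval(
    X: np.ndarray,
    y: np.ndarray,
    config: ModelConfig,
    folds: FoldPlan,
    seed: int = 0,
    max_epochs: int = DEFAULT_MAX_EPOCHS,
    patience: int = DEFAULT_PATIENCE,
    min_delta: float = DEFAULT_MIN_DELTA,
    class_weight: bool = False,
    feature_table_id: str = "",
) -> EnsembleModel:
    """Train one network per fold and assemble the mean-consensus ensemble.

    Requires a 5-fold plan (the ensemble contract is five members). The
    Youden-J threshold of the ensemble on the full training data is stored on
    the returned model as its default cut-off.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(np.int64)
    members: list[NetworkModel] = []
    for fold in range(folds.k):
        tr, va = folds.fold_indices(fold)
        member_seed = int((seed * 100003 + 7919 * fold + 1) % (2**31))
        try:
            member = train_network(
                X[tr], y[tr], X[va], y[va], config,
                seed=member_seed, max_epochs=max_epochs,
                patience=patience, min_delta=min_delta,
                class_weight=class_weight,
            )
        except Exception as exc:
            raise RuntimeError(f"training failed on fold {fold}: {exc}") from exc
        logger.info(
            "fold %d: stopped at epoch %d (val AuROCC %.4f)",
            fold, member.stopping_epoch,
            member.training_history["val_auroc"][member.stopping_epoch - 1],
        )
        members.append(member)
    ensemble = EnsembleModel(
        members=members,
        feature_table_id=feature_table_id,
        allow_any_size=folds.k != 5,
    )
    roc = metrics.roc_curve(ensemble.predict_batch(X), y)
    thr, _ = metrics.youden_threshold(roc)
    ensemble.threshold = thr
    return ensemble


# ---------------------------------------------------------------------------
# hyperparameter search over the published grid
# ---------------------------------------------------------------------------

_WIDTH_GRID = (8, 16, 32, 64, 128, 256, 512)


def _grid_configs():
    """Deterministic sweep: one shared width for all declared layers."""
    for n_bi, n_dense, dropout, width, batch, lr in itertools.product(
        (1, 2), (1, 2, 3), DROPOUT_GRID, _WIDTH_GRID, BATCH_SIZE_GRID,
        LEARNING_RATE_GRID,
    ):
        n_widths = 1 + n_bi + (n_dense - 1)
        yield ModelConfig(
            n_bidirectional_layers=n_bi,
            n_dense_layers=n_dense,
            dropout=dropout,
            neurons_per_layer=(width,) * n_widths,
            batch_size=batch,
            learning_rate=lr,
        )


def _random_configs(rng: np.random.Generator):
    while True:
        n_bi = int(rng.choice((1, 2)))
        n_dense = int(rng.choice((1, 2, 3)))
        n_widths = 1 + n_bi + (n_dense - 1)
        yield ModelConfig(
            n_bidirectional_layers=n_bi,
            n_dense_layers=n_dense,
            dropout=float(rng.choice(DROPOUT_GRID)),
            neurons_per_layer=tuple(int(rng.choice(_WIDTH_GRID)) for _ in range(n_widths)),
            batch_size=int(rng.choice(BATCH_SIZE_GRID)),
            learning_rate=float(rng.choice(LEARNING_RATE_GRID)),
        )


def hyperparameter_search(
    X: np.ndarray,
    y: np.ndarray,
    budget: int,
    strategy: str = "random",
    seed: int = 0,
    k: int = 5,
    max_epochs: int = 30,
    patience: int = DEFAULT_PATIENCE,
    min_delta: float = DEFAULT_MIN_DELTA,
    candidates: list[ModelConfig] | None = None,
) -> list[tuple[ModelConfig, float]]:
    """Evaluate `budget` configurations by cross-validated mean validation
    AuROCC; returns (config, score) pairs sorted non-increasing by score.

    ``candidates`` overrides the generated search space (e.g. to compare a
    handful of fixed architectures).
    """
    if budget < 1:
        raise ValueError("budget must be at least 1")
    if strategy not in ("grid", "random"):
        raise ValueError(f"strategy must be 'grid' or 'random', got {strategy!r}")
    y = _check_labels(y)
    if candidates is not None:
        if not candidates:
            raise ValueError("empty search space")
        configs = candidates[:budget]
    elif strategy == "grid":
        configs = list(itertools.islice(_grid_configs(), budget))
    else:
        configs = list(itertools.islice(
            _random_configs(np.random.default_rng(seed)), budget))
    folds = make_folds(y, k=k, seed=seed)
    ranked: list[tuple[ModelConfig, float]] = []
    for ci, config in enumerate(configs):
        fold_scores = []
        for fold in range(folds.k):
            tr, va = folds.fold_indices(fold)
            member = train_network(
                X[tr], y[tr], X[va], y[va], config,
                seed=int((seed * 99991 + 31 * ci + fold) % (2**31)),
                max_epochs=max_epochs, patience=patience, min_delta=min_delta,
            )
            fold_scores.append(
                member.training_history["val_auroc"][member.stopping_epoch - 1]
            )
        score = metrics.macro_average(fold_scores)
        logger.info("search %d/%d: mean val AuROCC %.4f", ci + 1, len(configs), score)
        ranked.append((config, score))
    ranked.sort(key=lambda t: -t[1])
    return ranked
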