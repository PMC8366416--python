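"""Training (Adam on MSE), prediction, Pearson CC and five-fold CV.

The decoder is trained with minibatch Adam on mean-squared error over the
three joint outputs (learning rate 0.001, 15 epochs for a full session;
transfer recalibration uses 5). Performance is the Pearson correlation
coefficient (CC) between the predicted and measured window-target angle
series, computed per joint on each held-out fold and averaged over the five
folds:

    CC = sum_i (X_i - mean X)(Y_i - mean Y)
         / sqrt( sum_i (X_i - mean X)^2  sum_i (Y_i - mean Y)^2 )

    CC_5 = (1/5) sum_k CC_k
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .dataset import FoldSplit, WindowDataset, fold_masks
from .errors import ConfigurationError, DataError, DegenerateDataError, TrainingError
from .model import ModelParams, forward_batch, init_model, mse_loss_and_grads

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimizer settings; defaults follow the full-session protocol."""

    learning_rate: float = 0.001
    epochs: int = 15
    batch_size: int = 64
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    shuffle: bool = True
    seed: int = 0
    freeze_conv: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


@dataclass
class CVResult:
    """Per-fold, per-joint CC with mean/std summaries."""

    per_fold_cc: np.ndarray  # (k, 3)
    mean_cc: np.ndarray  # (3,)
    std_cc: np.ndarray  # (3,)
    loss_histories: List[np.ndarray] = field(default_factory=list)

    @classmethod
    def from_folds(cls, per_fold_cc: np.ndarray, loss_histories=None) -> "CVResult":
        per_fold_cc = np.asarray(per_fold_cc, dtype=float)
        return cls(
            per_fold_cc=per_fold_cc,
            mean_cc=per_fold_cc.mean(axis=0),
            std_cc=per_fold_cc.std(axis=0),
            loss_histories=loss_histories or [],
        )


_PARAM_NAMES = ("conv_filters", "conv_biases", "fc_weights", "fc_biases")


def train(
    params: ModelParams, dataset: WindowDataset, config: TrainConfig
) -> Tuple[ModelParams, np.ndarray]:
    """Minibatch Adam on MSE; returns (trained params, per-epoch mean loss).

    Deterministic given the config seed (which drives batch shuffling).
    Raises :class:`TrainingError` if the loss becomes non-finite.
    """
    if dataset.n < 1:
        raise DataError("training requires at least one sample")
    params = params.copy()
    rng = np.random.default_rng(config.seed)
    m = {k: np.zeros_like(getattr(params, k)) for k in _PARAM_NAMES}
    v = {k: np.zeros_like(getattr(params, k)) for k in _PARAM_NAMES}
    t = 0
    history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(dataset.n) if config.shuffle else np.arange(dataset.n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, dataset.n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = mse_loss_and_grads(
                params, dataset.X[idx], dataset.y[idx], freeze_conv=config.freeze_conv
            )
            if not np.isfinite(loss):
                raise TrainingError(
                    f"loss became non-finite at epoch {epoch}, batch {n_batches} "
                    f"(lr={config.learning_rate})"
                )
            t += 1
            for k in _PARAM_NAMES:
                if config.freeze_conv and k.startswith("conv"):
                    continue
                g = grads[k]
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * g
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * g**2
                mhat = m[k] / (1 - config.beta1**t)
                vhat = v[k] / (1 - config.beta2**t)
                setattr(
                    params,
                    k,
                    getattr(params, k) - config.learning_rate * mhat / (np.sqrt(vhat) + config.eps),
                )
            epoch_loss += loss
            n_batches += 1
        history[epoch] = epoch_loss / n_batches
        log.info("epoch %d/%d: mean loss %.6f", epoch + 1, config.epochs, history[epoch])
    return params, history


def predict_series(params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Predicted (n, 3) angle matrix; pure function of params and X."""
    _, pred = forward_batch(params, np.asarray(X, dtype=float))
    return pred


def correlation_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson CC between two equal-length series.

    Returns NaN with a warning when either series is constant (the
    coefficient is undefined there); callers exclude NaNs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DataError(f"series lengths differ: {x.size} vs {y.size}")
    if x.size < 2:
        raise DataError("CC needs at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.sum(dx * dx))
    syy = float(np.sum(dy * dy))
    if sxx == 0.0 or syy == 0.0:
        warnings.warn("correlation undefined for constant series; returning NaN")
        return float("nan")
    return float(np.sum(dx * dy) / np.sqrt(sxx * syy))


def per_joint_cc(pred: np.ndarray, measured: np.ndarray) -> np.ndarray:
    """CC per joint column between two (n, 3) series."""
    pred = np.atleast_2d(pred)
    measured = np.atleast_2d(measured)
    return np.array(
        [correlation_coefficient(pred[:, j], measured[:, j]) for j in range(measured.shape[1])]
    )


def cross_validate(
    dataset: WindowDataset,
    folds: FoldSplit,
    config: TrainConfig = None,
    init_params: Optional[ModelParams] = None,
    init_seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of the decoder.

    For each fold, a model is initialized from the seed lineage
    (``init_seed + fold``) — or warm-started from ``init_params`` when given
    (transfer recalibration) — trained on the other k-1 groups and scored by
    per-joint CC on the held-out group.
    """
    config = config or TrainConfig()
    per_fold = np.empty((folds.k, dataset.y.shape[1]))
    histories = []
    for g, train_mask, test_mask in fold_masks(dataset, folds):
        if int(test_mask.sum()) < 2:
            raise DataError(f"fold {g} has fewer than 2 test windows")
        if init_params is None:
            params0 = init_model(seed=init_seed + g)
        else:
            params0 = init_params.copy()
        fold_config = replace(config, seed=config.seed + g)
        trained, hist = train(params0, dataset.subset(train_mask), fold_config)
        pred = predict_series(trained, dataset.X[test_mask])
        per_fold[g] = per_joint_cc(pred, dataset.y[test_mask])
        histories.append(hist)
    return CVResult.from_folds(per_fold, histories)
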