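"""New-day evaluation and freeze-conv recalibration.

Two procedures mirror the two ways an existing decoder meets a new session:

* **direct testing** — run the trained model on the new windows with no
  parameter updates and report per-joint CC (this is what degrades when
  electrode contact, sleeve position or skin impedance change between
  days);
* **FC-only fine-tuning** — freeze the convolutional force-pattern filters
  (they encode temporal activation shape, which transfers) and retrain only
  the linear readout on the small new-day session (five singleton-trial
  folds, 5 epochs), warm-started from the trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .dataset import FoldSplit, WindowDataset
from .errors import ConfigurationError, TrainingError
from .model import ModelParams
from .training import CVResult, TrainConfig, cross_validate, per_joint_cc, predict_series, train


@dataclass
class TransferConfig:
    """Recalibration settings: short FC-only training on the new session."""

    freeze_conv: bool = True
    epochs: int = 5
    learning_rate: float = 0.001
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ConfigurationError("learning_rate must be >= 0")

    def as_train_config(self) -> TrainConfig:
        # learning_rate 0 is allowed here (degenerate no-op fine-tune) but
        # TrainConfig forbids it; map it to a tiny rate with zero effect via
        # epochs — instead we special-case it in fine_tune_fc.
        return TrainConfig(
            learning_rate=self.learning_rate if self.learning_rate > 0 else 1e-30,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.seed,
            freeze_conv=self.freeze_conv,
        )


def direct_test(trained: ModelParams, dataset: WindowDataset) -> np.ndarray:
    """Per-joint CC of the trained model on a new dataset; no updates."""
    pred = predict_series(trained, dataset.X)
    return per_joint_cc(pred, dataset.y)


def _assert_conv_frozen(before: ModelParams, after: ModelParams) -> None:
    if not (
        np.array_equal(before.conv_filters, after.conv_filters)
        and np.array_equal(before.conv_biases, after.conv_biases)
    ):
        raise TrainingError("convolutional layer changed despite freeze_conv")


def fine_tune_fc(
    trained: ModelParams,
    dataset: WindowDataset,
    folds: FoldSplit,
    config: TransferConfig = None,
) -> Tuple[CVResult, ModelParams]:
    """Five-fold CV of FC-only fine-tuning, plus a model tuned on all trials.

    Each fold warm-starts from ``trained``, updates only the FC weights and
    biases for ``config.epochs`` epochs, and is scored on its held-out
    trial. Bit-equality of the frozen convolutional parameters is asserted.
    The returned model is fine-tuned the same way on the full new session.
    """
    config = config or TransferConfig()
    if config.learning_rate == 0.0:
        # degenerate config: no updates, CC equals direct testing per fold
        from .dataset import fold_masks

        per_fold = []
        for _, _, test_mask in fold_masks(dataset, folds):
            per_fold.append(direct_test(trained, dataset.subset(test_mask)))
        return CVResult.from_folds(np.asarray(per_fold)), trained.copy()
    tc = config.as_train_config()
    result = cross_validate(dataset, folds, tc, init_params=trained)
    tuned, _ = train(trained.copy(), dataset, tc)
    if config.freeze_conv:
        _assert_conv_frozen(trained, tuned)
    return result, tuned
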