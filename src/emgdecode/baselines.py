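"""Classical regression baselines and the model-comparison statistics.

The decoder is compared against four conventional regressors — linear
regression (LR), RBF support vector regression (SVR), k-nearest neighbors
(KNN, k=5) and decision tree regression (DT) — fitted per joint on the same
windows and scored with the identical fold splits and CC implementation.
Across subjects (independent sessions), models are compared with two-sided
paired t-tests under Benjamini-Hochberg FDR correction.

Baseline features are either the flattened 60 x 32 window (1920-dim,
matching the information the decoder sees) or the per-channel window mean
(32-dim); the representation must be identical across compared models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .dataset import FoldSplit, WindowDataset, fold_masks
from .errors import ConfigurationError, DataError, DegenerateDataError
from .training import CVResult, TrainConfig, cross_validate, per_joint_cc

BASELINE_KINDS = ("LR", "SVR", "KNN", "DT")
MODEL_ORDER = ("CNN",) + BASELINE_KINDS


@dataclass
class BaselineSpec:
    """One conventional regressor: kind, feature mode, hyperparameters."""

    model_kind: str
    feature_mode: str = "flat"  # "flat" (1920-dim) or "channel_mean" (32-dim)
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in BASELINE_KINDS:
            raise ConfigurationError(f"unknown baseline kind {self.model_kind!r}")
        if self.feature_mode not in ("flat", "channel_mean"):
            raise ConfigurationError(f"unknown feature mode {self.feature_mode!r}")


def featurize(X: np.ndarray, mode: str) -> np.ndarray:
    """(n, 60, 32) windows -> (n, d) feature matrix."""
    X = np.asarray(X, dtype=float)
    if mode == "flat":
        return X.reshape(X.shape[0], -1)
    if mode == "channel_mean":
        return X.mean(axis=1)
    raise ConfigurationError(f"unknown feature mode {mode!r}")


def _make_regressor(spec: BaselineSpec):
    from sklearn.linear_model import LinearRegression
    from sklearn.neighbors import KNeighborsRegressor
    from sklearn.svm import SVR
    from sklearn.tree import DecisionTreeRegressor

    hp = spec.hyperparameters
    if spec.model_kind == "LR":
        return LinearRegression(**hp)
    if spec.model_kind == "SVR":
        return SVR(**{"kernel": "rbf", **hp})
    if spec.model_kind == "KNN":
        return KNeighborsRegressor(**{"n_neighbors": 5, **hp})
    if spec.model_kind == "DT":
        return DecisionTreeRegressor(**{"random_state": spec.seed, **hp})
    raise ConfigurationError(spec.model_kind)


def fit_baseline(spec: BaselineSpec, X: np.ndarray, y: np.ndarray) -> List:
    """Fit three independent single-output regressors (one per joint)."""
    feats = featurize(X, spec.feature_mode)
    if feats.shape[0] < 2:
        raise DataError("baseline fitting needs >= 2 samples")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    models = []
    for j in range(y.shape[1]):
        reg = _make_regressor(spec)
        reg.fit(feats, y[:, j])
        models.append(reg)
    return models


def predict_baseline(models: List, X: np.ndarray, feature_mode: str) -> np.ndarray:
    feats = featurize(X, feature_mode)
    return np.column_stack([m.predict(feats) for m in models])


def cross_validate_baseline(
    spec: BaselineSpec, dataset: WindowDataset, folds: FoldSplit
) -> CVResult:
    """Five-fold CV of one baseline with the shared trial-level folds."""
    per_fold = np.empty((folds.k, dataset.y.shape[1]))
    for g, train_mask, test_mask in fold_masks(dataset, folds):
        models = fit_baseline(spec, dataset.X[train_mask], dataset.y[train_mask])
        pred = predict_baseline(models, dataset.X[test_mask], spec.feature_mode)
        per_fold[g] = per_joint_cc(pred, dataset.y[test_mask])
    return CVResult.from_folds(per_fold)


def evaluate_all_models(
    dataset: WindowDataset,
    folds: FoldSplit,
    cnn_config: TrainConfig = None,
    feature_mode: str = "flat",
    baseline_hyperparameters: Optional[Dict[str, Dict]] = None,
    cnn_result: Optional[CVResult] = None,
    seed: int = 0,
) -> Dict[str, CVResult]:
    """CV the decoder and all four baselines on identical splits.

    ``cnn_result`` may carry a precomputed decoder CV (same dataset and
    folds) to avoid retraining. Returns a dict model name -> CVResult in the
    order CNN, LR, SVR, KNN, DT.
    """
    hp = baseline_hyperparameters or {}
    results: Dict[str, CVResult] = {}
    results["CNN"] = (
        cnn_result
        if cnn_result is not None
        else cross_validate(dataset, folds, cnn_config or TrainConfig(), init_seed=seed)
    )
    for kind in BASELINE_KINDS:
        spec = BaselineSpec(kind, feature_mode=feature_mode,
                            hyperparameters=hp.get(kind, {}), seed=seed)
        results[kind] = cross_validate_baseline(spec, dataset, folds)
    return results


def mean_cc_table(per_subject: Dict[str, Dict[str, CVResult]]) -> pd.DataFrame:
    """Subjects x models table of CC averaged over folds and joints."""
    rows = {}
    for subject, results in per_subject.items():
        rows[subject] = {name: float(np.nanmean(res.mean_cc)) for name, res in results.items()}
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(MODEL_ORDER))


def paired_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired Student's t-test on per-subject values.

    Identical vectors give (t=0, p=1). A nonzero constant difference has
    zero variance, making t undefined; that degenerate case raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("paired test needs two equal-length 1-D vectors")
    if a.size < 2:
        raise DataError("paired test needs n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        raise DegenerateDataError(
            "paired differences are a nonzero constant; t statistic undefined"
        )
    t, p = sstats.ttest_rel(a, b)
    return float(t), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Model comparison across subjects: means, paired tests, BH q-values."""

    table: pd.DataFrame  # subjects x models mean CC
    summary_mean: pd.Series
    summary_std: pd.Series
    t_statistics: Dict[str, float]
    p_values: Dict[str, float]
    q_values: Dict[str, float]


def compare_models(table: pd.DataFrame, reference: str = "CNN") -> ComparisonResult:
    """Paired t-tests of the reference model against every other column."""
    others = [c for c in table.columns if c != reference]
    tstats, pvals = {}, {}
    for c in others:
        t, p = paired_t_test(table[reference].to_numpy(), table[c].to_numpy())
        tstats[c], pvals[c] = t, p
    qvals = dict(zip(others, bh_fdr([pvals[c] for c in others])))
    return ComparisonResult(
        table=table,
        summary_mean=table.mean(axis=0),
        summary_std=table.std(axis=0),
        t_statistics=tstats,
        p_values=pvals,
        q_values=qvals,
    )
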