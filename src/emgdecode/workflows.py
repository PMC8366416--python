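"""End-to-end experiment workflows tying the stages together.

These functions reproduce the two study designs on a synthetic session:

* the *initial experiment*: a 10-trial session, preprocessing with
  session-wide normalization stats, 500 ms / 100 ms windowing, a seeded
  random 5-group trial partition, five-fold CV of the decoder (15 epochs),
  and a final model trained on all trials;
* the *second experiment*: a 5-trial new-day session (day-shifted signal),
  scored first by direct testing with the old model and old normalization
  stats, then by FC-only fine-tuning (5 epochs) with singleton-trial folds
  and freshly computed stats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .containers import EnvelopeSignal
from .dataset import (FoldSplit, SyncedTrial, WindowDataset, build_dataset,
                      make_folds, synchronize)
from .model import ModelParams, init_model
from .preprocessing import (FilterSpec, apply_stats, envelope_filter,
                            normalize_unit, rectify, resample_to_angle_rate)
from .synthetic import DayShiftSpec, ParadigmSpec, SynergySpec, SyntheticSession, apply_day_shift, generate_session
from .training import CVResult, TrainConfig, cross_validate, train
from .transfer import TransferConfig, direct_test, fine_tune_fc


def session_envelope_stats(session: SyntheticSession, filter_spec: FilterSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel min/max of the filtered envelope over the whole session."""
    mins, maxs = [], []
    for emg, _ in session.trials:
        env = envelope_filter(rectify(emg), filter_spec)
        mins.append(env.samples.min(axis=0))
        maxs.append(env.samples.max(axis=0))
    return np.min(mins, axis=0), np.max(maxs, axis=0)


def preprocess_session(
    session: SyntheticSession,
    filter_spec: FilterSpec = None,
    stats: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[List[SyncedTrial], Tuple[np.ndarray, np.ndarray]]:
    """Rectify/filter/normalize/resample every trial and sync with angles.

    Normalization uses session-wide per-channel stats: either the stats of
    this session (training) or stats carried over from a previous session
    (direct testing on a new day).
    """
    filter_spec = filter_spec or FilterSpec()
    if stats is None:
        stats = session_envelope_stats(session, filter_spec)
    trials = []
    for emg, angles in session.trials:
        env = envelope_filter(rectify(emg), filter_spec)
        norm = apply_stats(env, stats[0], stats[1])
        resampled = resample_to_angle_rate(norm, angles.fs)
        trials.append(synchronize(resampled, angles))
    return trials, stats


@dataclass
class ExperimentResult:
    """Everything the initial experiment produces."""

    cv: CVResult
    final_model: ModelParams
    dataset: WindowDataset
    folds: FoldSplit
    stats: Tuple[np.ndarray, np.ndarray]
    session: SyntheticSession


def run_initial_experiment(
    seed: int = 0,
    paradigm: ParadigmSpec = None,
    synergy: SynergySpec = None,
    train_config: TrainConfig = None,
    filter_spec: FilterSpec = None,
    session: SyntheticSession = None,
) -> ExperimentResult:
    """Generate (or take) a 10-trial session, run five-fold CV, train final model."""
    paradigm = paradigm or ParadigmSpec()
    if session is None:
        session = generate_session(paradigm, synergy, seed=seed)
    trials, stats = preprocess_session(session, filter_spec)
    dataset = build_dataset(trials)
    folds = make_folds(sorted({t.trial_id for t in trials}), k=5, mode="initial", seed=seed)
    config = train_config or TrainConfig(seed=seed)
    cv = cross_validate(dataset, folds, config, init_seed=seed)
    final_model, _ = train(init_model(seed=seed), dataset, config)
    return ExperimentResult(cv=cv, final_model=final_model, dataset=dataset,
                            folds=folds, stats=stats, session=session)


@dataclass
class TransferResult:
    """Direct-test and fine-tuning outcomes on the new-day session."""

    direct_cc: np.ndarray
    finetune_cv: CVResult
    tuned_model: ModelParams
    new_dataset_old_stats: WindowDataset
    new_dataset_new_stats: WindowDataset
    folds: FoldSplit


def run_transfer_experiment(
    initial: ExperimentResult,
    seed: int = 1000,
    day_shift: DayShiftSpec = None,
    n_trials: int = 5,
    transfer_config: TransferConfig = None,
    filter_spec: FilterSpec = None,
) -> TransferResult:
    """New-day session -> direct testing, then FC-only fine-tuning.

    The new session reuses the initial session's paradigm and mixing matrix,
    regenerated with fresh noise and passed through a day shift. Direct
    testing reuses the old normalization stats (the deployed model knows
    nothing of the new day); fine-tuning recomputes stats on the new
    session, as a recalibration procedure may.
    """
    paradigm = initial.session.paradigm
    day_shift = day_shift or DayShiftSpec.random(seed)
    new_session = generate_session(paradigm, initial.session.synergy,
                                   n_trials=n_trials, seed=seed,
                                   session_id="second-day")
    new_session = apply_day_shift(new_session, day_shift)
    trials_old, _ = preprocess_session(new_session, filter_spec, stats=initial.stats)
    ds_old = build_dataset(trials_old)
    direct_cc = direct_test(initial.final_model, ds_old)
    trials_new, _ = preprocess_session(new_session, filter_spec)
    ds_new = build_dataset(trials_new)
    folds = make_folds(sorted({t.trial_id for t in trials_new}), k=5, mode="second", seed=seed)
    config = transfer_config or TransferConfig(seed=seed)
    finetune_cv, tuned = fine_tune_fc(initial.final_model, ds_new, folds, config)
    return TransferResult(direct_cc=direct_cc, finetune_cv=finetune_cv,
                          tuned_model=tuned, new_dataset_old_stats=ds_old,
                          new_dataset_new_stats=ds_new, folds=folds)
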