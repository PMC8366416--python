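"""Windowed supervised dataset construction and five-fold trial grouping.

A 500 ms window of the 120 Hz envelope is a 60 x 32 matrix; its target is
the per-joint mean angle over the same 60 samples. The sliding stride is
100 ms (12 samples, i.e. 400 ms overlap). Windows never cross trial
boundaries, and cross-validation folds are built at the trial level so no
window leaks between folds.

Two fold designs are supported, mirroring the two experiment designs:

* ``initial``: >= 5 trials (canonically 10) randomly partitioned into 5
  near-equal groups with a recorded seed;
* ``second``: exactly 5 trials, trial i -> group i (small recalibration
  session, one trial per group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .containers import AngleRecording, EnvelopeSignal
from .errors import ConfigurationError, DataError

WINDOW_MS = 500.0
STRIDE_MS = 100.0
SYNC_TOLERANCE_S = 1.0


@dataclass
class SyncedTrial:
    """Envelope and angles on a common 120 Hz timeline."""

    envelope: np.ndarray  # (T, 32)
    angles: np.ndarray  # (T, 3), degrees
    fs: float
    trial_id: Optional[int] = None
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.envelope.shape[0] != self.angles.shape[0]:
            raise DataError("envelope and angles must have equal length after sync")

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[0]


@dataclass
class WindowSample:
    """One supervised sample: 60x32 envelope window, 3-vector mean angle."""

    X: np.ndarray
    y: np.ndarray
    window_start_index: int
    trial_id: Optional[int] = None


@dataclass
class FoldSplit:
    """Trial-level assignment of trials to k cross-validation groups."""

    k: int
    group_of_trial: Dict[int, int]
    seed: Optional[int] = None
    mode: str = "initial"

    def __post_init__(self) -> None:
        groups = set(self.group_of_trial.values())
        if groups != set(range(self.k)):
            raise ConfigurationError(
                f"every group 0..{self.k - 1} must be non-empty, got {sorted(groups)}"
            )

    def trials_in_group(self, g: int) -> List[int]:
        return sorted(t for t, gg in self.group_of_trial.items() if gg == g)


def synchronize(envelope: EnvelopeSignal, angles: AngleRecording) -> SyncedTrial:
    """Truncate both streams to their common length.

    The streams must share the sampling rate; a length mismatch larger than
    one second indicates broken synchronization and raises.
    """
    if envelope.fs != angles.fs:
        raise DataError(f"rates differ: envelope {envelope.fs} Hz, angles {angles.fs} Hz")
    n_env, n_ang = envelope.n_samples, angles.n_samples
    mismatch_s = abs(n_env - n_ang) / envelope.fs
    if mismatch_s > SYNC_TOLERANCE_S:
        raise DataError(
            f"stream length mismatch of {mismatch_s:.2f} s exceeds "
            f"{SYNC_TOLERANCE_S:.1f} s sync tolerance"
        )
    n = min(n_env, n_ang)
    return SyncedTrial(
        envelope=envelope.samples[:n],
        angles=angles.samples[:n],
        fs=envelope.fs,
        trial_id=envelope.trial_id if envelope.trial_id is not None else angles.trial_id,
        session_id=envelope.session_id,
    )


def window_count(n_samples: int, win: int, stride: int) -> int:
    """Number of full windows: floor((T - win)/stride) + 1, or 0 if T < win."""
    if n_samples < win:
        return 0
    return (n_samples - win) // stride + 1


def segment_windows(
    trial: SyncedTrial, win_ms: float = WINDOW_MS, stride_ms: float = STRIDE_MS
) -> List[WindowSample]:
    """Slide a win_ms window with stride_ms step over one trial.

    Targets are the arithmetic per-joint mean of the angles inside each
    window. A trial shorter than one window yields an empty list with a
    warning.
    """
    win = int(round(win_ms * trial.fs / 1000.0))
    stride = int(round(stride_ms * trial.fs / 1000.0))
    if win <= 0 or stride <= 0:
        raise ConfigurationError("window and stride must be positive")
    n = trial.n_samples
    if n < win:
        warnings.warn(
            f"trial {trial.trial_id} has {n} samples < one {win}-sample window; skipped"
        )
        return []
    samples = []
    for start in range(0, n - win + 1, stride):
        X = trial.envelope[start : start + win]
        y = trial.angles[start : start + win].mean(axis=0)
        samples.append(WindowSample(X=X, y=y, window_start_index=start, trial_id=trial.trial_id))
    return samples


def make_folds(
    trial_ids: Sequence[int], k: int = 5, mode: str = "initial", seed: int = 0
) -> FoldSplit:
    """Assign trials to k groups.

    ``initial``: seeded random partition into k near-equal groups (10 trials
    -> 5 groups of 2). ``second``: exactly k trials, the i-th trial becomes
    group i.
    """
    trial_ids = list(trial_ids)
    if len(set(trial_ids)) != len(trial_ids):
        raise ConfigurationError("trial ids must be unique")
    if mode == "initial":
        if len(trial_ids) < k:
            raise ConfigurationError(
                f"initial mode needs >= {k} trials, got {len(trial_ids)}"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(trial_ids))
        assignment = {}
        for pos, idx in enumerate(order):
            assignment[trial_ids[idx]] = pos % k
    elif mode == "second":
        if len(trial_ids) != k:
            raise ConfigurationError(
                f"second mode needs exactly {k} trials, got {len(trial_ids)}"
            )
        assignment = {t: i for i, t in enumerate(trial_ids)}
    else:
        raise ConfigurationError(f"unknown fold mode {mode!r}")
    return FoldSplit(k=k, group_of_trial=assignment, seed=seed, mode=mode)


@dataclass
class WindowDataset:
    """Stacked window samples as arrays, with trial provenance."""

    X: np.ndarray  # (n, 60, 32)
    y: np.ndarray  # (n, 3)
    trial: np.ndarray  # (n,)
    start: np.ndarray = None  # (n,) in-trial start index

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.trial.shape[0]:
            raise DataError("X, y and trial must have equal first dimension")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowDataset":
        return WindowDataset(
            X=self.X[mask], y=self.y[mask], trial=self.trial[mask],
            start=None if self.start is None else self.start[mask],
        )


def stack_windows(samples: List[WindowSample]) -> WindowDataset:
    if not samples:
        raise DataError("no window samples to stack")
    return WindowDataset(
        X=np.stack([s.X for s in samples]),
        y=np.stack([s.y for s in samples]),
        trial=np.asarray([s.trial_id for s in samples]),
        start=np.asarray([s.window_start_index for s in samples]),
    )


def build_dataset(trials: List[SyncedTrial], win_ms: float = WINDOW_MS,
                  stride_ms: float = STRIDE_MS) -> WindowDataset:
    """Segment every trial and stack all windows."""
    samples: List[WindowSample] = []
    for trial in trials:
        samples.extend(segment_windows(trial, win_ms, stride_ms))
    return stack_windows(samples)


def fold_masks(dataset: WindowDataset, folds: FoldSplit):
    """Yield (fold_index, train_mask, test_mask) over the window array."""
    group = np.asarray([folds.group_of_trial[int(t)] for t in dataset.trial])
    for g in range(folds.k):
        test = group == g
        yield g, ~test, test
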