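"""In-memory containers for recordings and derived signals.

All time series are (time, channel) float arrays with an explicit sampling
rate. Joint angles are signed degrees with the convention that wrist flexion,
pronation and hand grip are positive excursions and wrist extension,
supination and hand open are negative ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DataError

JOINT_NAMES = ("WFWE", "PS", "HGHO")
N_JOINTS = 3


def _validate_2d_finite(samples: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2:
        raise DataError(f"{what} must be 2-D (time x channels), got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{what} contains non-finite values")
    return arr


@dataclass
class EMGRecording:
    """Raw or processed multichannel sEMG trial, (time, n_channels) at fs Hz."""

    samples: np.ndarray
    fs: float
    channel_ids: np.ndarray = None
    trial_id: Optional[int] = None
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = _validate_2d_finite(self.samples, "EMG samples")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_ids is None:
            self.channel_ids = np.arange(1, self.samples.shape[1] + 1)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if len(self.channel_ids) != self.samples.shape[1]:
            raise DataError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.samples.shape[1]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, fs: Optional[float] = None) -> "EMGRecording":
        """Copy with new sample array; metadata preserved."""
        return replace(self, samples=samples, fs=self.fs if fs is None else fs)


@dataclass
class AngleRecording:
    """3-DOF joint-angle trial (time, 3) in signed degrees at fs Hz."""

    samples: np.ndarray
    fs: float
    joint_names: tuple = JOINT_NAMES
    trial_id: Optional[int] = None
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = _validate_2d_finite(self.samples, "angle samples")
        if self.samples.shape[1] != N_JOINTS:
            raise DataError(
                f"angle recording must have {N_JOINTS} joints, got {self.samples.shape[1]}"
            )
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EnvelopeSignal:
    """0-1 normalized envelope with the min/max stats used to scale it.

    ``stats_min``/``stats_max`` are per-channel and are kept so that a model
    trained on one session can re-apply the same scaling to a new session
    (direct testing); values outside the training range then fall outside
    [0, 1] and are deliberately not clipped.
    """

    samples: np.ndarray
    fs: float
    stats_min: np.ndarray = None
    stats_max: np.ndarray = None
    channel_ids: np.ndarray = None
    trial_id: Optional[int] = None
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = _validate_2d_finite(self.samples, "envelope samples")
        if self.channel_ids is None:
            self.channel_ids = np.arange(1, self.samples.shape[1] + 1)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]
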