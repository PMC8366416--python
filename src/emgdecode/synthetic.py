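"""Synthetic sEMG / joint-angle session generator.

Real recordings pair 32-channel forearm sEMG at 500 Hz with 3-DOF joint
angles at 120 Hz, collected as trials in which the participant cycles
through six motions from a neutral central position (CP): wrist
flexion/extension (WF/WE), pronation/supination (P/S) and hand
grip/open (HG/HO), each motion twice per trial, returning to CP between
excursions. This module emulates that structure:

* joint-angle trajectories are sequences of smooth raised-cosine
  CP -> peak -> CP pulses, positive for WF/P/HG and negative for WE/S/HO;
* each of the six motions drives a nonnegative "activation" (rectified
  normalized excursion of its joint in its direction);
* each EMG channel is band-limited Gaussian carrier noise amplitude
  modulated by a nonnegative spatial mixture of the six activations plus
  a noise floor, so the rectified-and-smoothed channel envelope tracks a
  known linear readout of the activations;
* a day-shift model (per-channel gain change, whole-column sleeve slip,
  noise-floor change) emulates why a model trained on one day degrades on
  the next.

The mixing matrix places each motion on a small contiguous patch of the
correct sleeve face (flexors drive WF/P/HG, extensors WE/S/HO), so the
channel sets a trained decoder should weight are known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

from .containers import AngleRecording, EMGRecording
from .errors import ConfigurationError, DataError
from .layout import DEFAULT_LAYOUT, N_CHANNELS, ChannelLayout

MOTIONS = ("WF", "WE", "P", "S", "HG", "HO")
JOINT_OF_MOTION = {"WF": 0, "WE": 0, "P": 1, "S": 1, "HG": 2, "HO": 2}
SIGN_OF_MOTION = {"WF": 1, "WE": -1, "P": 1, "S": -1, "HG": 1, "HO": -1}

DEFAULT_MOTION_ORDER = ("WF", "WE", "WF", "WE", "P", "S", "P", "S", "HG", "HO", "HG", "HO")
DEFAULT_PEAK_ANGLE = {"WF": 60.0, "WE": -60.0, "P": 80.0, "S": -80.0, "HG": 45.0, "HO": -45.0}

# Core channel patch per motion: flexor face for positive motions, extensor
# face for negative ones, patches disjoint so planted structure is
# recoverable from decoder weights.
DEFAULT_CORE_CHANNELS: Dict[str, Tuple[int, ...]] = {
    "WF": (13, 21, 29, 14),
    "WE": (17, 18, 25, 26),
    "P": (22, 23, 30, 31),
    "S": (1, 2, 9, 10),
    "HG": (7, 8, 15, 16),
    "HO": (3, 4, 11, 12),
}


@dataclass
class ParadigmSpec:
    """Trial structure: motion order, pulse shape and rates."""

    motion_order: Sequence[str] = DEFAULT_MOTION_ORDER
    hold_duration: float = 2.0
    rest_duration: float = 1.0
    peak_angle: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PEAK_ANGLE))
    n_trials: int = 10
    fs_angle: float = 120.0
    fs_emg: float = 500.0
    angle_jitter_deg: float = 0.2

    def __post_init__(self) -> None:
        for m in self.motion_order:
            if m not in MOTIONS:
                raise ConfigurationError(f"unknown motion label {m!r}")
        for m, peak in self.peak_angle.items():
            if peak != 0.0 and np.sign(peak) != SIGN_OF_MOTION[m]:
                raise ConfigurationError(
                    f"peak angle for {m} must be "
                    f"{'positive' if SIGN_OF_MOTION[m] > 0 else 'negative'}, got {peak}"
                )
        if self.hold_duration <= 0 or self.rest_duration <= 0:
            raise ConfigurationError("durations must be positive")
        if self.fs_angle <= 0 or self.fs_emg <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")

    @property
    def trial_duration(self) -> float:
        n = len(self.motion_order)
        return self.rest_duration + n * (self.hold_duration + self.rest_duration)


def default_mixing_matrix(
    layout: ChannelLayout = DEFAULT_LAYOUT,
    core_gain: float = 1.0,
    neighbor_gain: float = 0.3,
    core_channels: Optional[Dict[str, Tuple[int, ...]]] = None,
) -> np.ndarray:
    """(32, 6) nonnegative mixing matrix with planted channel patches.

    Core channels of each motion get ``core_gain``; channels grid-adjacent
    (4-neighborhood, same face) to a core channel get ``neighbor_gain``.
    """
    cores = DEFAULT_CORE_CHANNELS if core_channels is None else core_channels
    mix = np.zeros((N_CHANNELS, len(MOTIONS)))
    for j, motion in enumerate(MOTIONS):
        core = cores[motion]
        for ch in core:
            mix[ch - 1, j] = core_gain
        for ch in core:
            side, r, c = layout.position(ch)
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < 4 and 0 <= cc < 4:
                    nb = layout.channel_at(side, rr, cc)
                    if mix[nb - 1, j] == 0.0:
                        mix[nb - 1, j] = neighbor_gain
    return mix


@dataclass
class SynergySpec:
    """Spatial mixture and carrier-noise model for EMG synthesis."""

    mixing_matrix: np.ndarray = None
    spatial_smoothness: float = 0.3
    carrier_band: Tuple[float, float] = (20.0, 200.0)
    noise_floor: float = 0.05
    layout: ChannelLayout = DEFAULT_LAYOUT

    def __post_init__(self) -> None:
        if self.mixing_matrix is None:
            self.mixing_matrix = default_mixing_matrix(
                self.layout, neighbor_gain=self.spatial_smoothness
            )
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if self.mixing_matrix.shape != (N_CHANNELS, len(MOTIONS)):
            raise ConfigurationError(
                f"mixing matrix must be (32, 6), got {self.mixing_matrix.shape}"
            )
        if np.any(self.mixing_matrix < 0):
            raise ConfigurationError("mixing matrix must be nonnegative")
        if np.any(self.mixing_matrix.sum(axis=0) <= 0):
            raise ConfigurationError("every motion primitive must activate >= 1 channel")
        lo, hi = self.carrier_band
        if not (0 < lo < hi):
            raise ConfigurationError(f"invalid carrier band {self.carrier_band}")
        if self.noise_floor < 0:
            raise ConfigurationError("noise floor must be nonnegative")

    def active_channels(self, motion: str, threshold: float = 0.5) -> set:
        """Channels whose mixing gain for ``motion`` exceeds threshold*max."""
        col = self.mixing_matrix[:, MOTIONS.index(motion)]
        if col.max() == 0:
            return set()
        return {int(ch) for ch in np.flatnonzero(col >= threshold * col.max()) + 1}

    def driven_channels(self, joint: int) -> set:
        """All channels with nonzero mixing gain for either motion of a joint."""
        chans = set()
        for j, motion in enumerate(MOTIONS):
            if JOINT_OF_MOTION[motion] == joint:
                chans |= {int(c) for c in np.flatnonzero(self.mixing_matrix[:, j] > 0) + 1}
        return chans


@dataclass
class DayShiftSpec:
    """Between-day signal change: gains, sleeve slip, noise level."""

    channel_gain: np.ndarray = None
    layout_shift: int = 0
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_gain is None:
            self.channel_gain = np.ones(N_CHANNELS)
        self.channel_gain = np.asarray(self.channel_gain, dtype=float)
        if self.channel_gain.shape != (N_CHANNELS,):
            raise ConfigurationError("channel_gain must be a 32-vector")
        if np.any(self.channel_gain <= 0):
            raise ConfigurationError("channel gains must be positive")
        if abs(self.layout_shift) >= 4:
            raise ConfigurationError("|layout_shift| must be < 4")
        if self.noise_scale <= 0:
            raise ConfigurationError("noise_scale must be positive")

    @classmethod
    def random(cls, seed: int, gain_sigma: float = 0.4, layout_shift: int = 1,
               noise_scale: float = 1.5) -> "DayShiftSpec":
        """Typical new-day shift: lognormal gains, one-column slip, more noise."""
        rng = np.random.default_rng(seed)
        gains = np.exp(rng.normal(0.0, gain_sigma, size=N_CHANNELS))
        return cls(channel_gain=gains, layout_shift=layout_shift,
                   noise_scale=noise_scale, seed=seed)


@dataclass
class SyntheticSession:
    """Generated trials plus the ground truth that produced them."""

    trials: List[Tuple[EMGRecording, AngleRecording]]
    activations: List[np.ndarray]
    synergy: SynergySpec
    paradigm: ParadigmSpec
    session_id: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.trials:
            raise DataError("session must contain at least one trial")
        fs_set = {emg.fs for emg, _ in self.trials}
        nch = {emg.n_channels for emg, _ in self.trials}
        if len(fs_set) != 1 or len(nch) != 1:
            raise DataError("all trials must share sampling rate and channel count")
        for (_, ang), act in zip(self.trials, self.activations):
            if len(act) != ang.n_samples:
                raise DataError("ground-truth activation length must match angles")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def _raised_cosine_pulse(n: int) -> np.ndarray:
    """C1-smooth 0 -> 1 -> 0 pulse of n samples."""
    t = np.arange(n) / n
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def build_paradigm_angles(spec: ParadigmSpec, seed: int = 0) -> AngleRecording:
    """One trial of 3-DOF joint angles following the motion paradigm.

    The trial starts at CP, then for each motion in ``motion_order`` performs
    a raised-cosine excursion to that motion's peak angle and back, followed
    by a rest at CP. Non-active joints stay at 0 degrees up to a small
    smooth jitter.
    """
    fs = spec.fs_angle
    n_hold = int(round(spec.hold_duration * fs))
    n_rest = int(round(spec.rest_duration * fs))
    segments = [np.zeros((n_rest, 3))]
    for motion in spec.motion_order:
        pulse = np.zeros((n_hold, 3))
        pulse[:, JOINT_OF_MOTION[motion]] = spec.peak_angle.get(motion, 0.0) * _raised_cosine_pulse(n_hold)
        segments.append(pulse)
        segments.append(np.zeros((n_rest, 3)))
    angles = np.concatenate(segments, axis=0)
    if spec.angle_jitter_deg > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.normal(0.0, spec.angle_jitter_deg, size=angles.shape)
        # smooth the jitter so it looks like tracker drift, not white noise
        win = max(int(round(0.25 * fs)), 1)
        kernel = np.ones(win) / win
        jitter = np.apply_along_axis(lambda x: np.convolve(x, kernel, mode="same"), 0, jitter)
        angles = angles + jitter
    return AngleRecording(samples=angles, fs=fs)


def simulate_activations(angles: AngleRecording, spec: SynergySpec = None) -> np.ndarray:
    """(time, 6) nonnegative activation of each motion primitive.

    Each primitive's activation is the excursion of its joint in its
    direction, rectified and normalized by the trial's peak excursion in that
    direction, so activations live in [0, 1] and are 0 at CP.
    """
    arr = np.asarray(angles.samples, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("angles must be finite")
    acts = np.zeros((arr.shape[0], len(MOTIONS)))
    for j, motion in enumerate(MOTIONS):
        directional = SIGN_OF_MOTION[motion] * arr[:, JOINT_OF_MOTION[motion]]
        rectified = np.clip(directional, 0.0, None)
        peak = rectified.max()
        if peak > 0:
            acts[:, j] = rectified / peak
    return acts


def synthesize_emg(
    activations: np.ndarray,
    spec: SynergySpec,
    fs_emg: float,
    seed: int = 0,
    fs_act: float = 120.0,
) -> EMGRecording:
    """Amplitude-modulated band-limited noise per channel.

    The modulator for channel c is ``mixing_matrix[c] . activation +
    noise_floor``, linearly interpolated from the activation rate up to
    ``fs_emg``; the carrier is unit-variance Gaussian noise band-passed to
    ``carrier_band``. The rectified-and-lowpassed output therefore tracks the
    modulator.
    """
    acts = np.asarray(activations, dtype=float)
    if np.any(acts < 0):
        raise DataError("activations must be nonnegative")
    lo, hi = spec.carrier_band
    if hi >= fs_emg / 2:
        raise ConfigurationError(
            f"carrier band {spec.carrier_band} exceeds Nyquist for fs={fs_emg}"
        )
    n_act = acts.shape[0]
    n_emg = int(round(n_act * fs_emg / fs_act))
    t_act = np.arange(n_act) / fs_act
    t_emg = np.arange(n_emg) / fs_emg
    modulator = acts @ spec.mixing_matrix.T + spec.noise_floor  # (time, 32)
    mod_up = np.empty((n_emg, N_CHANNELS))
    for c in range(N_CHANNELS):
        mod_up[:, c] = np.interp(t_emg, t_act, modulator[:, c])
    rng = np.random.default_rng(seed)
    carrier = rng.standard_normal((n_emg, N_CHANNELS))
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs_emg, output="sos")
    carrier = signal.sosfilt(sos, carrier, axis=0)
    std = carrier.std(axis=0)
    std[std == 0] = 1.0
    carrier = carrier / std
    emg = carrier * mod_up
    return EMGRecording(samples=emg, fs=fs_emg)


def generate_session(
    paradigm: ParadigmSpec,
    synergy: SynergySpec = None,
    n_trials: Optional[int] = None,
    seed: int = 0,
    session_id: str = "synthetic",
) -> SyntheticSession:
    """Generate ``n_trials`` independent trials sharing one mixing matrix.

    Per-trial randomness is derived as ``seed + trial_index`` so sessions are
    reproducible and trials mutually independent.
    """
    if synergy is None:
        synergy = SynergySpec()
    n = paradigm.n_trials if n_trials is None else n_trials
    if n < 1:
        raise ConfigurationError("n_trials must be >= 1")
    trials = []
    activations = []
    for i in range(n):
        trial_seed = seed + i
        angles = build_paradigm_angles(paradigm, seed=trial_seed)
        angles.trial_id = i
        angles.session_id = session_id
        acts = simulate_activations(angles, synergy)
        emg = synthesize_emg(acts, synergy, paradigm.fs_emg, seed=trial_seed + 10_000,
                             fs_act=paradigm.fs_angle)
        emg.trial_id = i
        emg.session_id = session_id
        trials.append((emg, angles))
        activations.append(acts)
    return SyntheticSession(trials=trials, activations=activations,
                            synergy=synergy, paradigm=paradigm, session_id=session_id)


def apply_day_shift(session: SyntheticSession, shift: DayShiftSpec) -> SyntheticSession:
    """Re-map a session through a between-day signal change.

    Channels are re-sourced through a whole-column sleeve rotation, rescaled
    by per-channel gains, and extra carrier noise proportional to
    ``noise_floor * (noise_scale - 1)`` is added. Angle series are unchanged.
    An identity spec returns bitwise-identical EMG.
    """
    perm = session.synergy.layout.column_rotation_permutation(shift.layout_shift)
    identity_noise = shift.noise_scale == 1.0
    lo, hi = session.synergy.carrier_band
    rng = np.random.default_rng(shift.seed)
    new_trials = []
    for emg, angles in session.trials:
        samples = emg.samples[:, perm] * shift.channel_gain[None, :]
        if not identity_noise:
            extra = rng.standard_normal(samples.shape)
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=emg.fs, output="sos")
            extra = signal.sosfilt(sos, extra, axis=0)
            std = extra.std(axis=0)
            std[std == 0] = 1.0
            extra = extra / std
            samples = samples + extra * session.synergy.noise_floor * (shift.noise_scale - 1.0)
        new_trials.append((emg.with_samples(samples), angles))
    return SyntheticSession(
        trials=new_trials,
        activations=session.activations,
        synergy=session.synergy,
        paradigm=session.paradigm,
        session_id=session.session_id + "+dayshift",
    )
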