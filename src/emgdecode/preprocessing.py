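"""Raw sEMG -> normalized envelope pipeline.

Order of stages: rectify -> envelope_filter -> normalize_unit ->
resample_to_angle_rate. Every stage preserves channel count and ids; from
rectification onward all values are nonnegative.

The envelope (IEMG) filter is a causal second-order low-pass realized as a
difference of exponentials, h(t) = A (e^{-a t} - e^{-b t}), the classic
quasi-tension filter used to map rectified EMG to a muscle-activation-like
envelope. The default constants (A = 6.44, a = 10.80/s, b = 16.52/s) are a
configuration choice, exposed through :class:`FilterSpec`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import EMGRecording, EnvelopeSignal
from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

ANGLE_RATE_HZ = 120.0


@dataclass(frozen=True)
class FilterSpec:
    """Difference-of-exponentials low-pass h(t) = gain (e^{-a t} - e^{-b t})."""

    gain: float = 6.44
    rate_a: float = 10.80  # 1/s, slower pole
    rate_b: float = 16.52  # 1/s, faster pole

    def __post_init__(self) -> None:
        if self.rate_a <= 0 or self.rate_b <= 0:
            raise ConfigurationError("filter rates must be positive (stable poles)")
        if self.rate_a == self.rate_b:
            raise ConfigurationError("filter rates must differ (h would be zero)")

    def dc_gain(self, fs: float) -> float:
        """Closed-form DC gain of the discretized filter at sampling rate fs."""
        T = 1.0 / fs
        ga = 1.0 / (1.0 - np.exp(-self.rate_a * T))
        gb = 1.0 / (1.0 - np.exp(-self.rate_b * T))
        return self.gain * T * (ga - gb)


def rectify(raw: EMGRecording) -> EMGRecording:
    """Elementwise absolute value; metadata preserved."""
    return raw.with_samples(np.abs(raw.samples))


def envelope_filter(rectified: EMGRecording, spec: FilterSpec = FilterSpec()) -> EMGRecording:
    """Causal per-channel low-pass of rectified EMG (IEMG envelope).

    Implemented as the difference of two one-pole IIR filters, the exact
    discretization of h(t) = gain (e^{-a t} - e^{-b t}) sampled at fs.
    Output is nonnegative for nonnegative input since h(t) >= 0 when a < b
    (or the symmetric case) — with the default rates a < b, e^{-a t} >=
    e^{-b t} for all t >= 0.
    """
    if np.any(rectified.samples < 0):
        raise DataError("envelope_filter expects rectified (nonnegative) input")
    fs = rectified.fs
    T = 1.0 / fs
    x = rectified.samples
    # one-pole sections y[n] = e^{-rT} y[n-1] + T x[n]
    ya = sps.lfilter([T], [1.0, -np.exp(-spec.rate_a * T)], x, axis=0)
    yb = sps.lfilter([T], [1.0, -np.exp(-spec.rate_b * T)], x, axis=0)
    sign = 1.0 if spec.rate_a < spec.rate_b else -1.0
    out = sign * spec.gain * (ya - yb)
    return rectified.with_samples(out)


def normalize_unit(env: EMGRecording, stats_source: EMGRecording = None) -> EnvelopeSignal:
    """Per-channel min-max scaling to [0, 1].

    Stats come from ``stats_source`` (default: ``env`` itself) and are stored
    on the result so a new session can be scaled with the training session's
    range. Data outside the source range maps outside [0, 1]; no clipping is
    applied, since out-of-range values are exactly the signal a day-shift
    detector needs to see.

    A constant channel in the source (max == min) maps to 0 with a warning.
    """
    src = env if stats_source is None else stats_source
    cmin = src.samples.min(axis=0)
    cmax = src.samples.max(axis=0)
    span = cmax - cmin
    constant = span <= 0
    if np.any(constant):
        bad = env.channel_ids[constant].tolist()
        warnings.warn(f"constant channel(s) {bad} mapped to 0 during normalization")
        log.warning("constant channel(s) %s mapped to 0 during normalization", bad)
    safe_span = np.where(constant, 1.0, span)
    scaled = (env.samples - cmin) / safe_span
    scaled[:, constant] = 0.0
    return EnvelopeSignal(
        samples=scaled,
        fs=env.fs,
        stats_min=cmin,
        stats_max=cmax,
        channel_ids=env.channel_ids,
        trial_id=env.trial_id,
        session_id=env.session_id,
    )


def apply_stats(env: EMGRecording, stats_min: np.ndarray, stats_max: np.ndarray) -> EnvelopeSignal:
    """Scale a recording with previously stored min/max stats (no clipping)."""
    span = np.asarray(stats_max, dtype=float) - np.asarray(stats_min, dtype=float)
    constant = span <= 0
    safe_span = np.where(constant, 1.0, span)
    scaled = (env.samples - stats_min) / safe_span
    scaled[:, constant] = 0.0
    return EnvelopeSignal(
        samples=scaled, fs=env.fs,
        stats_min=np.asarray(stats_min, float), stats_max=np.asarray(stats_max, float),
        channel_ids=env.channel_ids, trial_id=env.trial_id, session_id=env.session_id,
    )


def resample_to_angle_rate(env, fs_out: float = ANGLE_RATE_HZ):
    """Polyphase rational resampling down to the joint-angle rate.

    500 -> 120 Hz is the 6:25 rational ratio; output length is
    round(n_in * fs_out / fs_in). Small negative ringing introduced by the
    polyphase FIR on an otherwise nonnegative envelope is clipped at 0.
    Accepts and returns either :class:`EMGRecording` or
    :class:`EnvelopeSignal`.
    """
    if fs_out <= 0:
        raise ConfigurationError(f"target rate must be positive, got {fs_out}")
    if fs_out >= env.fs:
        raise ConfigurationError(
            f"resample_to_angle_rate downsamples only (fs_in={env.fs}, fs_out={fs_out})"
        )
    ratio = Fraction(fs_out / env.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(env.samples, up, down, axis=0)
    target_len = int(round(env.n_samples * fs_out / env.fs))
    out = out[:target_len]
    out = np.clip(out, 0.0, None) if np.all(env.samples >= 0) else out
    if isinstance(env, EnvelopeSignal):
        return EnvelopeSignal(samples=out, fs=fs_out, stats_min=env.stats_min,
                              stats_max=env.stats_max, channel_ids=env.channel_ids,
                              trial_id=env.trial_id, session_id=env.session_id)
    return env.with_samples(out, fs=fs_out)


def preprocess_recording(
    raw: EMGRecording,
    spec: FilterSpec = FilterSpec(),
    stats: tuple = None,
    fs_out: float = ANGLE_RATE_HZ,
) -> EnvelopeSignal:
    """Full pipeline: rectify, envelope-filter, normalize, resample.

    ``stats`` is an optional (min, max) pair from a previous session; when
    omitted the recording is normalized with its own range and the stats are
    stored on the result.
    """
    env = envelope_filter(rectify(raw), spec)
    if stats is None:
        norm = normalize_unit(env)
    else:
        norm = apply_stats(env, stats[0], stats[1])
    return resample_to_angle_rate(norm, fs_out)
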