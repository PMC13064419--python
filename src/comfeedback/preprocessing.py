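"""EMG and CoM-kinematics preprocessing.

Raw EMG at 1000 Hz is turned into a non-negative envelope by a zero-phase
chain — high-pass 35 Hz sixth-order Butterworth, mean subtraction, half-wave
rectification, low-pass 40 Hz — then epoched to [-200, 1200) ms around
perturbation onset, normalized to a shared maximum of 1 across all of a
participant's trials, and averaged within each condition after dropping
stepping trials (a condition with fewer than three non-stepping trials is
excluded from fitting).

CoM velocity comes from Savitzky-Golay smoothed displacement, CoM
acceleration from ground reaction force divided by body mass; 100 Hz
kinematics are linearly interpolated onto the 1000 Hz EMG grid before
fitting.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.signal import savgol_filter

from .series import ComKinematics, UniformSeries

__all__ = [
    "EPOCH_WINDOW",
    "ConditionAverage",
    "ExcludedCondition",
    "process_emg_trial",
    "epoch",
    "normalize_participant",
    "average_condition",
    "com_velocity",
    "com_acceleration",
    "align_kinematics",
    "peak_excursion",
]

EPOCH_WINDOW = (-0.2, 1.2)  # s, half-open
MIN_TRIALS = 3


@dataclass(frozen=True)
class ConditionAverage:
    """Across-trial mean of one participant x direction x magnitude cell."""

    emg: UniformSeries  # normalized envelope, analysis units
    com: ComKinematics
    n_trials: int
    participant_id: str = ""
    direction: str = ""
    magnitude: str = ""

    def __post_init__(self) -> None:
        if self.n_trials < MIN_TRIALS:
            raise ValueError(f"condition averages require >= {MIN_TRIALS} trials")
        if np.any(self.emg.values < 0):
            raise ValueError("averaged envelope must be non-negative")


@dataclass(frozen=True)
class ExcludedCondition:
    """Marker for a condition dropped by the >=3 non-stepping-trials rule."""

    participant_id: str
    direction: str
    magnitude: str
    n_nonstepped: int
    reason: str = "fewer than 3 non-stepping trials"


def process_emg_trial(
    raw: UniformSeries,
    highpass_hz: float = 35.0,
    lowpass_hz: float = 40.0,
    order: int = 6,
    lowpass_order: int = 6,
    padtype: str = "even",
) -> UniformSeries:
    """Raw EMG -> rectified, smoothed envelope.

    Chain (in order): zero-phase high-pass Butterworth at 35 Hz; subtraction
    of the whole-trial mean; half-wave rectification at 0; zero-phase
    low-pass Butterworth at 40 Hz. Zero-phase means forward-backward
    application (filtfilt) with reflective padding of 3x the filter order.
    The final trace is clipped at 0 (the low-pass can undershoot slightly),
    so the output is non-negative.
    """
    x = raw.values
    padlen = 3 * max(order, lowpass_order)
    if x.size <= 3 * padlen:
        raise ValueError(
            f"series of {x.size} samples too short for stable zero-phase filtering "
            f"(needs > {3 * padlen})"
        )
    b, a = signal.butter(order, highpass_hz, btype="high", fs=raw.rate)
    x = signal.filtfilt(b, a, x, padtype=padtype, padlen=padlen)
    x = x - x.mean()
    x = np.maximum(0.0, x)
    b, a = signal.butter(lowpass_order, lowpass_hz, btype="low", fs=raw.rate)
    x = signal.filtfilt(b, a, x, padtype=padtype, padlen=padlen)
    return raw.with_values(np.maximum(0.0, x))


def epoch(sig: UniformSeries, window: tuple[float, float] = EPOCH_WINDOW) -> UniformSeries:
    """Samples with window[0] <= t < window[1]; onset stays at t = 0."""
    t_start, t_stop = window
    eps = 1e-9
    if sig.t0 > t_start + eps or sig.t_end < t_stop - 1.0 / sig.rate - eps:
        raise ValueError(
            f"signal extent [{sig.t0:.3f}, {sig.t_end:.3f}] s does not cover the "
            f"epoch window [{t_start:.3f}, {t_stop:.3f}) s"
        )
    return sig.slice_time(t_start, t_stop)


def epoch_kinematics(com: ComKinematics, window: tuple[float, float] = EPOCH_WINDOW) -> ComKinematics:
    return ComKinematics(epoch(com.d, window), epoch(com.v, window), epoch(com.a, window))


def normalize_participant(trials: Sequence[UniformSeries]) -> list[UniformSeries]:
    """Scale all of one participant's envelopes by one shared factor so the
    global maximum across trials is exactly 1."""
    if not trials:
        raise ValueError("no trials to normalize")
    peak = max(float(np.max(tr.values)) for tr in trials)
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero trial set")
    return [tr.with_values(tr.values / peak) for tr in trials]


def average_condition(
    emgs: Sequence[UniformSeries],
    coms: Sequence[ComKinematics],
    stepped: Sequence[bool],
    participant_id: str = "",
    direction: str = "",
    magnitude: str = "",
) -> ConditionAverage | ExcludedCondition:
    """Pointwise mean over non-stepping trials of one condition.

    Stepping trials change the task goal and are dropped; if fewer than
    three non-stepping trials remain the condition is excluded (marker
    returned, not an error).
    """
    if not (len(emgs) == len(coms) == len(stepped)):
        raise ValueError("emgs, coms and stepped must have equal length")
    keep = [i for i, s in enumerate(stepped) if not s]
    if len(keep) < MIN_TRIALS:
        return ExcludedCondition(participant_id, direction, magnitude, len(keep))
    ref_e, ref_c = emgs[keep[0]], coms[keep[0]]
    for i in keep[1:]:
        if not emgs[i].same_grid(ref_e) or not coms[i].d.same_grid(ref_c.d):
            raise ValueError("all trials of a condition must share a common grid")
    mean_e = np.mean([emgs[i].values for i in keep], axis=0)
    mk = lambda ch: ref_c.d.with_values(
        np.mean([getattr(coms[i], ch).values for i in keep], axis=0)
    )
    com = ComKinematics(
        mk("d"),
        ref_c.v.with_values(np.mean([coms[i].v.values for i in keep], axis=0)),
        ref_c.a.with_values(np.mean([coms[i].a.values for i in keep], axis=0)),
    )
    return ConditionAverage(
        ref_e.with_values(mean_e), com, len(keep), participant_id, direction, magnitude
    )


def com_velocity(d: UniformSeries, window: int = 49, polyorder: int = 3) -> UniformSeries:
    """CoM velocity: Savitzky-Golay smoothing (third order, 49-sample window
    — the nearest odd width to the nominal 48) followed by central-difference
    differentiation."""
    if len(d) <= window:
        raise ValueError(f"series of {len(d)} samples shorter than SG window {window}")
    smooth = savgol_filter(d.values, window_length=window, polyorder=polyorder)
    vel = np.gradient(smooth, 1.0 / d.rate)
    return d.with_values(vel)


def com_acceleration(force: UniformSeries, mass: float) -> UniformSeries:
    """CoM acceleration from ground reaction force: force / mass."""
    if mass <= 0:
        raise ValueError("mass must be positive")
    return force.with_values(force.values / mass)


def align_kinematics(com: ComKinematics, target: UniformSeries) -> ComKinematics:
    """Interpolate d, v, a linearly onto the grid of `target` (the EMG).

    Channels already on the target grid are passed through; extrapolation is
    refused.
    """
    t = target.t

    def onto(ch: UniformSeries) -> UniformSeries:
        if ch.same_grid(target):
            return ch
        return UniformSeries(ch.interp(t), target.t0, target.rate)

    return ComKinematics(onto(com.d), onto(com.v), onto(com.a))


def peak_excursion(d: UniformSeries) -> float:
    """Maximum |CoM displacement| relative to the base of support over t >= 0."""
    post = d.values[d.t >= 0.0]
    if post.size == 0:
        raise ValueError("no post-onset samples")
    return float(np.max(np.abs(post)))
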