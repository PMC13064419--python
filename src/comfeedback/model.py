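"""Delayed CoM-feedback forward model.

Each feedback loop weighs the CoM kinematic error signals — displacement d,
velocity v, acceleration a relative to the base of support — by independent
gains, applies a common neural transmission/processing delay, and half-wave
rectifies the sum (net drive to motor pools is non-negative):

    s(t) = max(0, sigma * (k_d * d(t - lam) + k_v * v(t - lam) + k_a * a(t - lam)))

with sigma = +1 for predictors that stretch the analyzed muscle and -1 for
predictors that shorten it. Muscle activity is reconstructed as the linear sum
of two such loops:

* agonist:     a short-latency loop (LLR1, brainstem-attributed) plus a
  longer-latency loop (LLR2, cortically attributed), both stretch-signed;
* antagonist:  a stabilizing loop driven by kinematics that stretch the
  antagonist plus a destabilizing loop driven by kinematics that shorten it.

Kinematics passed to these functions are expressed in the analyzed muscle's
stretch frame: positive values stretch that muscle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .series import ComKinematics, UniformSeries

__all__ = [
    "LoopParams",
    "DualLoopModel",
    "Reconstruction",
    "rectify",
    "loop_output",
    "reconstruct",
    "decompose_destabilizing",
]

MAX_DELAY_S = 0.3
#: How far a delayed lookup may reach before the first sample by holding the
#: earliest value (quiet stance precedes the epoch, so the held head is the
#: resting state). Longer shortfalls are an error, not padded.
HOLD_EXTENSION_S = 0.1

SignMode = Literal["stretch", "shorten"]


@dataclass(frozen=True)
class LoopParams:
    """One feedback loop: three gains, one delay, and its sign convention.

    Gains are in normalized-EMG units per m, per m/s and per m/s^2; the delay
    is in seconds and is shared by all three predictors.
    """

    k_d: float
    k_v: float
    k_a: float
    delay: float
    sign_mode: SignMode = "stretch"

    def __post_init__(self) -> None:
        if min(self.k_d, self.k_v, self.k_a) < 0:
            raise ValueError("gains must be non-negative")
        if not 0.0 <= self.delay <= MAX_DELAY_S:
            raise ValueError(f"delay must lie in [0, {MAX_DELAY_S}] s, got {self.delay}")
        if self.sign_mode not in ("stretch", "shorten"):
            raise ValueError(f"unknown sign_mode {self.sign_mode!r}")

    @property
    def gains(self) -> np.ndarray:
        return np.array([self.k_d, self.k_v, self.k_a])


@dataclass(frozen=True)
class DualLoopModel:
    """Two summed feedback loops reconstructing one muscle.

    kind='agonist': both loops stretch-signed, loop1 (LLR1) earlier than
    loop2 (LLR2). kind='antagonist': loop1 stabilizing (stretch), loop2
    destabilizing (shorten).
    """

    loop1: LoopParams
    loop2: LoopParams
    kind: Literal["agonist", "antagonist"]

    def __post_init__(self) -> None:
        if self.kind == "agonist":
            if self.loop1.sign_mode != "stretch" or self.loop2.sign_mode != "stretch":
                raise ValueError("agonist model requires two stretch-signed loops")
            if not self.loop1.delay < self.loop2.delay:
                raise ValueError("agonist model requires loop1.delay < loop2.delay")
        elif self.kind == "antagonist":
            if self.loop1.sign_mode != "stretch":
                raise ValueError("antagonist loop1 (stabilizing) must be stretch-signed")
            if self.loop2.sign_mode != "shorten":
                raise ValueError("antagonist loop2 (destabilizing) must be shorten-signed")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def gains(self) -> np.ndarray:
        """All six gains, loop1 then loop2 (penalized by the fit cost)."""
        return np.concatenate([self.loop1.gains, self.loop2.gains])


@dataclass(frozen=True)
class Reconstruction:
    """Total reconstructed muscle activity and its per-loop traces."""

    total: UniformSeries
    loop1: UniformSeries
    loop2: UniformSeries
    kind: Literal["agonist", "antagonist"]


def rectify(x: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Half-wave rectification: elementwise max(threshold, x)."""
    return np.maximum(threshold, np.asarray(x, dtype=float))


def _delayed(com: ComKinematics, delay: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kinematic channels evaluated at t - delay on the com grid.

    Fractional-sample delays are resolved by linear interpolation; delayed
    samples are read from real pre-onset data, never zero-padded. Lookups
    reaching at most HOLD_EXTENSION_S before the first sample hold the
    earliest value (the quiet-stance rest state); anything earlier is an
    error.
    """
    t_lag = com.t - delay
    # Post-onset output (t >= 0) must resolve from the pre-onset history;
    # the history shortfall at onset is delay - (0 - t0).
    shortfall = delay + com.t0
    if shortfall > HOLD_EXTENSION_S + 0.5e-6 / com.rate:
        raise ValueError(
            f"delay {delay:.4f} s exceeds the available pre-onset history "
            f"(series starts at {com.t0:.4f} s; at most {HOLD_EXTENSION_S} s "
            f"of quiet-stance hold is allowed)"
        )
    t = com.t
    return (
        np.interp(t_lag, t, com.d.values),
        np.interp(t_lag, t, com.v.values),
        np.interp(t_lag, t, com.a.values),
    )


def loop_output(com: ComKinematics, p: LoopParams) -> UniformSeries:
    """Rectified output of a single delayed feedback loop on the com grid."""
    d, v, a = _delayed(com, p.delay)
    sigma = 1.0 if p.sign_mode == "stretch" else -1.0
    s = sigma * (p.k_d * d + p.k_v * v + p.k_a * a)
    return UniformSeries(rectify(s), com.t0, com.rate)


def reconstruct(com: ComKinematics, m: DualLoopModel) -> Reconstruction:
    """Sum of both rectified loop outputs, with per-loop traces retained."""
    e1 = loop_output(com, m.loop1)
    e2 = loop_output(com, m.loop2)
    return Reconstruction(e1.with_values(e1.values + e2.values), e1, e2, m.kind)


def decompose_destabilizing(
    com: ComKinematics, p: LoopParams
) -> tuple[UniformSeries, UniformSeries]:
    """Split a destabilizing (shorten-signed) loop into its CoM-acceleration
    component and its combined velocity+displacement component.

    Each part is rectified individually, so the two components need not sum
    to the jointly rectified loop output; the residual is an interaction.
    """
    if p.sign_mode != "shorten":
        raise ValueError("destabilizing decomposition requires sign_mode='shorten'")
    d, v, a = _delayed(com, p.delay)
    acc = UniformSeries(rectify(-p.k_a * a), com.t0, com.rate)
    veldisp = UniformSeries(rectify(-p.k_v * v - p.k_d * d), com.t0, com.rate)
    return acc, veldisp
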