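"""Uniformly sampled time series and aligned CoM kinematics containers.

Time is always expressed in seconds relative to perturbation onset (t = 0).
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["UniformSeries", "ComKinematics"]


@dataclass(frozen=True)
class UniformSeries:
    """One uniformly sampled signal.

    Parameters
    ----------
    values : ndarray
        Sample values.
    t0 : float
        Time of the first sample, seconds relative to perturbation onset.
    rate : float
        Sampling rate in Hz.
    """

    values: np.ndarray
    t0: float
    rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if v.ndim != 1 or v.size < 2:
            raise ValueError("values must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def t_end(self) -> float:
        """Time of the last sample."""
        return self.t0 + (self.values.size - 1) / self.rate

    def same_grid(self, other: "UniformSeries", rtol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.isclose(self.t0, other.t0, rtol=0, atol=rtol)
            and np.isclose(self.rate, other.rate, rtol=rtol)
        )

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def interp(self, times: np.ndarray) -> np.ndarray:
        """Linear interpolation at arbitrary times; refuses to extrapolate."""
        times = np.asarray(times, dtype=float)
        eps = 0.5 / self.rate * 1e-6
        if times.min() < self.t0 - eps or times.max() > self.t_end + eps:
            raise ValueError(
                f"requested times [{times.min():.4f}, {times.max():.4f}] s fall outside "
                f"the series extent [{self.t0:.4f}, {self.t_end:.4f}] s"
            )
        return np.interp(times, self.t, self.values)

    def slice_time(self, t_start: float, t_stop: float) -> "UniformSeries":
        """Samples with t_start <= t < t_stop (half-open)."""
        eps = 0.5 / self.rate * 1e-6
        if t_start < self.t0 - eps or t_stop > self.t_end + self.dt + eps:
            raise ValueError("slice window not covered by series")
        i0 = int(np.ceil((t_start - self.t0) * self.rate - 1e-9))
        i1 = int(np.ceil((t_stop - self.t0) * self.rate - 1e-9))
        if i1 - i0 < 2:
            raise ValueError("slice window too short")
        return UniformSeries(self.values[i0:i1], self.t0 + i0 / self.rate, self.rate)


@dataclass(frozen=True)
class ComKinematics:
    """Aligned CoM displacement / velocity / acceleration relative to the base
    of support — the model predictors d, v, a.

    After alignment all three channels share t0, rate and length.
    """

    d: UniformSeries
    v: UniformSeries
    a: UniformSeries

    def __post_init__(self) -> None:
        if not (self.d.same_grid(self.v) and self.d.same_grid(self.a)):
            raise ValueError("d, v, a must share a common grid")

    @property
    def t(self) -> np.ndarray:
        return self.d.t

    @property
    def rate(self) -> float:
        return self.d.rate

    @property
    def t0(self) -> float:
        return self.d.t0

    def scaled(self, c: float) -> "ComKinematics":
        return ComKinematics(
            self.d.with_values(c * self.d.values),
            self.v.with_values(c * self.v.values),
            self.a.with_values(c * self.a.values),
        )

    def __neg__(self) -> "ComKinematics":
        return self.scaled(-1.0)

    def slice_time(self, t_start: float, t_stop: float) -> "ComKinematics":
        return ComKinematics(
            self.d.slice_time(t_start, t_stop),
            self.v.slice_time(t_start, t_stop),
            self.a.slice_time(t_start, t_stop),
        )
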