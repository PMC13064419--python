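"""Fit-quality metrics and component quantification.

R^2 is the coefficient of determination of the ordinary least-squares
regression recorded ~ intercept + reconstructed. VAF is 100 times the
squared uncentered Pearson correlation, (sum x*y)^2 / (sum x^2 * sum y^2).
Model components are quantified as trapezoidal integrals over the fit
window (normalized-EMG * seconds); loop latencies are tabulated in ms.
"""
from __future__ import annotations

from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .series import UniformSeries

if TYPE_CHECKING:  # pragma: no cover
    from .fitting import FitResult

__all__ = ["r_squared", "vaf", "integrate_component", "latency_table"]


def r_squared(recorded: UniformSeries, reconstructed: UniformSeries) -> float:
    """Coefficient of determination of recorded regressed on reconstructed
    (with intercept); equals the squared Pearson correlation."""
    if not recorded.same_grid(reconstructed):
        raise ValueError("traces must share a grid")
    x, y = reconstructed.values, recorded.values
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("reconstructed trace has zero variance")
    syy = np.sum((y - y.mean()) ** 2)
    if syy == 0:
        return 0.0
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    return float(sxy * sxy / (sxx * syy))


def vaf(recorded: UniformSeries, reconstructed: UniformSeries) -> float:
    """Variability accounted for, percent: 100 * (sum x*y)^2 / (sum x^2 sum y^2)."""
    if not recorded.same_grid(reconstructed):
        raise ValueError("traces must share a grid")
    x, y = recorded.values, reconstructed.values
    ex, ey = np.sum(x * x), np.sum(y * y)
    if ex == 0 or ey == 0:
        raise ValueError("VAF undefined for a zero-energy trace")
    return float(100.0 * np.sum(x * y) ** 2 / (ex * ey))


def integrate_component(trace: UniformSeries, window: tuple[float, float]) -> float:
    """Trapezoidal integral of a trace over [window[0], window[1]]."""
    t_start, t_stop = window
    eps = 1e-9
    if trace.t0 > t_start + eps or trace.t_end < t_stop - eps:
        raise ValueError("trace does not cover the integration window")
    t = trace.t
    m = (t >= t_start - eps) & (t <= t_stop + eps)
    return float(np.trapezoid(trace.values[m], t[m]))


def latency_table(results: Sequence["FitResult"]) -> pd.DataFrame:
    """Long-format table of fitted loop delays in milliseconds.

    One row per fit x loop; the stabilizing loop's latency is additionally
    reported relative to deceleration onset (the antagonist-stretch
    kinematics begin at platform deceleration, so the two coincide in value
    but differ in reference event).
    """
    loop_names = {"agonist": ("llr1", "llr2"), "antagonist": ("stabilizing", "destabilizing")}
    rows = []
    for r in results:
        names = loop_names[r.model.kind]
        for name, loop in zip(names, (r.model.loop1, r.model.loop2)):
            rows.append(
                {
                    "participant": r.participant_id,
                    "muscle": r.model.kind,
                    "direction": r.direction,
                    "magnitude": r.magnitude,
                    "loop": name,
                    "latency_ms": 1e3 * loop.delay,
                    "latency_re_decel_ms": 1e3 * loop.delay if name == "stabilizing" else np.nan,
                }
            )
    cols = [
        "participant", "muscle", "direction", "magnitude",
        "loop", "latency_ms", "latency_re_decel_ms",
    ]
    return pd.DataFrame(rows, columns=cols)
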