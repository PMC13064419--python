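"""Synthetic balance-perturbation cohort generator.

Emulates a support-surface translation protocol: ramp-and-hold perturbations
at three magnitudes x two directions, eight trials per condition (48 trials
per participant), with CoM kinematic responses and muscle-envelope EMG
produced by the package's own delayed-feedback forward model plus noise.
Every trial carries known ground-truth loop parameters so downstream stages
(preprocessing, fitting, metrics, summaries) are verifiable by parameter
recovery.

Conventions
-----------
* The lab frame is signed by perturbation direction: a forward platform
  translation has positive platform acceleration.
* The analysis frame re-expresses kinematics so that positive values stretch
  the analyzed agonist muscle (TA for forward, MG for backward translations);
  the antagonist's stretch frame is its negation.
* EMG traces are forward-model envelopes in normalized units (baseline +
  reconstruction + 40 Hz-smoothed noise, half-wave rectified), not raw
  interference EMG.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .model import DualLoopModel, LoopParams, reconstruct, rectify
from .series import ComKinematics, UniformSeries

__all__ = [
    "G",
    "MAGNITUDE_SPECS",
    "PerturbationSpec",
    "BodyModel",
    "GroundTruth",
    "SyntheticTrial",
    "make_platform_profile",
    "simulate_com_kinematics",
    "to_agonist_frame",
    "generate_emg",
    "default_ground_truth",
    "draw_ground_truth",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

G = 9.81  # m/s^2 per g

Direction = Literal["forward", "backward"]
Magnitude = Literal["small", "medium", "large"]
Group = Literal["OA", "PD"]


@dataclass(frozen=True)
class PerturbationSpec:
    """Ramp-and-hold support-surface translation.

    peak_acceleration is in m/s^2; use `from_g` for g-multiples. The platform
    acceleration is a raised-cosine pulse reaching peak_acceleration, followed
    accel_to_decel_interval later by the opposite pulse; pulse width is solved
    so the constant-velocity plateau equals peak_velocity, and the total
    displacement is emergent.
    """

    direction: Direction
    peak_displacement: float  # m (protocol label; emergent in the profile)
    peak_velocity: float  # m/s
    peak_acceleration: float  # m/s^2
    accel_to_decel_interval: float = 0.5  # s
    sample_rate: float = 1000.0  # Hz

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        for name in ("peak_displacement", "peak_velocity", "peak_acceleration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.accel_to_decel_interval <= 0:
            raise ValueError("accel_to_decel_interval must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @classmethod
    def from_g(
        cls,
        direction: Direction,
        peak_displacement: float,
        peak_velocity: float,
        peak_acceleration_g: float,
        **kw,
    ) -> "PerturbationSpec":
        return cls(direction, peak_displacement, peak_velocity, peak_acceleration_g * G, **kw)

    @property
    def pulse_width(self) -> float:
        """Raised-cosine pulse duration satisfying both peak v and peak a."""
        return 2.0 * self.peak_velocity / self.peak_acceleration


#: Protocol magnitudes: the small triple is fixed (5.1 cm, 11.1 cm/s, 0.15 g);
#: medium/large use midpoints of the height-adjusted ranges
#: (7-7.4 cm, 15.2-16.1 cm/s, 0.21-0.22 g; 8.9-9.8 cm, 19.1-21.0 cm/s, 0.26-0.29 g).
MAGNITUDE_SPECS: dict[str, tuple[float, float, float]] = {
    "small": (0.051, 0.111, 0.15),
    "medium": (0.072, 0.1565, 0.215),
    "large": (0.0935, 0.2005, 0.275),
}


def magnitude_spec(magnitude: Magnitude, direction: Direction = "forward") -> PerturbationSpec:
    d, v, a_g = MAGNITUDE_SPECS[magnitude]
    return PerturbationSpec.from_g(direction, d, v, a_g)


@dataclass(frozen=True)
class BodyModel:
    """Linear damped second-order stand-in for stance dynamics.

    CoM displacement relative to the base of support responds to
    -coupling_gain * platform acceleration. Defaults put the CoM excursion
    peak 200-400 ms after perturbation onset, giving the three predictors
    distinct time courses (what gain identifiability needs), without claiming
    biomechanical fidelity.
    """

    natural_frequency: float = 3.0  # rad/s
    damping_ratio: float = 1.2
    coupling_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.natural_frequency <= 0:
            raise ValueError("natural_frequency must be positive")
        if self.damping_ratio < 0:
            raise ValueError("damping_ratio must be non-negative")


def make_platform_profile(
    spec: PerturbationSpec, t_start: float = -0.3, t_stop: float = 1.5
) -> ComKinematics:
    """Platform acceleration/velocity/displacement on a uniform grid.

    Acceleration is a raised-cosine pulse of width 2*peak_velocity/peak_acceleration
    reaching +-peak_acceleration, followed accel_to_decel_interval later by the
    opposite pulse; velocity and displacement are its running trapezoidal
    integrals, so terminal velocity is 0 and the channels are mutually
    consistent by construction.
    """
    T = spec.pulse_width
    if T > spec.accel_to_decel_interval:
        raise ValueError(
            f"infeasible spec: pulse width {T:.3f} s exceeds the "
            f"{spec.accel_to_decel_interval:.3f} s accel-to-decel interval"
        )
    if t_stop < spec.accel_to_decel_interval + T:
        raise ValueError("t_stop must cover the deceleration pulse")
    rate = spec.sample_rate
    n = int(round((t_stop - t_start) * rate)) + 1
    t = t_start + np.arange(n) / rate
    a = np.zeros(n)
    pulse = lambda tau: 0.5 * spec.peak_acceleration * (1.0 - np.cos(2.0 * np.pi * tau / T))
    m = (t >= 0.0) & (t <= T)
    a[m] += pulse(t[m])
    m = (t >= spec.accel_to_decel_interval) & (t <= spec.accel_to_decel_interval + T)
    a[m] -= pulse(t[m] - spec.accel_to_decel_interval)
    if spec.direction == "backward":
        a = -a
    v = cumulative_trapezoid(a, dx=1.0 / rate, initial=0.0)
    d = cumulative_trapezoid(v, dx=1.0 / rate, initial=0.0)
    mk = lambda x: UniformSeries(x, t_start, rate)
    return ComKinematics(mk(d), mk(v), mk(a))


def simulate_com_kinematics(
    platform: ComKinematics, body: BodyModel, guard_bound: float = 10.0
) -> ComKinematics:
    """CoM response (lab frame) to a platform profile.

    Integrates d'' + 2*zeta*omega*d' + omega^2*d = -coupling_gain * a_platform
    on the platform grid; acceleration is evaluated from the state equation so
    v = d' and a = v' hold exactly at the solver grid.
    """
    w, z, g = body.natural_frequency, body.damping_ratio, body.coupling_gain
    sys = signal.StateSpace(
        [[0.0, 1.0], [-w * w, -2.0 * z * w]], [[0.0], [-g]], np.eye(2), [[0.0], [0.0]]
    )
    t = platform.t
    _, y, _ = signal.lsim(sys, platform.a.values, t - t[0])
    d, v = y[:, 0], y[:, 1]
    a = -w * w * d - 2.0 * z * w * v - g * platform.a.values
    if not np.all(np.isfinite(d)) or np.max(np.abs(d)) > guard_bound:
        raise ValueError("body response diverged beyond the guard bound; unstable parameters")
    mk = lambda x: UniformSeries(x, platform.t0, platform.rate)
    return ComKinematics(mk(d), mk(v), mk(a))


def to_agonist_frame(com_lab: ComKinematics, direction: Direction) -> ComKinematics:
    """Re-express lab-frame kinematics so positive stretches the agonist.

    A forward translation displaces the CoM backward relative to the base of
    support (negative lab d), stretching TA; the flip makes the analysis-frame
    response identical for both directions.
    """
    s = -1.0 if direction == "forward" else 1.0
    return com_lab.scaled(s)


@dataclass(frozen=True)
class GroundTruth:
    """True feedback-loop parameters for one synthetic participant.

    Delay means follow the latencies typical of perturbation-evoked balance
    responses: LLR1 ~119 ms, LLR2 ~200 ms, destabilizing ~181 ms,
    stabilizing ~135 ms (the latter expressed relative to the kinematic
    reversal at platform deceleration).
    """

    agonist_llr1: LoopParams
    agonist_llr2: LoopParams
    antag_stab: LoopParams
    antag_destab: LoopParams
    magnitude_gain: dict[str, float] = field(
        default_factory=lambda: {"small": 1.0, "medium": 1.15, "large": 1.3}
    )
    baseline: float = 0.05  # normalized EMG units
    noise_sd: float = 0.03  # normalized EMG units, post-smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline < 0 or self.noise_sd < 0:
            raise ValueError("baseline and noise_sd must be non-negative")
        for p in (self.agonist_llr1, self.agonist_llr2, self.antag_stab, self.antag_destab):
            if not 0.06 <= p.delay <= 0.30:
                raise ValueError("ground-truth delays must lie in [0.06, 0.30] s")

    def _scaled(self, p: LoopParams, c: float) -> LoopParams:
        return replace(p, k_d=c * p.k_d, k_v=c * p.k_v, k_a=c * p.k_a)

    def agonist_model(self, magnitude: Magnitude = "small") -> DualLoopModel:
        c = self.magnitude_gain[magnitude]
        return DualLoopModel(
            self._scaled(self.agonist_llr1, c), self._scaled(self.agonist_llr2, c), "agonist"
        )

    def antagonist_model(self, magnitude: Magnitude = "small") -> DualLoopModel:
        c = self.magnitude_gain[magnitude]
        return DualLoopModel(
            self._scaled(self.antag_stab, c), self._scaled(self.antag_destab, c), "antagonist"
        )

    def to_dict(self) -> dict:
        loop = lambda p: {
            "k_d": p.k_d, "k_v": p.k_v, "k_a": p.k_a,
            "delay": p.delay, "sign_mode": p.sign_mode,
        }
        return {
            "agonist_llr1": loop(self.agonist_llr1),
            "agonist_llr2": loop(self.agonist_llr2),
            "antag_stab": loop(self.antag_stab),
            "antag_destab": loop(self.antag_destab),
            "magnitude_gain": dict(self.magnitude_gain),
            "baseline": self.baseline,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        loop = lambda q: LoopParams(**q)
        return cls(
            agonist_llr1=loop(d["agonist_llr1"]),
            agonist_llr2=loop(d["agonist_llr2"]),
            antag_stab=loop(d["antag_stab"]),
            antag_destab=loop(d["antag_destab"]),
            magnitude_gain=dict(d["magnitude_gain"]),
            baseline=d["baseline"],
            noise_sd=d["noise_sd"],
            seed=d["seed"],
        )


def default_ground_truth(noise_sd: float = 0.03, baseline: float = 0.05) -> GroundTruth:
    """Population-mean loop parameters, calibrated so loop outputs peak at
    roughly 0.2-0.4 normalized units under the small perturbation."""
    return GroundTruth(
        agonist_llr1=LoopParams(1.0, 0.8, 0.30, 0.119, "stretch"),
        agonist_llr2=LoopParams(6.0, 0.5, 0.15, 0.200, "stretch"),
        antag_stab=LoopParams(1.0, 0.6, 0.20, 0.135, "stretch"),
        antag_destab=LoopParams(0.8, 0.3, 0.25, 0.181, "shorten"),
        baseline=baseline,
        noise_sd=noise_sd,
    )


# Delay draw clip ranges per loop role; interiors of the fitting delay grids.
_DELAY_CLIP = {
    "agonist_llr1": (0.085, 0.165),
    "agonist_llr2": (0.165, 0.265),
    "antag_stab": (0.095, 0.185),
    "antag_destab": (0.135, 0.235),
}


def draw_ground_truth(
    rng: np.random.Generator,
    group: Group,
    base: GroundTruth | None = None,
    gain_cv: float = 0.2,
    delay_sd: float = 0.008,
    pd_destab_acc_multiplier: float = 1.5,
    seed: int = 0,
) -> GroundTruth:
    """Per-participant parameter draw: lognormal gains (coefficient of
    variation gain_cv), normal delays clipped to physiological ranges, and a
    larger destabilizing acceleration gain on average in the PD group."""
    base = base or default_ground_truth()
    sig = np.sqrt(np.log(1.0 + gain_cv**2))

    def draw_loop(p: LoopParams, name: str, acc_mult: float = 1.0) -> LoopParams:
        gains = [
            g * rng.lognormal(-0.5 * sig * sig, sig) if g > 0 else 0.0
            for g in (p.k_d, p.k_v, p.k_a * acc_mult)
        ]
        lo, hi = _DELAY_CLIP[name]
        delay = float(np.clip(rng.normal(p.delay, delay_sd), lo, hi))
        return LoopParams(gains[0], gains[1], gains[2], delay, p.sign_mode)

    l1 = draw_loop(base.agonist_llr1, "agonist_llr1")
    l2 = draw_loop(base.agonist_llr2, "agonist_llr2")
    if l2.delay - l1.delay < 0.03:  # keep the two agonist bursts separable
        l2 = replace(l2, delay=l1.delay + 0.03)
    stab = draw_loop(base.antag_stab, "antag_stab")
    destab = draw_loop(
        base.antag_destab, "antag_destab",
        acc_mult=pd_destab_acc_multiplier if group == "PD" else 1.0,
    )
    return replace(
        base, agonist_llr1=l1, agonist_llr2=l2, antag_stab=stab, antag_destab=destab, seed=seed
    )


def _smoothed_noise(
    n: int, rate: float, sd: float, rng: np.random.Generator, cutoff_hz: float = 40.0
) -> np.ndarray:
    """Zero-mean Gaussian noise low-pass filtered at cutoff_hz, rescaled so
    its post-filter standard deviation equals sd."""
    if sd == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    b, a = signal.butter(4, cutoff_hz, btype="low", fs=rate)
    smooth = signal.filtfilt(b, a, white)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def generate_emg(
    com_agonist_frame: ComKinematics,
    truth: GroundTruth,
    which: Literal["agonist", "antagonist"] = "agonist",
    seed: int = 0,
    magnitude: Magnitude = "small",
) -> UniformSeries:
    """Forward-model EMG envelope for one muscle of one trial.

    baseline + dual-loop reconstruction + smoothed zero-mean Gaussian noise,
    half-wave rectified at 0. Deterministic given seed. `com_agonist_frame`
    is in the agonist stretch frame; the antagonist model is evaluated on its
    negation.
    """
    if which == "agonist":
        com, m = com_agonist_frame, truth.agonist_model(magnitude)
    elif which == "antagonist":
        com, m = -com_agonist_frame, truth.antagonist_model(magnitude)
    else:
        raise ValueError(f"unknown muscle {which!r}")
    rec = reconstruct(com, m)
    rng = np.random.default_rng(seed)
    noise = _smoothed_noise(len(rec.total), com.rate, truth.noise_sd, rng)
    return rec.total.with_values(rectify(truth.baseline + rec.total.values + noise))


@dataclass(frozen=True)
class SyntheticTrial:
    """One perturbation trial: lab-frame CoM kinematics plus the agonist and
    antagonist EMG envelopes (1000 Hz, normalized units)."""

    participant_id: str
    group: Group
    direction: Direction
    magnitude: Magnitude
    stepped: bool
    com: ComKinematics  # lab frame
    emg_agonist: UniformSeries
    emg_antagonist: UniformSeries
    clinical_score: float


def generate_cohort(
    n_oa: int,
    n_pd: int,
    trials_per_condition: int = 8,
    seed: int = 0,
    stepped_fraction: float = 0.0871,
    noise_sd: float = 0.03,
    baseline: float = 0.05,
    kinematic_jitter: float = 0.02,
    gain_cv: float = 0.2,
    delay_sd: float = 0.008,
    pd_destab_acc_multiplier: float = 1.5,
    clinical_slope: float = 24.0,
    clinical_noise_sd: float = 1.6,
    body: BodyModel | None = None,
    t_start: float = -0.3,
    t_stop: float = 1.5,
) -> tuple[list[SyntheticTrial], dict[str, dict]]:
    """Generate a full synthetic cohort with known ground truth.

    Each participant receives trials_per_condition trials in each of the six
    conditions (3 magnitudes x 2 directions; 48 trials at the default 8).
    Trial-level variability enters through kinematic jitter on the platform
    peaks and independent EMG noise; a stepped_fraction of trials is flagged
    as stepping (default 8.71%, the protocol's observed rate). The clinical
    balance score (0-28, higher = better) is generated as
    28 - clinical_slope * k_aD + Gaussian noise, clipped to [0, 28], giving a
    recoverable negative correlation between destabilizing activity and the
    score. Returns the trial list and a per-participant registry holding the
    GroundTruth and metadata.
    """
    if n_oa < 0 or n_pd < 0 or n_oa + n_pd < 1:
        raise ValueError("need at least one participant")
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    if not 0.0 <= stepped_fraction <= 1.0:
        raise ValueError("stepped_fraction must lie in [0, 1]")
    body = body or BodyModel()
    base = default_ground_truth(noise_sd=noise_sd, baseline=baseline)
    rng = np.random.default_rng(seed)
    trials: list[SyntheticTrial] = []
    registry: dict[str, dict] = {}
    groups = ["OA"] * n_oa + ["PD"] * n_pd
    for i, group in enumerate(groups):
        pid = f"{group}{i + 1:03d}"
        p_seed = int(rng.integers(2**31))
        p_rng = np.random.default_rng(p_seed)
        truth = draw_ground_truth(
            p_rng, group, base, gain_cv=gain_cv, delay_sd=delay_sd,
            pd_destab_acc_multiplier=pd_destab_acc_multiplier, seed=p_seed,
        )
        score = float(
            np.clip(
                28.0 - clinical_slope * truth.antag_destab.k_a
                + p_rng.normal(0.0, clinical_noise_sd),
                0.0, 28.0,
            )
        )
        registry[pid] = {"group": group, "clinical_score": score, "ground_truth": truth}
        for direction in ("forward", "backward"):
            for magnitude in ("small", "medium", "large"):
                for _ in range(trials_per_condition):
                    jit = 1.0 + kinematic_jitter * p_rng.standard_normal()
                    jit = float(np.clip(jit, 0.8, 1.2))
                    d0, v0, a0 = MAGNITUDE_SPECS[magnitude]
                    spec = PerturbationSpec.from_g(
                        direction, d0, v0 * jit, a0 * jit
                    )
                    com_lab = simulate_com_kinematics(
                        make_platform_profile(spec, t_start, t_stop), body
                    )
                    com_ag = to_agonist_frame(com_lab, direction)
                    s_ag = int(p_rng.integers(2**31))
                    s_an = int(p_rng.integers(2**31))
                    trials.append(
                        SyntheticTrial(
                            participant_id=pid,
                            group=group,
                            direction=direction,
                            magnitude=magnitude,
                            stepped=bool(p_rng.random() < stepped_fraction),
                            com=com_lab,
                            emg_agonist=generate_emg(com_ag, truth, "agonist", s_ag, magnitude),
                            emg_antagonist=generate_emg(
                                com_ag, truth, "antagonist", s_an, magnitude
                            ),
                            clinical_score=score,
                        )
                    )
    return trials, registry


def write_cohort(
    out_dir: str | Path,
    trials: list[SyntheticTrial],
    registry: dict[str, dict],
    com_rate: float | None = None,
) -> Path:
    """Write a cohort directory: manifest.json plus one CSV per trial.

    Columns: time_s, com_disp_m, com_vel_mps, com_acc_mps2, emg_agonist,
    emg_antagonist. If com_rate is given (e.g. 100 Hz), kinematics are
    decimated into a separate `<trial>_com.csv` to exercise resampling and
    the main CSV carries only time and EMG.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "emg_kind": "envelope",
        "emg_rate": trials[0].emg_agonist.rate if trials else 1000.0,
        "com_rate": com_rate or (trials[0].com.rate if trials else 1000.0),
        "separate_com": com_rate is not None,
        "participants": {
            pid: {
                "group": entry["group"],
                "clinical_score": entry["clinical_score"],
                "ground_truth": entry["ground_truth"].to_dict(),
            }
            for pid, entry in registry.items()
        },
        "trials": [],
    }
    counters: dict[str, int] = {}
    for tr in trials:
        counters[tr.participant_id] = counters.get(tr.participant_id, 0) + 1
        trial_id = f"{tr.participant_id}_t{counters[tr.participant_id]:03d}"
        fname = f"{trial_id}.csv"
        t = tr.emg_agonist.t
        if com_rate is None:
            df = pd.DataFrame(
                {
                    "time_s": t,
                    "com_disp_m": tr.com.d.values,
                    "com_vel_mps": tr.com.v.values,
                    "com_acc_mps2": tr.com.a.values,
                    "emg_agonist": tr.emg_agonist.values,
                    "emg_antagonist": tr.emg_antagonist.values,
                }
            )
            df.to_csv(out / fname, index=False, float_format="%.10g")
        else:
            pd.DataFrame(
                {
                    "time_s": t,
                    "emg_agonist": tr.emg_agonist.values,
                    "emg_antagonist": tr.emg_antagonist.values,
                }
            ).to_csv(out / fname, index=False, float_format="%.10g")
            step = int(round(tr.com.rate / com_rate))
            if step < 1 or abs(tr.com.rate / step - com_rate) > 1e-9:
                raise ValueError("com_rate must divide the simulation rate")
            sl = slice(None, None, step)
            pd.DataFrame(
                {
                    "time_s": tr.com.t[sl],
                    "com_disp_m": tr.com.d.values[sl],
                    "com_vel_mps": tr.com.v.values[sl],
                    "com_acc_mps2": tr.com.a.values[sl],
                }
            ).to_csv(out / f"{trial_id}_com.csv", index=False, float_format="%.10g")
        manifest["trials"].append(
            {
                "trial_id": trial_id,
                "participant": tr.participant_id,
                "group": tr.group,
                "direction": tr.direction,
                "magnitude": tr.magnitude,
                "stepped": tr.stepped,
                "file": fname,
            }
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def load_cohort(cohort_dir: str | Path) -> tuple[list[SyntheticTrial], dict[str, dict]]:
    """Read a cohort directory written by `write_cohort`."""
    root = Path(cohort_dir)
    with open(root / "manifest.json") as fh:
        manifest = json.load(fh)
    registry = {
        pid: {
            "group": entry["group"],
            "clinical_score": entry["clinical_score"],
            "ground_truth": GroundTruth.from_dict(entry["ground_truth"]),
        }
        for pid, entry in manifest["participants"].items()
    }
    emg_rate = float(manifest["emg_rate"])
    com_rate = float(manifest["com_rate"])
    trials = []
    for rec in manifest["trials"]:
        df = pd.read_csv(root / rec["file"])
        t0 = float(df["time_s"].iloc[0])
        if manifest.get("separate_com"):
            cdf = pd.read_csv(root / f"{rec['trial_id']}_com.csv")
            ct0 = float(cdf["time_s"].iloc[0])
            mk = lambda col: UniformSeries(cdf[col].to_numpy(), ct0, com_rate)
        else:
            cdf = df
            mk = lambda col: UniformSeries(cdf[col].to_numpy(), t0, com_rate)
        com = ComKinematics(mk("com_disp_m"), mk("com_vel_mps"), mk("com_acc_mps2"))
        trials.append(
            SyntheticTrial(
                participant_id=rec["participant"],
                group=rec["group"],
                direction=rec["direction"],
                magnitude=rec["magnitude"],
                stepped=bool(rec["stepped"]),
                com=com,
                emg_agonist=UniformSeries(df["emg_agonist"].to_numpy(), t0, emg_rate),
                emg_antagonist=UniformSeries(df["emg_antagonist"].to_numpy(), t0, emg_rate),
                clinical_score=float(registry[rec["participant"]]["clinical_score"]),
            )
        )
    return trials, registry
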