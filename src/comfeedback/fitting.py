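"""Two-stage identification of delayed-feedback loop parameters.

The cost combines three penalties over the fit window,

    J = mu_s * int e^2 dt  +  mu_m * max|e|  +  mu_k * k'k ,

with e the difference between the recorded envelope and the model
reconstruction, and weight ratio mu_s : mu_m : mu_k = 1 : 1 : 1e-6. The
squared-error integral uses trapezoidal quadrature; the gain penalty shrinks
parameters that do not improve reconstruction.

Stage 1 fits each loop alone: delays are scanned on a 5 ms grid over the
loop role's physiological range, gains at each delay start from a
non-negative least-squares solution on the un-rectified design and are
refined on the full rectified cost; the grid-best is then refined locally in
delay (+-5 ms). Stage 2 refits both loops jointly, with gains bounded to
+-10% and delays to +-10 ms of their stage-1 seeds, so the joint fit can
shed activity a single loop over-claimed. The cost is non-smooth in the
delay (rectification, max-error term), so the local optimizer is
derivative-free (bounded Powell) at parameter tolerance 1e-9, objective
tolerance 1e-7, and at most 1e5 evaluations per solve; the returned cost
never exceeds the cost at initialization.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import minimize, nnls

from .metrics import integrate_component, r_squared, vaf
from .model import (
    DualLoopModel,
    LoopParams,
    Reconstruction,
    decompose_destabilizing,
    loop_output,
    reconstruct,
)
from .preprocessing import ConditionAverage, ExcludedCondition
from .series import ComKinematics, UniformSeries

__all__ = [
    "CostWeights",
    "FitConfig",
    "FitResult",
    "cost",
    "fit_single_loop",
    "fit_double_loop",
    "fit_condition",
    "LOOP_ROLES",
]

MuscleRole = Literal["agonist", "antagonist"]
LoopRole = Literal["llr1", "llr2", "stabilizing", "destabilizing"]

#: Loop roles per muscle, in (loop1, loop2) order.
LOOP_ROLES: dict[str, tuple[LoopRole, LoopRole]] = {
    "agonist": ("llr1", "llr2"),
    "antagonist": ("stabilizing", "destabilizing"),
}

_SIGN_MODE: dict[str, str] = {
    "llr1": "stretch",
    "llr2": "stretch",
    "stabilizing": "stretch",
    "destabilizing": "shorten",
}


@dataclass(frozen=True)
class CostWeights:
    """Weights of the squared-error, max-error and gain-magnitude penalties."""

    mu_s: float = 1.0
    mu_m: float = 1.0
    mu_k: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.mu_s, self.mu_m, self.mu_k) < 0:
            raise ValueError("cost weights must be non-negative")


@dataclass(frozen=True)
class FitConfig:
    """Everything the two-stage fit needs besides the data.

    Stage-1 delay grids encode each loop role's physiological latency prior
    (LLR1 ~120 ms, LLR2 ~200 ms, stabilizing ~130 ms after the kinematic
    reversal at platform deceleration, destabilizing ~180 ms); widths are
    generous and configurable. The default fit window [0, 0.8] s covers
    both agonist bursts and the deceleration-locked stabilizing burst while
    excluding late voluntary activity.
    """

    fit_window: tuple[float, float] = (0.0, 0.8)
    delay_grids: dict = field(
        default_factory=lambda: {
            "llr1": (0.07, 0.18),
            "llr2": (0.15, 0.28),
            "stabilizing": (0.08, 0.20),
            "destabilizing": (0.12, 0.25),
        }
    )
    grid_step: float = 0.005  # s
    stage2_gain_frac: float = 0.10  # +-10% of the stage-1 seed
    stage2_delay_pad: float = 0.010  # +-10 ms of the stage-1 seed
    xtol: float = 1e-9
    ftol: float = 1e-7
    maxfev: int = 100_000
    weights: CostWeights = field(default_factory=CostWeights)
    #: stage-1 delay-basin candidates per loop carried into stage 2
    multistart: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        t0, t1 = self.fit_window
        if not t0 < t1:
            raise ValueError("fit_window must satisfy t_start < t_end")
        for role, (lo, hi) in self.delay_grids.items():
            if not (0.0 <= lo < hi <= 0.3):
                raise ValueError(f"delay grid for {role!r} must lie within [0, 0.3] s")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass(frozen=True)
class FitResult:
    """Fitted dual-loop model plus reconstruction quality and components."""

    model: DualLoopModel
    cost: float
    seeds: tuple[LoopParams, LoopParams]
    seed_cost: float
    reconstruction: Reconstruction
    r2: float
    vaf: float
    integrals: dict[str, float]
    diagnostics: dict
    participant_id: str = ""
    direction: str = ""
    magnitude: str = ""

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be non-negative")
        if self.cost > self.seed_cost + 1e-12:
            raise ValueError("stage-2 cost exceeds its initialization cost")


def _window_mask(series: UniformSeries, window: tuple[float, float]) -> np.ndarray:
    t = series.t
    eps = 1e-9
    m = (t >= window[0] - eps) & (t <= window[1] + eps)
    if m.sum() < 2:
        raise ValueError("fit window not covered by trace")
    return m


def cost(
    recorded: UniformSeries,
    reconstructed: UniformSeries,
    gains: np.ndarray,
    w: CostWeights = CostWeights(),
    window: tuple[float, float] = (0.0, 0.8),
) -> float:
    """Three-term penalized reconstruction cost over the fit window."""
    if not recorded.same_grid(reconstructed):
        raise ValueError("traces must share a grid")
    m = _window_mask(recorded, window)
    e = recorded.values[m] - reconstructed.values[m]
    t = recorded.t[m]
    gains = np.asarray(gains, dtype=float)
    return float(
        w.mu_s * np.trapezoid(e * e, t)
        + w.mu_m * np.max(np.abs(e))
        + w.mu_k * np.dot(gains, gains)
    )


class _Objective:
    """Shared machinery: cached window mask and fast cost evaluation."""

    def __init__(self, emg: UniformSeries, com: ComKinematics, cfg: FitConfig):
        if not emg.same_grid(com.d):
            raise ValueError("EMG and kinematics must share a grid before fitting")
        self.emg = emg
        self.com = com
        self.cfg = cfg
        self.mask = _window_mask(emg, cfg.fit_window)
        self.t_win = emg.t[self.mask]
        self.y_win = emg.values[self.mask]
        # channels as plain arrays for np.interp (pre-t0 queries hold the
        # first sample, the quiet-stance rest state)
        self.tc = com.t
        self.ch = (com.d.values, com.v.values, com.a.values)

    def delayed_design(self, delay: float, sigma: float) -> np.ndarray:
        """(n_win, 3) matrix of sigma-signed delayed predictors on the window."""
        tq = self.t_win - delay
        return np.column_stack([sigma * np.interp(tq, self.tc, c) for c in self.ch])

    def loop_values(self, delay: float, sigma: float, gains: np.ndarray) -> np.ndarray:
        tq = self.t_win - delay
        s = np.zeros_like(tq)
        for g, c in zip(gains, self.ch):
            if g != 0.0:
                s += g * np.interp(tq, self.tc, c)
        return np.maximum(0.0, sigma * s)

    def eval_cost(self, recon_win: np.ndarray, gains: np.ndarray, y: np.ndarray | None = None) -> float:
        e = (self.y_win if y is None else y) - recon_win
        w = self.cfg.weights
        return float(
            w.mu_s * np.trapezoid(e * e, self.t_win)
            + w.mu_m * np.max(np.abs(e))
            + w.mu_k * np.dot(gains, gains)
        )

    def single_cost(self, params: np.ndarray, sigma: float, y: np.ndarray | None = None) -> float:
        gains, delay = params[:3], params[3]
        return self.eval_cost(self.loop_values(delay, sigma, gains), gains, y)

    def double_cost(self, params: np.ndarray, sig1: float, sig2: float) -> float:
        g1, l1, g2, l2 = params[:3], params[3], params[4:7], params[7]
        recon = self.loop_values(l1, sig1, g1) + self.loop_values(l2, sig2, g2)
        return self.eval_cost(recon, np.concatenate([g1, g2]))


def _minimize(fun, x0, bounds, cfg: FitConfig):
    bounds = [
        (lo if lo is not None else -np.inf, hi if hi is not None else np.inf)
        for lo, hi in bounds
    ]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = minimize(
        fun,
        x0,
        method="Powell",
        bounds=bounds,
        options={"xtol": cfg.xtol, "ftol": cfg.ftol, "maxfev": cfg.maxfev},
    )
    f0 = fun(x0)
    if res.fun <= f0:
        return np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds]), float(res.fun)
    return x0, float(f0)  # never accept a step uphill from the seed


def fit_single_loop(
    avg: ConditionAverage | tuple[UniformSeries, ComKinematics],
    role: LoopRole,
    cfg: FitConfig | None = None,
) -> tuple[LoopParams, float]:
    """Stage 1: fit one feedback loop alone to the recorded envelope.

    Scans the role's delay grid; at each delay the gains start from NNLS on
    the un-rectified delayed design and are refined on the rectified cost;
    the best grid point is then refined jointly in (gains, delay) within
    +-5 ms. Grid ties break toward the smaller (earliest physiologically
    plausible) delay.
    """
    cands = fit_single_loop_candidates(avg, role, cfg, n_candidates=1)
    return cands[0]


def fit_single_loop_candidates(
    avg: ConditionAverage | tuple[UniformSeries, ComKinematics],
    role: LoopRole,
    cfg: FitConfig | None = None,
    n_candidates: int | None = None,
) -> list[tuple[LoopParams, float]]:
    """Stage-1 candidates: locally refined fits at each basin of the delay
    grid, best first.

    The rectified cost is multi-basin in the delay whenever the recorded
    envelope holds more than one burst; the grid's local minima (plus the
    global grid-best) are each refined and returned so stage 2 can start
    from every plausible basin. Ties break toward the smaller delay.
    """
    cfg = cfg or FitConfig()
    if isinstance(avg, ConditionAverage):
        emg, com_k = avg.emg, avg.com
    else:
        emg, com_k = avg
    n_candidates = n_candidates if n_candidates is not None else cfg.multistart
    obj = _Objective(emg, com_k, cfg)
    return _fit_loop_to_target(obj, role, obj.y_win, cfg, n_candidates)


def _fit_loop_to_target(
    obj: _Objective,
    role: LoopRole,
    y: np.ndarray,
    cfg: FitConfig,
    n_candidates: int = 1,
) -> list[tuple[LoopParams, float]]:
    """Grid scan + local refinement of one loop against an arbitrary target
    trace on the fit window (the recorded envelope, or a backfitting
    residual). Returns up to n_candidates basin fits, best first."""
    sigma = 1.0 if _SIGN_MODE[role] == "stretch" else -1.0
    lo, hi = cfg.delay_grids[role]
    grid = np.arange(lo, hi + 1e-12, cfg.grid_step)
    fits: list[tuple[float, np.ndarray, float]] = []  # (cost, gains, delay)
    # For a non-negative target (a recorded envelope) solve the gain
    # subproblem on the rows where the target is active: where the rectifier
    # is off (y == 0) the unrectified design would otherwise drag the
    # least-squares gains toward zero. Backfitting residuals carry signed
    # information in every row and use them all.
    if np.all(y >= 0.0) and (y > 0.0).sum() >= 10:
        active = y > 0.0
    else:
        active = np.ones_like(y, dtype=bool)
    for delay in grid:
        D = obj.delayed_design(delay, sigma)
        g0, _ = nnls(D[active], y[active])
        f = obj.eval_cost(np.maximum(0.0, D @ g0), g0, y)
        fits.append((f, g0, float(delay)))
    if not fits:
        raise RuntimeError(f"single-loop fit failed on an empty delay grid for role {role!r}")
    costs = np.array([f for f, _, _ in fits])
    is_min = np.ones(len(fits), dtype=bool)
    if len(fits) > 1:
        is_min[1:] &= costs[1:] < costs[:-1] + 1e-15  # strict vs left: tie -> smaller delay
        is_min[:-1] &= costs[:-1] <= costs[1:] + 1e-15
    order = sorted(np.flatnonzero(is_min), key=lambda i: (costs[i], fits[i][2]))
    out: list[tuple[LoopParams, float]] = []
    for i in order[:n_candidates]:
        _, g_best, d_best = fits[i]
        x0 = np.append(g_best, d_best)
        x, f = _minimize(
            lambda p: obj.single_cost(p, sigma, y),
            x0,
            [(0.0, None)] * 3
            + [(max(0.0, d_best - cfg.grid_step), min(0.3, d_best + cfg.grid_step))],
            cfg,
        )
        out.append((LoopParams(x[0], x[1], x[2], x[3], _SIGN_MODE[role]), f))
    out.sort(key=lambda pf: (pf[1], pf[0].delay))
    return out


def _stage2_bounds(
    seed1: LoopParams, seed2: LoopParams, kind: MuscleRole, cfg: FitConfig
) -> list[tuple[float, float]]:
    def gain_b(g: float) -> tuple[float, float]:
        if g <= 1e-12:
            return (0.0, 1e-12)
        return ((1.0 - cfg.stage2_gain_frac) * g, (1.0 + cfg.stage2_gain_frac) * g)

    def delay_b(d: float) -> tuple[float, float]:
        return (max(0.0, d - cfg.stage2_delay_pad), min(0.3, d + cfg.stage2_delay_pad))

    b1d, b2d = delay_b(seed1.delay), delay_b(seed2.delay)
    if kind == "agonist" and b1d[1] >= b2d[0]:
        # keep loop1 strictly earlier than loop2
        mid = 0.5 * (seed1.delay + seed2.delay)
        b1d = (b1d[0], min(b1d[1], mid - 5e-4))
        b2d = (max(b2d[0], mid + 5e-4), b2d[1])
    return (
        [gain_b(seed1.k_d), gain_b(seed1.k_v), gain_b(seed1.k_a), b1d]
        + [gain_b(seed2.k_d), gain_b(seed2.k_v), gain_b(seed2.k_a), b2d]
    )


def fit_double_loop(
    avg: ConditionAverage,
    seeds: tuple[LoopParams, LoopParams],
    kind: MuscleRole,
    cfg: FitConfig | None = None,
    com: ComKinematics | None = None,
    participant_id: str = "",
    direction: str = "",
    magnitude: str = "",
) -> FitResult:
    """Stage 2: joint bounded refinement of both loops from stage-1 seeds.

    Gains bounded to +-10% and delays to +-10 ms of the seeds; the final
    cost never exceeds the seed cost.
    """
    cfg = cfg or FitConfig()
    com_k = com if com is not None else avg.com
    obj = _Objective(avg.emg, com_k, cfg)
    s1, s2 = seeds
    sig1 = 1.0 if s1.sign_mode == "stretch" else -1.0
    sig2 = 1.0 if s2.sign_mode == "stretch" else -1.0
    bounds = _stage2_bounds(s1, s2, kind, cfg)
    x0 = np.array([s1.k_d, s1.k_v, s1.k_a, s1.delay, s2.k_d, s2.k_v, s2.k_a, s2.delay])
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    f_seed = obj.double_cost(x0, sig1, sig2)
    best_x, best_f = _minimize(lambda p: obj.double_cost(p, sig1, sig2), x0, bounds, cfg)
    loop1 = LoopParams(best_x[0], best_x[1], best_x[2], best_x[3], s1.sign_mode)
    loop2 = LoopParams(best_x[4], best_x[5], best_x[6], best_x[7], s2.sign_mode)
    model = DualLoopModel(loop1, loop2, kind)
    rec = reconstruct(com_k, model)
    win = cfg.fit_window
    emg_w = avg.emg.slice_time(*win)
    tot_w = rec.total.slice_time(*win)
    integrals = _component_integrals(com_k, model, rec, win)
    return FitResult(
        model=model,
        cost=best_f,
        seeds=seeds,
        seed_cost=f_seed,
        reconstruction=rec,
        r2=r_squared(emg_w, tot_w),
        vaf=vaf(emg_w, tot_w),
        integrals=integrals,
        diagnostics={"n_window_samples": int(obj.mask.sum()), "seed_cost": f_seed},
        participant_id=participant_id,
        direction=direction,
        magnitude=magnitude,
    )


def _component_integrals(
    com: ComKinematics, model: DualLoopModel, rec: Reconstruction, window: tuple[float, float]
) -> dict[str, float]:
    names = LOOP_ROLES[model.kind]
    out = {
        names[0]: integrate_component(rec.loop1, window),
        names[1]: integrate_component(rec.loop2, window),
    }
    if model.kind == "antagonist":
        acc, veldisp = decompose_destabilizing(com, model.loop2)
        out["destab_acc"] = integrate_component(acc, window)
        out["destab_veldisp"] = integrate_component(veldisp, window)
    return out


def fit_condition(
    avg: ConditionAverage | ExcludedCondition,
    muscle_role: MuscleRole,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Full two-stage fit of one condition average for one muscle.

    `avg.com` is expressed in the agonist stretch frame; the antagonist
    model is fit on its negation (the antagonist's stretch frame), with its
    stabilizing loop stretch-signed and destabilizing loop shorten-signed.
    """
    if isinstance(avg, ExcludedCondition):
        raise ValueError(
            f"condition {avg.participant_id}/{avg.direction}/{avg.magnitude} was excluded "
            f"({avg.reason}); cannot fit"
        )
    cfg = cfg or FitConfig()
    com = avg.com if muscle_role == "agonist" else -avg.com
    role1, role2 = LOOP_ROLES[muscle_role]
    obj = _Objective(avg.emg, com, cfg)
    cands1 = _fit_loop_to_target(obj, role1, obj.y_win, cfg, cfg.multistart)
    cands2 = _fit_loop_to_target(obj, role2, obj.y_win, cfg, cfg.multistart)

    def sig(p: LoopParams) -> float:
        return 1.0 if p.sign_mode == "stretch" else -1.0

    def loop_win(p: LoopParams) -> np.ndarray:
        return obj.loop_values(p.delay, sig(p), p.gains)

    def pair_cost(s_a: LoopParams, s_b: LoopParams) -> float:
        return obj.eval_cost(
            loop_win(s_a) + loop_win(s_b), np.concatenate([s_a.gains, s_b.gains])
        )

    def backfit(
        start: LoopParams, role_a: LoopRole, role_b: LoopRole, max_iter: int = 10
    ) -> tuple[LoopParams, LoopParams]:
        """Alternately refit each loop on the other's residual: a single loop
        over-claims activity the other loop explains better, and coordinate
        descent sheds it. Returns the best (role_a, role_b) pair seen."""
        s_a = start
        best_pair, best_c, stall = None, np.inf, 0
        for _ in range(max_iter):
            s_b = _fit_loop_to_target(obj, role_b, obj.y_win - loop_win(s_a), cfg, 1)[0][0]
            s_a = _fit_loop_to_target(obj, role_a, obj.y_win - loop_win(s_b), cfg, 1)[0][0]
            c = pair_cost(s_a, s_b)
            if c < best_c - 1e-12:
                best_pair, best_c, stall = (s_a, s_b), c, 0
            else:
                stall += 1
                if stall >= 2:
                    break
        return best_pair if best_pair is not None else (s_a, s_b)

    pairs: list[tuple[LoopParams, LoopParams]] = [
        (s1, s2) for s1, _ in cands1[:2] for s2, _ in cands2[:2]
    ]
    pairs.append(backfit(cands1[0][0], role1, role2))
    s2c, s1c = backfit(cands2[0][0], role2, role1)
    pairs.append((s1c, s2c))
    if muscle_role == "agonist":
        pairs = [(s1, s2) for s1, s2 in pairs if s1.delay < s2.delay]
    # dedupe near-identical seed pairs (same delays to within half a grid step)
    seen: set[tuple[int, int]] = set()
    unique_pairs = []
    for s1, s2 in pairs:
        key = (round(s1.delay / cfg.grid_step * 2), round(s2.delay / cfg.grid_step * 2))
        if key not in seen:
            seen.add(key)
            unique_pairs.append((s1, s2))
    pairs = unique_pairs
    if not pairs:  # every candidate pair violated the role ordering
        s1 = cands1[0][0]
        s2 = replace(cands2[0][0], delay=min(0.3, s1.delay + 2 * cfg.stage2_delay_pad))
        pairs = [(s1, s2)]
    best: FitResult | None = None
    meta = dict(
        com=com,
        participant_id=avg.participant_id,
        direction=avg.direction,
        magnitude=avg.magnitude,
    )
    for seeds in pairs:
        res = fit_double_loop(avg, seeds, muscle_role, cfg, **meta)
        if best is None or res.cost < best.cost:
            best = res
    # re-centered polishing rounds: the stage-2 box is re-anchored on the
    # winning iterate until the bounded refit stops improving
    for _ in range(2):
        res = fit_double_loop(
            avg, (best.model.loop1, best.model.loop2), muscle_role, cfg, **meta
        )
        if res.cost < best.cost - cfg.ftol:
            best = res
        else:
            break
    return best
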