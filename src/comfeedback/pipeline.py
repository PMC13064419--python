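"""End-to-end cohort pipeline: preprocess -> fit -> tables.

Reads a cohort directory (manifest + per-trial CSVs), builds per-condition
averages under the epoching/normalization/exclusion rules, fits the agonist
and antagonist dual-loop models to every retained condition, and writes
descriptive summary tables: component integrals, latencies, fit quality,
peak CoM excursions, group x direction x magnitude means +- SE, and Pearson
correlations of integrated components against the clinical balance score.
Inferential statistics (mixed-effects models, post hocs) are deliberately
left to downstream tools; the emitted long-format tables feed any stats
package.

Everything is deterministic given the cohort directory, the configuration
and the seed; a provenance JSON records enough to reproduce any table.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .fitting import LOOP_ROLES, FitConfig, FitResult, fit_condition
from .metrics import latency_table
from .preprocessing import (
    ConditionAverage,
    ExcludedCondition,
    average_condition,
    epoch,
    epoch_kinematics,
    normalize_participant,
    peak_excursion,
    process_emg_trial,
)
from .series import ComKinematics
from .synthetic import SyntheticTrial, load_cohort, to_agonist_frame
from .preprocessing import align_kinematics

__all__ = [
    "PipelineConfig",
    "preprocess_cohort",
    "fit_cohort",
    "summarize_cohort",
    "correlate_components",
    "run_pipeline",
]

log = logging.getLogger("comfeedback.pipeline")

MUSCLES = ("agonist", "antagonist")
MAG_ORDER = ("small", "medium", "large")


@dataclass(frozen=True)
class PipelineConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    normalize: bool = True
    subtract_baseline: bool = False  # subtract mean pre-onset activity before fitting
    muscles: tuple[str, ...] = MUSCLES
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["muscles"] = list(self.muscles)
        return d


def _condition_key(tr: SyntheticTrial) -> tuple[str, str, str]:
    return (tr.participant_id, tr.direction, tr.magnitude)


def preprocess_cohort(
    trials: list[SyntheticTrial],
    cfg: PipelineConfig | None = None,
    emg_kind: str = "envelope",
) -> tuple[dict[tuple, dict[str, ConditionAverage]], list[ExcludedCondition]]:
    """Epoch, normalize and average a cohort into per-condition inputs.

    Returns {(participant, direction, magnitude): {muscle: ConditionAverage}}
    with kinematics in the agonist stretch frame on the EMG grid, plus the
    list of conditions excluded by the >=3 non-stepping-trials rule.
    Envelope-kind EMG (the synthetic forward model's output) skips the raw
    filter chain; raw-kind EMG passes through it first.
    """
    cfg = cfg or PipelineConfig()
    by_pid: dict[str, list[SyntheticTrial]] = {}
    for tr in trials:
        by_pid.setdefault(tr.participant_id, []).append(tr)

    averages: dict[tuple, dict[str, ConditionAverage]] = {}
    exclusions: list[ExcludedCondition] = []
    for pid, ptrials in by_pid.items():
        env = {}
        for muscle in MUSCLES:
            raws = [getattr(tr, f"emg_{muscle}") for tr in ptrials]
            if emg_kind == "raw":
                raws = [process_emg_trial(r) for r in raws]
            epoched = [epoch(r) for r in raws]
            env[muscle] = normalize_participant(epoched) if cfg.normalize else epoched
        coms = []
        for tr in ptrials:
            com_ag = to_agonist_frame(tr.com, tr.direction)
            com_ag = epoch_kinematics(com_ag) if com_ag.rate == epoched[0].rate else com_ag
            coms.append(align_kinematics(com_ag, env["agonist"][0]))
        by_cond: dict[tuple, list[int]] = {}
        for i, tr in enumerate(ptrials):
            by_cond.setdefault(_condition_key(tr), []).append(i)
        for key in sorted(by_cond):
            idx = by_cond[key]
            stepped = [ptrials[i].stepped for i in idx]
            cell: dict[str, ConditionAverage] = {}
            excluded = False
            for muscle in cfg.muscles:
                out = average_condition(
                    [env[muscle][i] for i in idx],
                    [coms[i] for i in idx],
                    stepped,
                    participant_id=key[0],
                    direction=key[1],
                    magnitude=key[2],
                )
                if isinstance(out, ExcludedCondition):
                    excluded = True
                    break
                if cfg.subtract_baseline:
                    pre = out.emg.values[out.emg.t < 0.0]
                    out = ConditionAverage(
                        out.emg.with_values(np.maximum(0.0, out.emg.values - pre.mean())),
                        out.com, out.n_trials, *key,
                    )
                cell[muscle] = out
            if excluded:
                exclusions.append(
                    ExcludedCondition(key[0], key[1], key[2], sum(not s for s in stepped))
                )
            else:
                averages[key] = cell
    return averages, exclusions


def fit_cohort(
    averages: dict[tuple, dict[str, ConditionAverage]],
    cfg: PipelineConfig | None = None,
) -> list[FitResult]:
    """Two-stage fit of every retained condition x muscle."""
    cfg = cfg or PipelineConfig()
    results = []
    for key in sorted(averages):
        for muscle in cfg.muscles:
            t0 = time.perf_counter()
            res = fit_condition(averages[key][muscle], muscle, cfg.fit)
            log.info(
                "fit %s/%s/%s %s: cost %.3e (seed %.3e) R2 %.3f VAF %.1f [%.1f s]",
                *key, muscle, res.cost, res.seed_cost, res.r2, res.vaf,
                time.perf_counter() - t0,
            )
            results.append(res)
    return results


def _result_tables(
    results: list[FitResult],
    averages: dict[tuple, dict[str, ConditionAverage]],
    groups: dict[str, str],
    scores: dict[str, float],
) -> dict[str, pd.DataFrame]:
    qual_rows, integ_rows = [], []
    for r in results:
        base = {
            "participant": r.participant_id,
            "group": groups.get(r.participant_id, ""),
            "muscle": r.model.kind,
            "direction": r.direction,
            "magnitude": r.magnitude,
        }
        qual_rows.append({**base, "cost": r.cost, "r2": r.r2, "vaf": r.vaf})
        for comp, val in r.integrals.items():
            integ_rows.append({**base, "component": comp, "integral": val})
    peak_rows = [
        {
            "participant": key[0],
            "group": groups.get(key[0], ""),
            "direction": key[1],
            "magnitude": key[2],
            "peak_excursion_m": peak_excursion(cell["agonist"].com.d),
            "n_trials": cell["agonist"].n_trials,
        }
        for key, cell in sorted(averages.items())
    ]
    lat = latency_table(results)
    lat.insert(1, "group", lat["participant"].map(groups).fillna(""))
    score_rows = [
        {"participant": p, "group": groups.get(p, ""), "clinical_score": s}
        for p, s in sorted(scores.items())
    ]
    return {
        "fit_quality": pd.DataFrame(qual_rows),
        "integrals": pd.DataFrame(integ_rows),
        "peak_excursion": pd.DataFrame(peak_rows),
        "latencies": lat,
        "clinical_scores": pd.DataFrame(score_rows),
    }


def summarize_cohort(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Group x direction x magnitude mean +- SE of integrals, latencies and
    fit quality, long format."""
    rows = []

    def add(df, value_col, label_cols):
        for keys, sub in df.groupby(label_cols, sort=True):
            v = sub[value_col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rec = dict(zip(label_cols, keys))
            rec.update(
                measure=value_col if "component" not in label_cols else rec.pop("component"),
                mean=v.mean(),
                se=v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0,
                n=int(v.size),
            )
            rows.append(rec)

    add(tables["integrals"], "integral", ["group", "muscle", "direction", "magnitude", "component"])
    add(tables["latencies"], "latency_ms", ["group", "muscle", "direction", "magnitude", "loop"])
    add(tables["fit_quality"], "r2", ["group", "muscle", "direction", "magnitude"])
    add(tables["fit_quality"], "vaf", ["group", "muscle", "direction", "magnitude"])
    add(tables["peak_excursion"], "peak_excursion_m", ["group", "direction", "magnitude"])
    df = pd.DataFrame(rows)
    front = [c for c in ("group", "muscle", "direction", "magnitude", "loop", "measure") if c in df]
    rest = [c for c in df.columns if c not in front]
    return df[front + rest].sort_values(front, kind="stable").reset_index(drop=True)


def correlate_components(
    integrals: pd.DataFrame, scores: dict[str, float], min_n: int = 3
) -> pd.DataFrame:
    """Pearson correlation of each integrated component against the clinical
    score, per group x muscle x direction; participant-level values are means
    across magnitudes. Cells with fewer than min_n participants or zero
    variance are marked NA."""
    rows = []
    per = (
        integrals.groupby(
            ["group", "muscle", "direction", "component", "participant"], sort=True
        )["integral"].mean().reset_index()
    )
    for (group, muscle, direction, comp), sub in per.groupby(
        ["group", "muscle", "direction", "component"], sort=True
    ):
        x = sub["integral"].to_numpy(dtype=float)
        y = np.array([scores.get(p, np.nan) for p in sub["participant"]])
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        rec = {
            "group": group, "muscle": muscle, "direction": direction,
            "component": comp, "n": int(x.size),
        }
        if x.size < min_n or np.ptp(x) == 0 or np.ptp(y) == 0:
            rec.update(r=np.nan, p=np.nan)
        else:
            r, p = stats.pearsonr(x, y)
            rec.update(r=float(r), p=float(p))
        rows.append(rec)
    return pd.DataFrame(rows)


def _fit_result_record(r: FitResult) -> dict:
    loop = lambda p: {
        "k_d": p.k_d, "k_v": p.k_v, "k_a": p.k_a, "delay": p.delay, "sign_mode": p.sign_mode,
    }
    return {
        "participant": r.participant_id,
        "muscle": r.model.kind,
        "direction": r.direction,
        "magnitude": r.magnitude,
        "loop1": loop(r.model.loop1),
        "loop2": loop(r.model.loop2),
        "seeds": [loop(r.seeds[0]), loop(r.seeds[1])],
        "cost": r.cost,
        "seed_cost": r.seed_cost,
        "r2": r.r2,
        "vaf": r.vaf,
        "integrals": r.integrals,
        "diagnostics": r.diagnostics,
    }


def run_pipeline(
    cohort_dir: str | Path, out_dir: str | Path, cfg: PipelineConfig | None = None
) -> Path:
    """Full run on a cohort directory; returns the results directory.

    Writes condition averages, per-fit JSON records, the long-format tables
    (integrals, latencies, fit quality, peak excursions, clinical scores),
    the cohort summary, component-score correlations, an exclusions report
    and a provenance JSON. Deterministic given cohort + config + seed.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        trials, registry = load_cohort(cohort_dir)
        with open(Path(cohort_dir) / "manifest.json") as fh:
            emg_kind = json.load(fh).get("emg_kind", "envelope")
        groups = {pid: entry["group"] for pid, entry in registry.items()}
        scores = {pid: entry["clinical_score"] for pid, entry in registry.items()}
        log.info("loaded %d trials, %d participants", len(trials), len(registry))

        averages, exclusions = preprocess_cohort(trials, cfg, emg_kind=emg_kind)
        n_conditions = len({_condition_key(tr) for tr in trials})
        assert len(averages) + len(exclusions) == n_conditions
        log.info("%d conditions averaged, %d excluded", len(averages), len(exclusions))

        avg_dir = out / "condition_averages"
        avg_dir.mkdir(exist_ok=True)
        for key, cell in sorted(averages.items()):
            ag = cell[cfg.muscles[0]]
            df = pd.DataFrame(
                {
                    "time_s": ag.emg.t,
                    "com_disp_m": ag.com.d.values,
                    "com_vel_mps": ag.com.v.values,
                    "com_acc_mps2": ag.com.a.values,
                    **{f"emg_{m}": cell[m].emg.values for m in cfg.muscles},
                }
            )
            df.to_csv(avg_dir / ("_".join(key) + ".csv"), index=False, float_format="%.10g")
        with open(out / "exclusions.json", "w") as fh:
            json.dump(
                [
                    {
                        "participant": e.participant_id,
                        "direction": e.direction,
                        "magnitude": e.magnitude,
                        "n_nonstepped": e.n_nonstepped,
                        "reason": e.reason,
                    }
                    for e in exclusions
                ],
                fh, indent=1, sort_keys=True,
            )

        results = fit_cohort(averages, cfg)
        with open(out / "fit_results.json", "w") as fh:
            json.dump([_fit_result_record(r) for r in results], fh, indent=1, sort_keys=True)

        tables = _result_tables(results, averages, groups, scores)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False, float_format="%.10g")
        summarize_cohort(tables).to_csv(out / "cohort_summary.csv", index=False, float_format="%.10g")
        correlate_components(tables["integrals"], scores).to_csv(
            out / "correlations.csv", index=False, float_format="%.10g"
        )

        cfg_json = json.dumps(cfg.to_dict(), sort_keys=True)
        import scipy  # local import to keep provenance self-contained

        provenance = {
            "package": "comfeedback",
            "version": __version__,
            "config": cfg.to_dict(),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": cfg.seed,
            "cohort_dir": str(cohort_dir),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        }
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, sort_keys=True)
        log.info("pipeline complete: %d fits", len(results))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
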