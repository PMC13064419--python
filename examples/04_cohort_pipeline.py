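"""Run the full pipeline on a small synthetic cohort.

Generates 2 participants (one older adult, one with PD), writes the cohort
directory, and runs preprocessing -> fitting -> summary tables. Uses a
reduced stage-1 search to keep the demo around a minute; drop the custom
FitConfig for full-effort fits.
"""
import tempfile
from pathlib import Path

import pandas as pd

import comfeedback as cf
from comfeedback.fitting import FitConfig
from comfeedback.pipeline import PipelineConfig, run_pipeline

root = Path(tempfile.mkdtemp(prefix="comfb_"))
trials, registry = cf.generate_cohort(
    1, 1, trials_per_condition=3, seed=7, stepped_fraction=0.0, noise_sd=0.02
)
cohort = cf.write_cohort(root / "cohort", trials, registry)
print(f"cohort: {len(trials)} trials, {len(registry)} participants -> {cohort}")

cfg = PipelineConfig(fit=FitConfig(grid_step=0.01, multistart=1))
out = run_pipeline(cohort, root / "results", cfg)

lat = pd.read_csv(out / "latencies.csv")
print("\nmean fitted latencies (ms) by loop:")
print(lat.groupby("loop")["latency_ms"].mean().round(1).to_string())
qual = pd.read_csv(out / "fit_quality.csv")
print("\nmedian fit quality by muscle:")
print(qual.groupby("muscle")[["r2", "vaf"]].median().round(3).to_string())
print(f"\nall tables in {out}")
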