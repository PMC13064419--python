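"""Fit the dual-loop model to one synthetic condition and compare against
the known ground truth (forward/inverse closure).

Generates a noise-free agonist envelope from known loop parameters, runs the
two-stage constrained fit (delay-grid seeding, residual backfitting, bounded
joint refinement) and prints recovered vs true parameters.
"""
import dataclasses

import numpy as np

import comfeedback as cf
from comfeedback.synthetic import magnitude_spec, to_agonist_frame

com_lab = cf.simulate_com_kinematics(
    cf.make_platform_profile(magnitude_spec("small")), cf.BodyModel()
)
ag = to_agonist_frame(com_lab, "forward")
com = cf.ComKinematics(*(s.slice_time(-0.2, 1.2) for s in (ag.d, ag.v, ag.a)))

truth = dataclasses.replace(cf.default_ground_truth(), baseline=0.0, noise_sd=0.0)
emg = cf.generate_emg(com, truth, "agonist", seed=0)
avg = cf.ConditionAverage(emg, com, 3, "P001", "forward", "small")

res = cf.fit_condition(avg, "agonist")
print(f"fit quality: R^2 = {res.r2:.4f}, VAF = {res.vaf:.2f}%, cost = {res.cost:.2e}")
for name, tp, fp in [
    ("LLR1", truth.agonist_llr1, res.model.loop1),
    ("LLR2", truth.agonist_llr2, res.model.loop2),
]:
    print(f"{name}: delay true {tp.delay*1e3:.1f} ms -> fitted {fp.delay*1e3:.1f} ms")
    print(f"      gains true (k_d, k_v, k_a) = {np.round(tp.gains, 3).tolist()}")
    print(f"      gains fitted               = {np.round(fp.gains, 3).tolist()}")
print("Sub-millisecond delay recovery indicates the staged search found the "
      "global basin; weakly contributing gains are the least constrained.")
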