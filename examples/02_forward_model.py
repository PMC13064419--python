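"""Reconstruct agonist and antagonist EMG envelopes from delayed CoM feedback.

Each muscle is the sum of two rectified feedback loops. The agonist combines
a brainstem-latency loop (LLR1, ~119 ms) and a cortical-latency loop (LLR2,
~200 ms); the antagonist combines a stabilizing loop (driven by kinematics
that stretch it, at the deceleration reversal) and a destabilizing loop
(driven by kinematics that shorten it). Component areas are trapezoidal
integrals over the 0-0.8 s window.
"""
import comfeedback as cf
from comfeedback.metrics import integrate_component
from comfeedback.synthetic import magnitude_spec, to_agonist_frame

com_lab = cf.simulate_com_kinematics(
    cf.make_platform_profile(magnitude_spec("small")), cf.BodyModel()
)
com = to_agonist_frame(com_lab, "forward")
truth = cf.default_ground_truth()

rec_ag = cf.reconstruct(com, truth.agonist_model())
rec_an = cf.reconstruct(-com, truth.antagonist_model())
win = (0.0, 0.8)
print("agonist:")
print(f"  LLR1 area  {integrate_component(rec_ag.loop1, win):.4f} (norm EMG * s)")
print(f"  LLR2 area  {integrate_component(rec_ag.loop2, win):.4f}")
print("antagonist:")
print(f"  stabilizing area    {integrate_component(rec_an.loop1, win):.4f}")
print(f"  destabilizing area  {integrate_component(rec_an.loop2, win):.4f}")
acc, veldisp = cf.decompose_destabilizing(-com, truth.antag_destab)
print(f"  destabilizing split: acceleration part {integrate_component(acc, win):.4f}, "
      f"velocity+displacement part {integrate_component(veldisp, win):.4f}")
print("Destabilizing activity is an inappropriate response to the initial "
      "perturbation; its acceleration component dominates here.")
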