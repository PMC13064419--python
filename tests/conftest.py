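"""Shared fixtures: small-perturbation kinematics and noise-free ground truth."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import comfeedback as cf
from comfeedback.synthetic import magnitude_spec, to_agonist_frame


@pytest.fixture(scope="session")
def body():
    return cf.BodyModel()


@pytest.fixture(scope="session")
def small_platform():
    return cf.make_platform_profile(magnitude_spec("small"))


@pytest.fixture(scope="session")
def com_lab(small_platform, body):
    return cf.simulate_com_kinematics(small_platform, body)


@pytest.fixture(scope="session")
def com_agonist(com_lab):
    """Agonist-frame CoM kinematics on the [-0.2, 1.2) epoch grid."""
    ag = to_agonist_frame(com_lab, "forward")
    return cf.ComKinematics(*(s.slice_time(-0.2, 1.2) for s in (ag.d, ag.v, ag.a)))


@pytest.fixture(scope="session")
def truth_clean():
    """Population-mean ground truth with no baseline and no noise."""
    return dataclasses.replace(cf.default_ground_truth(), baseline=0.0, noise_sd=0.0)


def com_for(muscle: str, com_agonist):
    return com_agonist if muscle == "agonist" else -com_agonist


@pytest.fixture(scope="session")
def clean_condition(com_agonist, truth_clean):
    """Factory: noise-free condition average for one muscle at one magnitude."""

    def make(muscle: str = "agonist", magnitude: str = "small") -> cf.ConditionAverage:
        emg = cf.generate_emg(com_agonist, truth_clean, muscle, seed=0, magnitude=magnitude)
        return cf.ConditionAverage(emg, com_agonist, 3, "P001", "forward", magnitude)

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
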