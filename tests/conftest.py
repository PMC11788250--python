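"""Shared fixtures: schedules, a reference input, and small synthetic fits.

Expensive multistart ensembles used by several identifiability tests are
session-scoped so they are computed once.
"""

import numpy as np
import pytest

from mokin import FrameSchedule, ORGAN_IDS
from mokin.fitting import (
    DEFAULT_NOISE_SC,
    MultiOrganKineticModel,
    build_param_spec,
    noise_sigma_from_data,
)
from mokin.synthetic import default_ground_truth, noiseless_frames, simulate_dataset


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def spec():
    return build_param_spec()


@pytest.fixture(scope="session")
def subject():
    """Ground truth plus noiseless and noisy realizations of one subject."""
    gt = default_ground_truth(0)
    clean = noiseless_frames(gt)
    noisy, sigma = simulate_dataset(gt, rng=1000, return_sigma=True)
    return {"gt": gt, "clean": clean, "noisy": noisy, "sigma": sigma}


def as_dict(df):
    return {o: df[o].to_numpy() for o in ORGAN_IDS}


@pytest.fixture(scope="session")
def noiseless_problem(subject, schedule):
    """Noiseless data with model-based weights (for exact-recovery checks)."""
    gt = subject["gt"]
    data = as_dict(subject["clean"])
    sigma = noise_sigma_from_data(
        data, schedule, {o: DEFAULT_NOISE_SC[o] for o in ORGAN_IDS}
    )
    return {"gt": gt, "data": data, "sigma": sigma, "idif": gt.idif_true}


@pytest.fixture(scope="session")
def short_scale_fit(subject):
    """A modest short-scale multistart fit of the reference subject."""
    return MultiOrganKineticModel(
        scale="short", n_starts=40, seed=0, max_nfev=60
    ).fit(subject["noisy"])
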