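import numpy as np
import pandas as pd
import pytest

from metidx import synthetic_data as syn
from metidx import respirometry as resp
from metidx import published_parameters


@pytest.fixture(scope="session")
def published():
    return published_parameters()


@pytest.fixture(scope="session")
def default_config():
    return syn.SyntheticConfig()


@pytest.fixture(scope="session")
def noiseless_cohort():
    """One noiseless cohort: (trials, per-trial truth table)."""
    truth = syn.PlantedTruth(seed=11, noise_sd_mr=0.0)
    return syn.generate_respirometry_cohort(syn.SyntheticConfig(), truth)


@pytest.fixture(scope="session")
def small_world():
    """A compact planted world for SDM unit tests: environment grids,
    occurrence points and the truth/config that produced them."""
    truth = syn.PlantedTruth(seed=5)
    config = syn.SyntheticConfig(contemporary_years=(2005, 2006),
                                 future_years=(2095, 2096),
                                 n_occurrences=120)
    env = syn.generate_environment(config, truth)
    occ = syn.generate_occurrences(env, truth, config)
    return {"truth": truth, "config": config, "env": env, "occurrences": occ}


def make_trial(routine_mr=None, post_chase_mr=None, hypoxia=None,
               temp=16.0, mass=1.0, trial_id="t0"):
    """Hand-built trial from raw per-phase values.

    ``hypoxia`` is a list of (o2_sat, mr) pairs, descending saturation.
    """
    rows = []
    t = 0.0
    for mr in (routine_mr if routine_mr is not None else [2.0] * 12):
        rows.append((t, mr, 95.0, "routine"))
        t += 20.0
    for mr in (post_chase_mr or []):
        rows.append((t, mr, 95.0, "post_chase"))
        t += 5.0
    for sat, mr in (hypoxia or []):
        rows.append((t, mr, sat, "hypoxia"))
        t += 5.0
    df = pd.DataFrame(rows, columns=["time_min", "mr", "o2_sat", "phase"])
    return resp.RespirometryTrial(trial_id=trial_id, mass=mass, test_temp=temp,
                                  measurements=df)
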