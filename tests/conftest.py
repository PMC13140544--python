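import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from stnspot.pipeline import RunConfig, process_hemisphere
from stnspot.spectral import summarize_ers
from stnspot.synthcohort import SynthConfig, simulate_cohort

warnings.filterwarnings("ignore", message="fewer than 100 surrogate draws")


@pytest.fixture(scope="session")
def run_cfg():
    cfg = RunConfig(seed=11)
    cfg.n_surrogates = 200
    return cfg


@pytest.fixture(scope="session")
def cohort_static(run_cfg):
    """Sixteen fully synthesized hemispheres at the default trial count.

    Sources are spatially static (drift scale 0) so envelope-timing estimands
    are isolated from the selection-drift interaction; hotspot drift recovery
    has its own dedicated cohorts.
    """
    synth = dataclasses.replace(
        run_cfg.synth, n_hemispheres=16, n_trials=18, rest_dur_s=20.0,
        fs_raw=800.0, rng_seed=11, prop_scale_range=(0.0, 0.0),
    )
    recs, gts, stn = simulate_cohort(synth)
    return recs, gts, stn


@pytest.fixture(scope="session")
def processed_static(cohort_static, run_cfg):
    """End-to-end preprocess + ERS for the static 16-hemisphere cohort."""
    recs, gts, stn = cohort_static
    tensors, views = [], []
    for rec in recs:
        tensor, view, _, _ = process_hemisphere(rec, run_cfg)
        tensors.append(tensor)
        views.append(view)
    summary = pd.concat([summarize_ers(t) for t in tensors], ignore_index=True)
    return tensors, views, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
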