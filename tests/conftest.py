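import numpy as np
import pandas as pd
import pytest

from streamresp import synthetic
from streamresp.pipeline import RunConfig, process_cohort
from streamresp.traces import MO2Series


def make_series(
    mo2,
    temps=None,
    fish_id="fish",
    cycle_s=600.0,
    measure_s=360.0,
    mass_kg=0.02,
    chamber_volume_l=2.0,
):
    """Hand-built MO2Series: one entry per 10-min cycle."""
    mo2 = np.asarray(mo2, dtype=float)
    if temps is None:
        temps = np.full_like(mo2, 18.0)
    mid = measure_s / 2.0 + cycle_s * np.arange(len(mo2))
    entries = pd.DataFrame(
        {
            "cycle_index": np.arange(len(mo2)),
            "mid_time_s": mid,
            "mo2": mo2,
            "mean_temp_c": np.asarray(temps, dtype=float),
        }
    )
    return MO2Series(
        fish_id=fish_id,
        entries=entries,
        chamber_volume_l=chamber_volume_l,
        mass_kg=mass_kg,
    )


@pytest.fixture(scope="session")
def noiseless_truth():
    return synthetic.SimFishTruth(
        fish_id="NL-1",
        mass_g=20.0,
        fork_length_mm=126.0,
        smr_ref=2.0,
        t_ref_c=18.0,
        q10_true=2.0,
        epoc_magnitude=8.0,
        epoc_rate_k=0.1,
        ctmax_true_mean=30.0,
        ctmax_true_sd=0.2,
    )


@pytest.fixture(scope="session")
def noiseless_design():
    return synthetic.TrialDesign(
        duration_h=18.0,
        sample_interval_s=5.0,
        noise_sd=0.0,
        background_fraction=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_truth, noiseless_design):
    trace, gt = synthetic.simulate_trial(
        noiseless_truth, noiseless_design, synthetic.constant_profile(18.0)
    )
    return trace, gt


@pytest.fixture(scope="session")
def default_cohort():
    design = synthetic.TrialDesign(sample_interval_s=5.0, seed=0)
    return synthetic.simulate_cohort(synthetic.default_scenario(seed=0, design=design))


@pytest.fixture(scope="session")
def default_cohort_result(default_cohort):
    return process_cohort(default_cohort, RunConfig(seed=0))
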