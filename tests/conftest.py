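import numpy as np
import pandas as pd
import pytest

from penguinforage import synthetic as syn


@pytest.fixture(scope="session")
def truth():
    return syn.default_truth(seed=0)


@pytest.fixture(scope="session")
def small_truth():
    """A scaled-down study (few birds, short deployments) for fast tests."""
    t = syn.default_truth(seed=0)
    t.n_birds_per_stage = 3
    t.isotope_n_per_stage = 3
    t.gps_birds = {"incubation": 1, "chick-rearing": 1}
    t.deployment_days = (4.0, 5.0)
    t.class_params["krill"].n_birds = 4
    t.class_params["fish"].n_birds = 2
    return t


@pytest.fixture(scope="session")
def small_study(small_truth):
    return syn.generate_population(small_truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dive_table():
    """Moderate two-stage dive table generated straight from the truth
    (no 1 Hz rendering), for mixed-model tests."""
    from penguinforage._rng import child_rng

    truth = syn.default_truth(seed=5)
    rows = []
    for stage in ("incubation", "chick-rearing"):
        for b in range(12):
            r = child_rng(5, "bird", stage, b)
            shift = float(r.normal(0.0, truth.depth_individual_sd_m))
            span = float(r.uniform(*truth.deployment_days)) * 86400
            trips = syn.simulate_trip_schedule(truth.stage_params[stage], span, r)
            dv = syn.simulate_dive_table(f"{stage[:3]}{b}", stage, trips, truth, r, shift)
            rows.append(dv)
    data = pd.concat(rows, ignore_index=True)
    data["trip_id"] = data.bird_id + "/" + data.trip_index.astype(str)
    return data
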