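import datetime as dt

import pytest
from hypothesis import settings

import approvoi as av

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from approvoi.synthetic import SimSpec, gen_forecast, gen_params, gen_trials


@pytest.fixture(scope="session")
def packaged_trials():
    return av.datasets.synthetic_evidence()


@pytest.fixture(scope="session")
def packaged_dist():
    return av.datasets.synthetic_params()


@pytest.fixture(scope="session")
def policy_schedule():
    return av.datasets.synthetic_policy_schedule()


@pytest.fixture(scope="session")
def toy_params():
    """Deterministic two-cycle configuration with closed-form outputs:
    no discounting, full utility, identical ward/ICU pathways."""
    return av.ModelParams(
        p_death_28d_ctrl=0.36,
        p_icu=0.3,
        los_ward=2.0,
        los_icu=2.0,
        c_day_ward=1000.0,
        c_day_icu=1000.0,
        c_drug=500.0,
        u_hosp=1.0,
        u_post_ward=1.0,
        u_post_icu=1.0,
        le_post_ward=10.0,
        le_post_icu=10.0,
        wtp=100_000.0,
        disc=0.0,
    )


@pytest.fixture(scope="session")
def pooled_meta(packaged_trials):
    return av.pool_random_effects(packaged_trials)


@pytest.fixture(scope="session")
def psa(packaged_dist, pooled_meta):
    return av.sample_psa(packaged_dist, pooled_meta, n_iter=4000, seed=123)


@pytest.fixture()
def three_trials():
    studies = [(15, 120, 25, 118), (8, 60, 6, 62), (40, 300, 55, 295)]
    return [
        av.TrialComparison(f"S{i}", dt.date(2020, 1, i + 1), a, n1, c, n2)
        for i, (a, n1, c, n2) in enumerate(studies)
    ]


@pytest.fixture(scope="session")
def small_store():
    spec = SimSpec(master_seed=5)
    return gen_forecast(spec, ["2020-10-01", "2021-03-01", "2021-12-20"])
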