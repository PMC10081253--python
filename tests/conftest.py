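import numpy as np
import pytest

import schoolkit as sk


@pytest.fixture(scope="session")
def arena():
    return sk.ArenaGeometry(radius_cm=17.0, center_xy=(0.0, 0.0),
                            radius_px=500.0, depth_mm=25.0)


@pytest.fixture(scope="session")
def cohort():
    return sk.CohortSpec(population="surface", age_dpf=70,
                         mean_body_length_cm=2.2, mean_swim_speed_cm_s=5.0)


@pytest.fixture(scope="session")
def small_trial():
    """One short schooling trial used by cheap structural tests."""
    cfg, _ = sk.make_preset("schooling", duration_s=30.0, seed=2)
    return sk.simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_null_trials():
    """Six short independent-walker trials (shared cheap null fixture)."""
    return sk.simulate_cohort("null_random", n_trials=6, seed=4,
                              duration_s=40.0)


@pytest.fixture(scope="session")
def schooling_trials():
    """Study-scale schooling cohort: 12 trials of 120 s."""
    return sk.simulate_cohort("schooling", n_trials=12, seed=11)


@pytest.fixture(scope="session")
def null_trials():
    """Study-scale independent-walker cohort: 12 trials of 120 s."""
    return sk.simulate_cohort("null_random", n_trials=12, seed=5)


@pytest.fixture(scope="session")
def asocial_trials():
    """Study-scale wall-following (asocial) cohort: 12 trials of 120 s."""
    return sk.simulate_cohort("asocial_wall", n_trials=12, seed=3)


@pytest.fixture(scope="session")
def schooling_analysis(schooling_trials):
    from schoolkit.pipeline import analyze_cohort

    return analyze_cohort(schooling_trials, seed=11)


@pytest.fixture(scope="session")
def asocial_analysis(asocial_trials):
    from schoolkit.pipeline import analyze_cohort

    return analyze_cohort(asocial_trials, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
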