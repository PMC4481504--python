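import pytest

import weightmsm as wm


@pytest.fixture(scope="session")
def confounded_panel():
    """One moderate confounded cohort shared by estimator tests."""
    params = wm.default_params("confounded", n_subjects=2500, seed=42)
    return wm.simulate_cohort(params)


@pytest.fixture(scope="session")
def person_periods(confounded_panel):
    pp, _ = wm.prepare(confounded_panel)
    return pp


@pytest.fixture(scope="session")
def exposure_pair(person_periods):
    return wm.fit_exposure_models(person_periods, design="M4")


@pytest.fixture(scope="session")
def weight_set(person_periods, exposure_pair):
    cens = wm.fit_censoring_models(person_periods, design="M4")
    return wm.compute_stabilized_weights(person_periods, exposure_pair,
                                         censor_models=cens)
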