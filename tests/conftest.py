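"""Shared fixtures: model builds and the expensive reference simulations.

Simulation fixtures are session-scoped so each trajectory is integrated once
and reused by unit, property and acceptance tests alike.
"""

import pytest

from coagkin import (
    Scenario,
    build_hockin_mann,
    build_platelet_plasma,
    run_titration,
    simulate,
)


@pytest.fixture(scope="session")
def pp_model():
    return build_platelet_plasma()


@pytest.fixture(scope="session")
def hm_model():
    return build_hockin_mann()


@pytest.fixture(scope="session")
def hm_siia_model():
    return build_hockin_mann(with_detection=True)


@pytest.fixture(scope="session")
def tc_resting(pp_model):
    """Resting 5x-diluted blood, no added TF, eps0 = 0.01."""
    return simulate(pp_model, Scenario())


@pytest.fixture(scope="session")
def tc_preactivated(pp_model):
    """Same well with platelets fully pre-activated at t = 0."""
    return simulate(pp_model, Scenario(eps0_override=1.0))


@pytest.fixture(scope="session")
def tc_whole_blood_tf(pp_model):
    """Undiluted blood stimulated with 5 pM lipidated TF."""
    sc = Scenario(dilution_factor=1.0, additions={"TF": 5e-12}, lipidated_tf=True)
    return simulate(pp_model, sc)


@pytest.fixture(scope="session")
def tf_titration(pp_model):
    """TF dose-response, 20 fM - 20 pM, lipidated-TF mode."""
    return run_titration(
        pp_model, Scenario(lipidated_tf=True), "TF", [2e-14, 2e-13, 2e-12, 2e-11]
    )


@pytest.fixture(scope="session")
def xa_titration(pp_model):
    """Xa dose-response at 1, 10 and 100 pM."""
    return run_titration(pp_model, Scenario(), "Xa", [1e-12, 1e-11, 1e-10])
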