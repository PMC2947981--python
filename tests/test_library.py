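"""Model builders and scenario transformation."""

import dataclasses

import pytest

from coagkin import (
    Scenario,
    apply_scenario,
    build_hockin_mann,
    build_platelet_plasma,
)
from coagkin.experiments import model_hash
from coagkin.network import ModelSpec


def _conc(model, name):
    return next(s.initial_conc for s in model.species if s.name == name)


def test_platelet_plasma_structure(pp_model):
    assert len(pp_model.species) == 76
    assert len(pp_model.reactions) == 57
    assert pp_model.activation is not None


def test_hockin_mann_structure(hm_model, hm_siia_model):
    assert len(hm_model.species) == 34
    assert len(hm_model.reactions) == 27
    assert hm_model.activation is None
    assert len(hm_siia_model.species) == 38
    assert len(hm_siia_model.reactions) == 28


@pytest.mark.parametrize(
    "name,conc",
    [
        ("II", 1.4e-6),
        ("ATIII", 3.4e-6),
        ("XII", 3.4e-7),
        ("PK", 4.5e-7),
        ("XI", 3.1e-8),
        ("CTI", 4.2e-6),
        ("C1inh", 2.5e-6),
        ("alpha1AT", 4.5e-5),
        ("alpha2AP", 1.0e-6),
        ("Fbg", 9.0e-6),
        ("Boc-VPR-MCA", 1.0e-5),
        ("TF", 0.0),
    ],
)
def test_tabulated_initial_conditions(pp_model, name, conc):
    assert _conc(pp_model, name) == conc


def test_xiia_source_rate(pp_model):
    assert pp_model.reaction(29).rates.k_first == 5e-4


def test_xi_autoactivation_default_is_quarter_of_literature(pp_model):
    assert pp_model.reaction(40).rates.k_on == pytest.approx(3.19e6 / 4)
    alt = build_platelet_plasma(xi_autoactivation_rate=3.19e6)
    assert alt.reaction(40).rates.k_on == 3.19e6


def test_builders_are_idempotent():
    assert model_hash(build_platelet_plasma()) == model_hash(build_platelet_plasma())
    assert model_hash(build_hockin_mann()) == model_hash(build_hockin_mann())


def test_model_serialization_round_trip(pp_model):
    clone = ModelSpec.from_dict(pp_model.to_dict())
    assert model_hash(clone) == model_hash(pp_model)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_dilution_arithmetic(pp_model):
    m = apply_scenario(pp_model, Scenario(dilution_factor=5))
    assert _conc(m, "II") == pytest.approx(2.8e-7)
    # CTI: 4.2 uM in the syringe -> 0.84 uM in the well
    assert _conc(m, "CTI") == pytest.approx(8.4e-7)


def test_additions_are_final_in_well_concentrations(pp_model):
    sc = Scenario(dilution_factor=5, additions={"TF": 5e-12})
    m = apply_scenario(pp_model, sc)
    assert _conc(m, "TF") == pytest.approx(5e-12)  # never diluted


def test_dilution_then_addition_order_is_pinned(pp_model):
    # an addition equal to the tabulated concentration ends up on top of the
    # *diluted* baseline, not the undiluted one
    sc = Scenario(dilution_factor=5, additions={"VIIa": 1e-9})
    m = apply_scenario(pp_model, sc)
    assert _conc(m, "VIIa") == pytest.approx(1e-10 / 5 + 1e-9)


def test_knockouts_scale_initial_concentration(pp_model):
    m = apply_scenario(pp_model, Scenario(knockouts={"XII": 0.0, "XI": 0.01}))
    assert _conc(m, "XII") == 0.0
    assert _conc(m, "XI") == pytest.approx(3.1e-8 / 5 * 0.01)


def test_substrate_repipetting_switch(pp_model):
    default = apply_scenario(pp_model, Scenario())
    assert _conc(default, "Boc-VPR-MCA") == pytest.approx(2e-6)
    well = apply_scenario(pp_model, Scenario(substrate_at_well_conc=True))
    assert _conc(well, "Boc-VPR-MCA") == pytest.approx(1e-5)


def test_eps0_override_replaces_basal_activation(pp_model):
    m = apply_scenario(pp_model, Scenario(eps0_override=1.0))
    assert m.activation.eps0 == 1.0
    assert pp_model.activation.eps0 == 0.01  # original untouched


def test_unknown_addition_is_an_error(pp_model):
    with pytest.raises(KeyError):
        apply_scenario(pp_model, Scenario(additions={"Ghost": 1e-9}))


def test_scenario_validation():
    with pytest.raises(ValueError):
        Scenario(dilution_factor=0.5)
    with pytest.raises(ValueError):
        Scenario(knockouts={"XI": 1.5})
    with pytest.raises(ValueError):
        Scenario(eps0_override=0.0)


def test_scenario_round_trip_through_dict():
    sc = Scenario(additions={"TF": 5e-12}, knockouts={"XI": 0.01}, eps0_override=0.5)
    assert Scenario.from_dict(sc.to_dict()) == sc


def test_lipidated_flag_propagates(pp_model):
    m = apply_scenario(pp_model, Scenario(lipidated_tf=True))
    assert m.lipidated_tf_mode
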