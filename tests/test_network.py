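"""Reaction data model, rate-constant helpers and the mass-action RHS."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coagkin import (
    ActivationParams,
    ModelSpec,
    RateConstants,
    ReactionDef,
    SpeciesDef,
    assemble_rhs,
    build_hockin_mann,
    build_platelet_plasma,
    effective_off_rate,
    km_to_off_rate,
    validate_model,
)
from coagkin.library import HM_KM_KD, PP_KM_KD
from coagkin.network import ModelError, atoms_of


# ---------------------------------------------------------------------------
# km_to_off_rate
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "km,k_on,k_cat,expected",
    [
        (6.1e-5, 1.0e8, 53.8, 6.1e3),  # fluorogenic-substrate chemistry
        (2.0e-6, 1.0e8, 5.7e-4, 200.0),  # XIIa activation of XI
    ],
)
def test_off_rate_from_km(km, k_on, k_cat, expected):
    assert km_to_off_rate(km, k_on, k_cat) == pytest.approx(expected, rel=0.02)


def test_off_rate_vanishes_for_purely_catalytic_km():
    k_on, k_cat = 1e8, 7.7
    assert km_to_off_rate(k_cat / k_on, k_on, k_cat) == pytest.approx(0.0, abs=1e-9)


def test_off_rate_negative_result_is_an_error():
    with pytest.raises(ModelError, match="reaction 45"):
        km_to_off_rate(1e-9, 1e6, 53.8, reaction_id=45)


@settings(max_examples=50, derandomize=True)
@given(
    km=st.floats(1e-12, 1e-3),
    k_on=st.floats(1e3, 1e9),
    k_cat=st.floats(0, 100),
)
def test_off_rate_round_trips_km(km, k_on, k_cat):
    """(k_off + k_cat)/k_on must reproduce the K_m it was derived from."""
    if km * k_on < k_cat:
        return
    k_off = km_to_off_rate(km, k_on, k_cat)
    assert (k_off + k_cat) / k_on == pytest.approx(km, rel=1e-12)


# ---------------------------------------------------------------------------
# epsilon-modulated off-rates
# ---------------------------------------------------------------------------

def _rxn(model, rid):
    return model.reaction(rid)


def test_effective_off_rate_fully_activated_matches_eta(pp_model):
    # TF-VIIa dissociation: eta = 0.01 tightens K_d to 1.3e-12 M at eps = 1
    r2 = _rxn(pp_model, 2)
    k = effective_off_rate(r2, 3.1e-3, 1.0)
    assert k == pytest.approx(3.1e-5)
    assert k / r2.rates.k_on == pytest.approx(1.3e-12, rel=0.05)


def test_effective_off_rate_resting_restores_reference(pp_model):
    # eta/eps = 1 at eps = 0.01 for eta = 0.01 reactions
    assert effective_off_rate(_rxn(pp_model, 2), 3.1e-3, 0.01) == pytest.approx(3.1e-3)


def test_effective_off_rate_eta_one(pp_model):
    assert effective_off_rate(_rxn(pp_model, 8), 2.4, 1.0) == pytest.approx(2.4)


def test_effective_off_rate_lipidated_freeze(pp_model):
    r = _rxn(pp_model, 2)
    frozen = effective_off_rate(r, 3.1e-3, 0.01, lipidated_tf_mode=True)
    assert frozen == pytest.approx(effective_off_rate(r, 3.1e-3, 1.0))
    # non-TF reactions still feel eps
    r11 = _rxn(pp_model, 11)
    assert effective_off_rate(r11, 5e-3, 0.5, lipidated_tf_mode=True) == pytest.approx(
        0.02 * 5e-3 / 0.5
    )


def test_effective_off_rate_domain_errors(pp_model):
    with pytest.raises(ModelError):
        effective_off_rate(_rxn(pp_model, 2), 3.1e-3, 0.0)
    with pytest.raises(ModelError):
        effective_off_rate(_rxn(pp_model, 9), 1.0, 0.5)  # no epsilon coupling


@pytest.mark.parametrize("rid,km", sorted(PP_KM_KD.items()))
def test_published_km_kd_round_trip_fully_activated(pp_model, rid, km):
    """(eta*k_off + k_cat)/k_on reproduces the published eps = 1 column."""
    r = pp_model.reaction(rid)
    eta = 1.0 if r.eta is None else r.eta
    k_off = eta * r.rates.k_off
    k_cat = r.rates.k_cat or 0.0
    assert (k_off + k_cat) / r.rates.k_on == pytest.approx(km, rel=0.05)


@pytest.mark.parametrize("rid,km", sorted(HM_KM_KD.items()))
def test_published_km_kd_round_trip_reference(hm_model, rid, km):
    r = hm_model.reaction(rid)
    k_cat = r.rates.k_cat or 0.0
    assert (r.rates.k_off + k_cat) / r.rates.k_on == pytest.approx(km, rel=0.05)


# ---------------------------------------------------------------------------
# ReactionDef invariants
# ---------------------------------------------------------------------------

def test_eta_requires_epsilon_mode():
    with pytest.raises(ModelError):
        ReactionDef(
            id=7, scheme="reversible_binding", reactants=("A", "B"),
            complex_="A=B", rates=RateConstants(k_on=1.0, k_off=1.0), eta=2.0,
        )


def test_on_rate_mode_reserved_for_subunit_dissociation():
    with pytest.raises(ModelError):
        ReactionDef(
            id=7, scheme="reversible_binding", reactants=("A", "B"),
            complex_="A=B", rates=RateConstants(k_on=1.0, k_off=1.0),
            eta=1.0, epsilon_mode="on_rate",
        )


# ---------------------------------------------------------------------------
# RHS assembly vs. hand-written mass action
# ---------------------------------------------------------------------------

def _tiny_model(with_activation=False):
    """3-species prothrombin conversion + epsilon-coupled binding."""
    species = [
        SpeciesDef("II", 1.4e-6),
        SpeciesDef("Xa", 1e-9, "enzyme"),
        SpeciesDef("IIa", 0.0, "enzyme"),
        SpeciesDef("Va", 1e-9, "cofactor"),
        SpeciesDef("Xa=Va", 0.0, "complex"),
    ]
    reactions = [
        ReactionDef(
            id=9, scheme="bimolecular_irreversible", reactants=("II", "Xa"),
            products=("IIa", "Xa"), rates=RateConstants(k_on=7.5e3),
        ),
        ReactionDef(
            id=17, scheme="reversible_binding", reactants=("Xa", "Va"),
            complex_="Xa=Va", rates=RateConstants(k_on=4.0e8, k_off=0.2),
            eta=0.04, epsilon_mode="off_rate",
        ),
    ]
    act = ActivationParams() if with_activation else None
    return ModelSpec(species=species, reactions=reactions, activation=act)


def _tiny_oracle(y, eps):
    """Independent hand-written derivative for _tiny_model."""
    ii, xa, iia, va, xava = y[:5]
    v9 = 7.5e3 * ii * xa
    v_on = 4.0e8 * xa * va
    v_off = (0.04 * 0.2 / eps) * xava
    return np.array([-v9, -v_on + v_off, v9, -v_on + v_off, v_on - v_off])


@pytest.mark.parametrize("with_activation", [False, True])
def test_rhs_matches_hand_written_oracle(with_activation):
    cm = assemble_rhs(_tiny_model(with_activation))
    rng = np.random.default_rng(42)
    for _ in range(100):
        y = np.zeros(cm.n_state)
        y[:5] = rng.uniform(0, 1e-6, 5)
        eps = rng.uniform(0.01, 1.0) if with_activation else 1.0
        y[cm.i_eps] = eps
        dy = cm(0.0, y)
        expected = _tiny_oracle(y, eps if with_activation else 1.0)
        if not with_activation:
            # frozen mode: off-rate is eta*k_off with eps = 1
            expected = _tiny_oracle(y, 1.0)
        np.testing.assert_allclose(dy[:5], expected, rtol=1e-12, atol=1e-30)


def test_rhs_zero_state_gives_zero_derivative(pp_model):
    cm = assemble_rhs(pp_model)
    y = np.zeros(cm.n_state)
    y[cm.i_eps] = pp_model.activation.eps0
    dy = cm(0.0, y)
    assert np.all(dy[: cm.i_eps] == 0.0)


def test_rhs_single_term_prothrombin_conversion(hm_model):
    """Only Xa and II present: d[IIa]/dt is the lone second-order term."""
    cm = assemble_rhs(hm_model)
    y = np.zeros(cm.n_state)
    y[cm.species_names.index("Xa")] = 1e-9
    y[cm.species_names.index("II")] = 1.4e-6
    y[cm.i_eps] = 1.0
    dy = cm(0.0, y)
    assert dy[cm.species_names.index("IIa")] == pytest.approx(
        7.5e3 * 1e-9 * 1.4e-6, rel=1e-12
    )


def test_rhs_conserves_moiety_totals_structurally(pp_model):
    """S^T w = 0 for every conserved moiety: exact at any state."""
    cm = assemble_rhs(pp_model)
    rng = np.random.default_rng(7)
    y = np.zeros(cm.n_state)
    y[: cm.i_eps] = rng.uniform(0, 1e-6, cm.i_eps)
    y[cm.i_eps] = 0.4
    dy = cm(0.0, y)
    for atom in ("TF", "CTI", "AMC", "Fbg"):
        w = cm.moiety_weights(atom)
        scale = np.abs(w[: cm.i_eps] * dy[: cm.i_eps]).max() + 1e-30
        assert abs(float(w @ dy)) / scale < 1e-10


def test_analytic_jacobian_matches_finite_differences(pp_model):
    """Central differences are exact for mass action (at most bilinear), so
    at a well-scaled state they must agree with the analytic Jacobian to
    rounding; the nonlinear activation rows are held to a looser tolerance."""
    cm = assemble_rhs(pp_model)
    rng = np.random.default_rng(3)
    y = np.zeros(cm.n_state)
    y[: cm.i_eps] = rng.uniform(0.5e-6, 2e-6, cm.i_eps)
    y[cm.i_eps] = 0.3
    y[cm.i_max] = 2e-9
    J = cm.jac(0.0, y)
    for j in range(cm.n_state):
        h = 1e-3 * max(abs(y[j]), 1e-10)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        col = (cm(0.0, yp) - cm(0.0, ym)) / (2 * h)
        scale = np.abs(col).max() + 1e-20
        np.testing.assert_allclose(
            J[: cm.i_eps, j], col[: cm.i_eps], rtol=1e-6, atol=1e-7 * scale
        )
        np.testing.assert_allclose(
            J[cm.i_eps :, j], col[cm.i_eps :], rtol=1e-3, atol=1e-5 * scale
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def test_validate_counts(pp_model, hm_model):
    rep = validate_model(pp_model)
    assert (rep.n_species, rep.n_reactions) == (76, 57)
    assert rep.ok
    rep_hm = validate_model(hm_model)
    assert (rep_hm.n_species, rep_hm.n_reactions) == (34, 27)
    assert rep_hm.ok


def test_validate_reports_unknown_species(pp_model):
    broken = dataclasses.replace(
        pp_model,
        reactions=pp_model.reactions
        + [
            ReactionDef(
                id=99, scheme="bimolecular_irreversible",
                reactants=("IIa", "Ghost"), products=("IIa=Ghost",),
                rates=RateConstants(k_on=1.0),
            )
        ],
    )
    rep = validate_model(broken)
    assert any("Ghost" in line for line in rep.unknown_species)


def test_complex_names_decompose_to_tracked_components(pp_model):
    """Every '='-joined complex resolves to species that exist in the model."""
    names = set(pp_model.species_names)
    atomic = {atom for n in names for atom in atoms_of(n)}
    for sp in pp_model.species:
        for atom, n in atoms_of(sp.name).items():
            assert atom in atomic and n >= 1


def test_builder_duplicate_species_rejected():
    m = build_platelet_plasma()
    m.species.append(m.species[0])
    with pytest.raises(ModelError):
        assemble_rhs(m)
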