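"""Canonical model builders and scenario transformation.

Two networks are provided:

* the classic extrinsic-pathway (tissue-factor) network of thrombin
  generation -- 34 species, 27 reactions, platelets implicitly fully
  activated (fixed rate constants);
* the extended platelet-plasma network -- 76 species, 57 reactions -- which
  adds a first-order XIIa source (contact activation leak), XII/prekallikrein
  reciprocal activation, XI activation and autoactivation, CTI and plasma
  inhibitors of the contact proteases, TF-independent VIIa activity on IX and
  X, fluorogenic thrombin-substrate detection chemistry, fibrin formation as
  a thrombin sink, and the continuous thrombin-driven platelet activation
  state eps that rescales membrane-dependent dissociation rates.

Scenarios transform a model for one well: dilution of all initial
concentrations, exogenous additions at final in-well concentration,
deficiency/antibody knockouts as initial-concentration scaling, platelet
pre-activation (eps0 override), and lipidated-TF mode.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

from .activation import ActivationParams
from .network import ModelSpec, RateConstants, ReactionDef, SpeciesDef

__all__ = [
    "Scenario",
    "build_hockin_mann",
    "build_platelet_plasma",
    "apply_scenario",
    "to_hockin_mann_limit",
    "XI_AUTOACTIVATION_RATE",
    "PP_KM_KD",
    "HM_KM_KD",
]

# Second-order rate of XI autoactivation on negative surfaces (1/M/s).  The
# literature estimate (3.19e6) comes from a model that considers either
# autoactivation or thrombin feedback on XI, not both; since this network
# carries thrombin feedback separately, a 4-fold lower value is the default.
XI_AUTOACTIVATION_RATE = 3.19e6 / 4.0


# ---------------------------------------------------------------------------
# species: (name, initial concentration M, role); first 34 rows are the
# classic extrinsic-pathway set, shared by both builders.
# ---------------------------------------------------------------------------

_SPECIES: list[tuple[str, float, str]] = [
    ("TF", 0.0, "cofactor"),
    ("VII", 1.0e-8, "zymogen"),
    ("TF=VII", 0.0, "complex"),
    ("VIIa", 1.0e-10, "enzyme"),
    ("TF=VIIa", 0.0, "complex"),
    ("Xa", 0.0, "enzyme"),
    ("IIa", 0.0, "enzyme"),
    ("X", 1.6e-7, "zymogen"),
    ("TF=VIIa=X", 0.0, "complex"),
    ("TF=VIIa=Xa", 0.0, "complex"),
    ("IX", 9.0e-8, "zymogen"),
    ("TF=VIIa=IX", 0.0, "complex"),
    ("IXa", 0.0, "enzyme"),
    ("II", 1.4e-6, "zymogen"),
    ("VIII", 7.0e-10, "zymogen"),
    ("VIIIa", 0.0, "cofactor"),
    ("IXa=VIIIa", 0.0, "complex"),
    ("IXa=VIIIa=X", 0.0, "complex"),
    ("VIIIa1-L", 0.0, "product"),
    ("VIIIa2", 0.0, "product"),
    ("V", 2.0e-8, "zymogen"),
    ("Va", 0.0, "cofactor"),
    ("Xa=Va", 0.0, "complex"),
    ("Xa=Va=II", 0.0, "complex"),
    ("mIIa", 0.0, "enzyme"),
    ("TFPI", 2.5e-9, "inhibitor"),
    ("Xa=TFPI", 0.0, "complex"),
    ("TF=VIIa=Xa=TFPI", 0.0, "complex"),
    ("ATIII", 3.4e-6, "inhibitor"),
    ("Xa=ATIII", 0.0, "complex"),
    ("mIIa=ATIII", 0.0, "complex"),
    ("IXa=ATIII", 0.0, "complex"),
    ("IIa=ATIII", 0.0, "complex"),
    ("TF=VIIa=ATIII", 0.0, "complex"),
    # --- detection chemistry -------------------------------------------------
    ("Boc-VPR-MCA", 1.0e-5, "substrate"),
    ("Boc-VPR-MCA=IIa", 0.0, "complex"),
    ("Boc-VPR", 0.0, "product"),
    ("AMC", 0.0, "product"),
    # --- contact pathway -----------------------------------------------------
    ("XII", 3.4e-7, "zymogen"),
    ("XIIa", 0.0, "enzyme"),
    ("XIIa=XII", 0.0, "complex"),
    ("PK", 4.5e-7, "zymogen"),
    ("XIIa=PK", 0.0, "complex"),
    ("K=XII", 0.0, "complex"),
    ("K", 0.0, "enzyme"),
    ("CTI", 4.2e-6, "inhibitor"),
    ("XIIa=CTI", 0.0, "complex"),
    ("C1inh", 2.5e-6, "inhibitor"),
    ("XIIa=C1inh", 0.0, "complex"),
    ("XIIa=ATIII", 0.0, "complex"),
    ("XI", 3.1e-8, "zymogen"),
    ("XI=IIa", 0.0, "complex"),
    ("XIa", 0.0, "enzyme"),
    ("XIIa=XI", 0.0, "complex"),
    ("XIa=ATIII", 0.0, "complex"),
    ("XIa=C1inh", 0.0, "complex"),
    ("alpha1AT", 4.5e-5, "inhibitor"),
    ("alpha2AP", 1.0e-6, "inhibitor"),
    ("XIa=alpha1AT", 0.0, "complex"),
    ("XIa=alpha2AP", 0.0, "complex"),
    ("XIa=IX", 0.0, "complex"),
    ("IXa=X", 0.0, "complex"),
    ("Xa=VIII", 0.0, "complex"),
    ("VIIa=IX", 0.0, "complex"),
    ("VIIa=X", 0.0, "complex"),
    # --- fibrin(ogen) --------------------------------------------------------
    ("Fbg", 9.0e-6, "substrate"),
    ("Fbg=IIa", 0.0, "complex"),
    ("Fbn1", 0.0, "product"),
    ("Fbn1=IIa", 0.0, "complex"),
    ("(Fbn1)2", 0.0, "complex"),
    ("(Fbn1)2=IIa", 0.0, "complex"),
    ("Fbn2", 0.0, "product"),
    ("Fbn2=IIa", 0.0, "complex"),
    ("(Fbn1)2=IIa=ATIII", 0.0, "complex"),
    ("Fbn1=IIa=ATIII", 0.0, "complex"),
    ("Fbn2=IIa=ATIII", 0.0, "complex"),
]

_N_HM_SPECIES = 34
_DETECTION_SPECIES = ("Boc-VPR-MCA", "Boc-VPR-MCA=IIa", "Boc-VPR", "AMC")


# ---------------------------------------------------------------------------
# reactions: compact rows
# (id, scheme, reactants, complex, products, rates-dict, eta, eps_mode, untracked)
# Schemes: rb = reversible_binding, bc = binding_catalysis,
#          bi = bimolecular_irreversible, fo = first_order, fs = first_order_sink
# For epsilon-coupled rows, k_off is the fixed-platelet reference constant and
# eta rescales it to the fully-activated (eps = 1) value.
# ---------------------------------------------------------------------------

_R = [
    (1, "rb", ("TF", "VII"), "TF=VII", (), dict(k_on=3.2e6, k_off=3.1e-3), 10.0, "off_rate", ()),
    (2, "rb", ("TF", "VIIa"), "TF=VIIa", (), dict(k_on=2.3e7, k_off=3.1e-3), 0.01, "off_rate", ()),
    (3, "bi", ("TF=VIIa", "VII"), None, ("TF=VIIa", "VIIa"), dict(k_on=4.4e5), None, "none", ()),
    (4, "bi", ("Xa", "VII"), None, ("Xa", "VIIa"), dict(k_on=1.3e7), None, "none", ()),
    (5, "bi", ("IIa", "VII"), None, ("IIa", "VIIa"), dict(k_on=2.3e4), None, "none", ()),
    (6, "bc", ("TF=VIIa", "X"), "TF=VIIa=X", ("TF=VIIa=Xa",), dict(k_on=2.5e7, k_off=1.05, k_cat=6.0), 0.01, "off_rate", ()),
    (7, "rb", ("TF=VIIa", "Xa"), "TF=VIIa=Xa", (), dict(k_on=2.2e7, k_off=19.0), 1.0, "off_rate", ()),
    (8, "bc", ("TF=VIIa", "IX"), "TF=VIIa=IX", ("TF=VIIa", "IXa"), dict(k_on=1.0e7, k_off=2.4, k_cat=1.8), 1.0, "off_rate", ()),
    (9, "bi", ("II", "Xa"), None, ("IIa", "Xa"), dict(k_on=7.5e3), None, "none", ()),
    (10, "bi", ("IIa", "VIII"), None, ("IIa", "VIIIa"), dict(k_on=2.0e7), None, "none", ()),
    (11, "rb", ("VIIIa", "IXa"), "IXa=VIIIa", (), dict(k_on=1.0e7, k_off=5.0e-3), 0.02, "off_rate", ()),
    (12, "bc", ("IXa=VIIIa", "X"), "IXa=VIIIa=X", ("IXa=VIIIa", "Xa"), dict(k_on=1.0e8, k_off=1.0e-3, k_cat=8.2), 0.01, "off_rate", ()),
    # VIIIa subunit dissociation: written complex-first in the source table,
    # with the epsilon-modulated constant in the forward (k_1) column.
    (13, "rb", ("VIIIa1-L", "VIIIa2"), "VIIIa", (), dict(k_on=2.2e4, k_off=6.0e-3), 0.01, "on_rate", ()),
    (14, "fo", ("IXa=VIIIa=X",), None, ("VIIIa1-L", "VIIIa2", "X", "IXa"), dict(k_first=1.0e-3), None, "none", ()),
    (15, "fo", ("IXa=VIIIa",), None, ("VIIIa1-L", "VIIIa2", "IXa"), dict(k_first=1.0e-3), None, "none", ()),
    (16, "bi", ("IIa", "V"), None, ("IIa", "Va"), dict(k_on=2.0e7), None, "none", ()),
    (17, "rb", ("Xa", "Va"), "Xa=Va", (), dict(k_on=4.0e8, k_off=0.2), 0.04, "off_rate", ()),
    (18, "bc", ("Xa=Va", "II"), "Xa=Va=II", ("Xa=Va", "mIIa"), dict(k_on=1.0e8, k_off=103.0, k_cat=63.5), 0.02, "off_rate", ()),
    (19, "bi", ("Xa=Va", "mIIa"), None, ("Xa=Va", "IIa"), dict(k_on=1.5e7), None, "none", ()),
    (20, "rb", ("Xa", "TFPI"), "Xa=TFPI", (), dict(k_on=9.0e5, k_off=3.6e-4), 1.0, "off_rate", ()),
    (21, "rb", ("TF=VIIa=Xa", "TFPI"), "TF=VIIa=Xa=TFPI", (), dict(k_on=3.2e8, k_off=1.1e-4), 100.0, "off_rate", ()),
    (22, "bi", ("TF=VIIa", "Xa=TFPI"), None, ("TF=VIIa=Xa=TFPI",), dict(k_on=5.0e7), None, "none", ()),
    (23, "bi", ("Xa", "ATIII"), None, ("Xa=ATIII",), dict(k_on=1.5e3), None, "none", ()),
    (24, "bi", ("mIIa", "ATIII"), None, ("mIIa=ATIII",), dict(k_on=7.1e3), None, "none", ()),
    (25, "bi", ("IXa", "ATIII"), None, ("IXa=ATIII",), dict(k_on=4.9e2), None, "none", ()),
    (26, "bi", ("IIa", "ATIII"), None, ("IIa=ATIII",), dict(k_on=7.1e3), None, "none", ()),
    (27, "bi", ("TF=VIIa", "ATIII"), None, ("TF=VIIa=ATIII",), dict(k_on=2.3e2), None, "none", ()),
    # --- thrombin detection chemistry (in solution; epsilon-independent) -----
    (28, "bc", ("Boc-VPR-MCA", "IIa"), "Boc-VPR-MCA=IIa", ("Boc-VPR", "AMC", "IIa"), dict(k_on=1.0e8, k_off=6.1e3, k_cat=53.8), None, "none", ()),
    # --- contact pathway -----------------------------------------------------
    (29, "fo", ("XII",), None, ("XIIa",), dict(k_first=5.0e-4), None, "none", ()),
    (30, "bc", ("XIIa", "XII"), "XIIa=XII", ("XIIa", "XIIa"), dict(k_on=1.0e8, k_off=750.0, k_cat=3.3e-2), 1.0, "off_rate", ()),
    (31, "bc", ("XIIa", "PK"), "XIIa=PK", ("XIIa", "K"), dict(k_on=1.0e8, k_off=3.6e3, k_cat=40.0), 1.0, "off_rate", ()),
    (32, "bc", ("XII", "K"), "K=XII", ("XIIa", "K"), dict(k_on=1.0e8, k_off=45.3, k_cat=5.7), 1.0, "off_rate", ()),
    (33, "bi", ("PK", "K"), None, ("K", "K"), dict(k_on=2.7e4), None, "none", ()),
    (34, "fs", ("K",), None, (), dict(k_first=1.1e-2), None, "none", ("K.Inhibited",)),
    (35, "rb", ("XIIa", "CTI"), "XIIa=CTI", (), dict(k_on=1.0e8, k_off=2.4), None, "none", ()),
    (36, "bi", ("XIIa", "C1inh"), None, ("XIIa=C1inh",), dict(k_on=3.6e3), None, "none", ()),
    (37, "bi", ("XIIa", "ATIII"), None, ("XIIa=ATIII",), dict(k_on=21.6), None, "none", ()),
    (38, "bc", ("XI", "IIa"), "XI=IIa", ("XIa", "IIa"), dict(k_on=1.0e8, k_off=5.0, k_cat=1.3e-4), None, "none", ()),
    (39, "bc", ("XIIa", "XI"), "XIIa=XI", ("XIIa", "XIa"), dict(k_on=1.0e8, k_off=200.0, k_cat=5.7e-4), 1.0, "off_rate", ()),
    (40, "bi", ("XIa", "XI"), None, ("XIa", "XIa"), dict(k_on=XI_AUTOACTIVATION_RATE), None, "none", ()),
    (41, "bi", ("XIa", "ATIII"), None, ("XIa=ATIII",), dict(k_on=3.2e2), None, "none", ()),
    (42, "bi", ("XIa", "C1inh"), None, ("XIa=C1inh",), dict(k_on=1.8e3), None, "none", ()),
    (43, "bi", ("XIa", "alpha1AT"), None, ("XIa=alpha1AT",), dict(k_on=1.0e2), None, "none", ()),
    (44, "bi", ("XIa", "alpha2AP"), None, ("XIa=alpha2AP",), dict(k_on=4.3e3), None, "none", ()),
    (45, "bc", ("XIa", "IX"), "XIa=IX", ("XIa", "IXa"), dict(k_on=1.0e8, k_off=41.0, k_cat=7.7), 1.0, "off_rate", ()),
    (46, "bc", ("IXa", "X"), "IXa=X", ("IXa", "Xa"), dict(k_on=1.0e8, k_off=0.64, k_cat=7.0e-4), 1.0, "off_rate", ()),
    (47, "bc", ("Xa", "VIII"), "Xa=VIII", ("Xa", "VIIIa"), dict(k_on=1.0e8, k_off=2.1, k_cat=0.023), 1.0, "off_rate", ()),
    (48, "bc", ("VIIa", "IX"), "VIIa=IX", ("VIIa", "IXa"), dict(k_on=1.0e8, k_off=0.9, k_cat=3.6e-5), None, "none", ()),
    (49, "bc", ("VIIa", "X"), "VIIa=X", ("VIIa", "Xa"), dict(k_on=1.0e8, k_off=210.0, k_cat=1.6e-6), 1.0, "off_rate", ()),
    # --- fibrin formation and thrombin sequestration -------------------------
    (50, "bc", ("Fbg", "IIa"), "Fbg=IIa", ("Fbn1", "IIa"), dict(k_on=1.0e8, k_off=636.0, k_cat=84.0), None, "none", ("FPA",)),
    (51, "bc", ("Fbn1", "IIa"), "Fbn1=IIa", ("Fbn2", "IIa"), dict(k_on=1.0e8, k_off=742.6, k_cat=7.4), None, "none", ("FPB",)),
    (52, "rb", ("Fbn1", "Fbn1"), "(Fbn1)2", (), dict(k_on=1.0e6, k_off=6.4e-2), None, "none", ()),
    (53, "bc", ("(Fbn1)2", "IIa"), "(Fbn1)2=IIa", ("IIa",), dict(k_on=1.0e8, k_off=701.0, k_cat=49.0), None, "none", ("(Fbn2)2", "FPB")),
    (54, "rb", ("Fbn2", "IIa"), "Fbn2=IIa", (), dict(k_on=1.0e8, k_off=1.0e3), None, "none", ()),
    (55, "bi", ("(Fbn1)2=IIa", "ATIII"), None, ("(Fbn1)2=IIa=ATIII",), dict(k_on=1.6e4), None, "none", ()),
    (56, "bi", ("Fbn1=IIa", "ATIII"), None, ("Fbn1=IIa=ATIII",), dict(k_on=1.6e4), None, "none", ()),
    (57, "bi", ("Fbn2=IIa", "ATIII"), None, ("Fbn2=IIa=ATIII",), dict(k_on=1.0e4), None, "none", ()),
]

_SCHEME = {
    "rb": "reversible_binding",
    "bc": "binding_catalysis",
    "bi": "bimolecular_irreversible",
    "fo": "first_order",
    "fs": "first_order_sink",
}

#: Published K_m/K_d column values (M), used by self-consistency tests.
#: PP: fully-activated-platelet (eps = 1) column; HM: fixed-rate column.
PP_KM_KD = {
    1: 9.6e-9, 2: 1.3e-12, 6: 2.4e-7, 7: 8.6e-7, 8: 4.2e-7, 11: 1.0e-11,
    12: 8.2e-8, 13: 2.7e-9, 17: 2.0e-11, 18: 6.5e-7, 20: 4.0e-10, 21: 3.4e-11,
    28: 6.1e-5, 30: 7.5e-6, 31: 3.7e-5, 32: 5.1e-7, 35: 2.4e-8, 38: 5.0e-8,
    39: 2.0e-6, 45: 4.9e-7, 46: 6.4e-9, 47: 2.1e-8, 48: 9.0e-9, 49: 2.1e-6,
    50: 7.2e-6, 51: 7.5e-6, 53: 7.5e-6, 54: 1.0e-5,
}
HM_KM_KD = {
    1: 9.6e-10, 2: 1.3e-10, 6: 2.8e-7, 7: 8.6e-7, 8: 4.2e-7, 11: 5.0e-10,
    12: 8.2e-8, 13: 2.7e-7, 17: 5.0e-10, 18: 1.6e-6, 20: 4.0e-10, 21: 3.4e-13,
}


def _reaction(row, with_eta: bool, overrides: Optional[dict] = None) -> ReactionDef:
    rid, sch, reactants, cplx, products, rates, eta, mode, untracked = row
    rates = dict(rates)
    if overrides and rid in overrides:
        rates.update(overrides[rid])
    if not with_eta:
        eta, mode = None, "none"
    return ReactionDef(
        id=rid,
        scheme=_SCHEME[sch],
        reactants=tuple(reactants),
        rates=RateConstants(**rates),
        complex_=cplx,
        products=tuple(products),
        eta=eta,
        epsilon_mode=mode,
        untracked_products=tuple(untracked),
    )


def build_hockin_mann(with_detection: bool = False) -> ModelSpec:
    """Fixed-rate extrinsic-pathway model: 34 species, 27 reactions.

    Rate constants are the fixed-platelet reference column (no eta, eps frozen
    at 1).  ``with_detection`` appends the fluorogenic-substrate chemistry
    (4 species, 1 reaction) so that substrate-conversion metrics can be
    computed for this model too.
    """
    rows = [_SPECIES[i] for i in range(_N_HM_SPECIES)]
    rids = set(range(1, 28))
    if with_detection:
        rows += [s for s in _SPECIES if s[0] in _DETECTION_SPECIES]
        rids.add(28)
    species = [SpeciesDef(name=n, initial_conc=c, role=r) for n, c, r in rows]
    reactions = [_reaction(row, with_eta=False) for row in _R if row[0] in rids]
    return ModelSpec(
        species=species,
        reactions=reactions,
        activation=None,
        label="hockin_mann+SIIa" if with_detection else "hockin_mann",
    )


def build_platelet_plasma(
    activation: Optional[ActivationParams] = None,
    xi_autoactivation_rate: float = XI_AUTOACTIVATION_RATE,
) -> ModelSpec:
    """Full platelet-plasma model: 76 species, 57 reactions.

    ``xi_autoactivation_rate`` overrides the XI autoactivation constant
    (reaction 40), for which only an indirect literature estimate exists.
    """
    species = [SpeciesDef(name=n, initial_conc=c, role=r) for n, c, r in _SPECIES]
    overrides = {40: dict(k_on=xi_autoactivation_rate)}
    reactions = [_reaction(row, with_eta=True, overrides=overrides) for row in _R]
    return ModelSpec(
        species=species,
        reactions=reactions,
        activation=activation if activation is not None else ActivationParams(),
        label="platelet_plasma",
    )


def to_hockin_mann_limit(model: ModelSpec) -> ModelSpec:
    """Strip the platelet-plasma extensions from a full model.

    Zeroes the XIIa source, contact-pathway species, fibrinogen and
    fluorogenic substrate; disables the cofactor-independent IXa/Xa routes
    and TF-independent VIIa activity (reactions 46-49, which would otherwise
    sequester VIIa and amplify X activation); freezes eps at 1 and forces
    eta to 1.  The result has the full 76-species state but the dynamics of
    the fixed-rate extrinsic-pathway model (useful for equivalence checks).
    """
    contact = {
        "XII", "PK", "XI", "CTI", "C1inh", "alpha1AT", "alpha2AP",
        "Fbg", "Boc-VPR-MCA",
    }
    species = [
        dataclasses.replace(s, initial_conc=0.0) if s.name in contact else s
        for s in model.species
    ]
    reactions = []
    for r in model.reactions:
        if r.id == 29:
            r = dataclasses.replace(r, rates=RateConstants(k_first=0.0))
        if r.id in (46, 47, 48, 49):
            zeroed = {
                k: (0.0 if v is not None else None)
                for k, v in dataclasses.asdict(r.rates).items()
            }
            r = dataclasses.replace(r, rates=RateConstants(**zeroed))
        if r.epsilon_mode != "none":
            r = dataclasses.replace(r, eta=1.0)
        reactions.append(r)
    return ModelSpec(
        species=species,
        reactions=reactions,
        activation=None,  # eps frozen at 1
        lipidated_tf_mode=model.lipidated_tf_mode,
        label=model.label + "+hm_limit",
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One in-silico well.

    dilution_factor -- blood dilution in the well; all tabulated initial
        concentrations are divided by it (default 5, the plate protocol).
    additions -- species -> final in-well concentration (M), added after
        dilution (exogenous spikes are expressed on the in-well axis and are
        never diluted).
    knockouts -- species -> scale factor in [0, 1] applied to the initial
        concentration (0.01 emulates immunodepleted plasma with <1% residual
        activity; 0 is a perfect knockout).
    eps0_override -- initial platelet activation fraction; 1.0 emulates
        agonist (convulxin) pre-activation.
    lipidated_tf -- freeze TF-dependent reactions at their fully-activated
        rates (exogenous TF supplied on lipid vesicles).
    cti_syringe_conc -- CTI concentration in the phlebotomy syringe (M),
        subject to the same dilution.
    substrate_at_well_conc -- if True the fluorogenic substrate is set to its
        tabulated concentration *after* dilution (in-well 10 uM, as pipetted
        in the plate protocol) instead of being diluted with the blood.
    horizon -- simulated duration (s); the plate is read for 4 h.
    """

    dilution_factor: float = 5.0
    additions: dict[str, float] = field(default_factory=dict)
    knockouts: dict[str, float] = field(default_factory=dict)
    eps0_override: Optional[float] = None
    lipidated_tf: bool = False
    cti_syringe_conc: float = 4.2e-6
    substrate_at_well_conc: bool = False
    horizon: float = 14400.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        for sp, fr in self.knockouts.items():
            if not 0.0 <= fr <= 1.0:
                raise ValueError(f"knockout scale for {sp} must be in [0, 1]")
        if self.eps0_override is not None and not 0.0 < self.eps0_override <= 1.0:
            raise ValueError("eps0_override must be in (0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(**d)


def apply_scenario(model: ModelSpec, s: Scenario) -> ModelSpec:
    """Transform a model's initial conditions for one well.

    Order is pinned: syringe-level edits (CTI), then dilution of every
    tabulated concentration, then substrate repipetting, then knockouts, then
    exogenous additions at final in-well concentration.
    """
    index = model.species_index()
    for name in list(s.additions) + list(s.knockouts):
        if name not in index:
            raise KeyError(f"scenario references unknown species {name!r}")

    conc = {sp.name: sp.initial_conc for sp in model.species}
    if "CTI" in conc:
        conc["CTI"] = s.cti_syringe_conc
    for name in conc:
        conc[name] = conc[name] / s.dilution_factor
    if s.substrate_at_well_conc and "Boc-VPR-MCA" in conc:
        tab = next(sp.initial_conc for sp in model.species if sp.name == "Boc-VPR-MCA")
        conc["Boc-VPR-MCA"] = tab
    for name, fr in s.knockouts.items():
        conc[name] *= fr
    for name, add in s.additions.items():
        conc[name] += add

    species = [
        dataclasses.replace(sp, initial_conc=conc[sp.name]) for sp in model.species
    ]
    activation = model.activation
    if activation is not None and s.eps0_override is not None:
        activation = dataclasses.replace(activation, eps0=s.eps0_override)
    return ModelSpec(
        species=species,
        reactions=list(model.reactions),
        activation=activation,
        lipidated_tf_mode=s.lipidated_tf or model.lipidated_tf_mode,
        label=model.label + (f"|{s.label}" if s.label else ""),
    )
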