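"""Species/reaction data model and mass-action ODE assembly.

The reaction network is a set of elementary mass-action steps in molar units
and seconds.  Binding-catalysis reactions are expanded into explicit complex
formation (k_on*[E][S]), dissociation (k_off*[ES]) and turnover (k_cat*[ES]).
Dissociation of membrane-dependent complexes is dynamically rescaled by the
platelet activation state: the effective off-rate is

    k_off_eff = eta * k_off / eps

where ``eta`` converts the tabulated reference constant to its value on the
fully activated platelet (eps = 1) and ``eps`` in (0, 1] is the instantaneous
activation fraction.  One reaction (VIIIa subunit dissociation, id 13) is
written complex-first in the source table, so its epsilon-coupled constant is
the tabulated forward (k_1) rate; after normalization to the
association/dissociation convention used here the modulated step is still the
physical unbinding step.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Optional

import numpy as np
from scipy import sparse

from .activation import ActivationParams

__all__ = [
    "SpeciesDef",
    "RateConstants",
    "ReactionDef",
    "ModelSpec",
    "CompiledModel",
    "ModelError",
    "ValidationReport",
    "km_to_off_rate",
    "effective_off_rate",
    "assemble_rhs",
    "validate_model",
    "atoms_of",
    "LIPIDATED_TF_REACTIONS",
]


class ModelError(ValueError):
    """Invalid model structure or parameters."""


#: Reactions whose epsilon coupling is frozen at the fully-activated value
#: when tissue factor is supplied in pre-lipidated form (relipidated TF
#: vesicles carry their own procoagulant surface, so TF-dependent assembly
#: does not wait for platelet PS exposure).
LIPIDATED_TF_REACTIONS = frozenset({1, 2, 6, 7, 8, 21})

SCHEMES = (
    "reversible_binding",
    "binding_catalysis",
    "bimolecular_irreversible",
    "first_order",
    "first_order_sink",
)

ROLES = ("zymogen", "enzyme", "complex", "inhibitor", "substrate", "product", "cofactor")


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    initial_conc: float  # M
    role: str = "zymogen"

    def __post_init__(self) -> None:
        if self.initial_conc < 0:
            raise ModelError(f"negative initial concentration for {self.name}")
        if self.role not in ROLES:
            raise ModelError(f"unknown role {self.role!r} for {self.name}")


@dataclass(frozen=True)
class RateConstants:
    """Rate constants of one reaction (absent entries are None).

    k_on   -- bimolecular association / second-order rate (1/M/s)
    k_off  -- dissociation rate at the eps = 1 reference (1/s)
    k_cat  -- catalytic turnover (1/s)
    k_first-- first-order rate (1/s)
    """

    k_on: Optional[float] = None
    k_off: Optional[float] = None
    k_cat: Optional[float] = None
    k_first: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_cat", "k_first"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ModelError(f"negative rate constant {name}={v}")


@dataclass(frozen=True)
class ReactionDef:
    """One elementary reaction of the network.

    ``scheme`` fixes the interpretation of species fields:

    reversible_binding       reactants <-> complex_
    binding_catalysis        reactants <-> complex_ -> products
    bimolecular_irreversible reactants -> products
    first_order              reactants[0] -> products
    first_order_sink         reactants[0] -> (untracked only)

    ``untracked_products`` are released species not carried as state
    (fibrinopeptides, inhibited kallikrein, the fibrin-II dimer); they are
    recorded for stoichiometric bookkeeping and accumulated as auxiliary
    outputs during simulation.
    """

    id: int
    scheme: str
    reactants: tuple[str, ...]
    rates: RateConstants
    complex_: Optional[str] = None
    products: tuple[str, ...] = ()
    eta: Optional[float] = None
    epsilon_mode: str = "none"  # none | off_rate | on_rate
    untracked_products: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ModelError(f"reaction {self.id}: unknown scheme {self.scheme!r}")
        if self.epsilon_mode not in ("none", "off_rate", "on_rate"):
            raise ModelError(f"reaction {self.id}: bad epsilon_mode {self.epsilon_mode!r}")
        if (self.eta is not None) != (self.epsilon_mode != "none"):
            raise ModelError(
                f"reaction {self.id}: eta must be present iff epsilon_mode != none"
            )
        if self.epsilon_mode == "on_rate" and self.id != 13:
            raise ModelError("epsilon_mode 'on_rate' is reserved for reaction 13")


@dataclass
class ModelSpec:
    """A full reaction network with initial conditions and activation model.

    ``activation is None`` freezes eps at 1 (fixed-rate mode, as in models
    that assume fully activated platelets at t = 0).  ``lipidated_tf_mode``
    freezes the epsilon coupling of the TF-dependent reactions
    (ids 1, 2, 6-8, 21) at their eps = 1 values.
    """

    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    activation: Optional[ActivationParams] = None
    lipidated_tf_mode: bool = False
    label: str = ""

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def initial_concentrations(self) -> np.ndarray:
        return np.array([s.initial_conc for s in self.species], dtype=float)

    def reaction(self, rid: int) -> ReactionDef:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid}")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "lipidated_tf_mode": self.lipidated_tf_mode,
            "activation": None if self.activation is None else self.activation.to_dict(),
            "species": [asdict(s) for s in self.species],
            "reactions": [
                {
                    "id": r.id,
                    "scheme": r.scheme,
                    "reactants": list(r.reactants),
                    "complex": r.complex_,
                    "products": list(r.products),
                    "rates": {k: v for k, v in asdict(r.rates).items() if v is not None},
                    "eta": r.eta,
                    "epsilon_mode": r.epsilon_mode,
                    "untracked_products": list(r.untracked_products),
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        species = [SpeciesDef(**s) for s in d["species"]]
        reactions = [
            ReactionDef(
                id=r["id"],
                scheme=r["scheme"],
                reactants=tuple(r["reactants"]),
                rates=RateConstants(**r.get("rates", {})),
                complex_=r.get("complex"),
                products=tuple(r.get("products", ())),
                eta=r.get("eta"),
                epsilon_mode=r.get("epsilon_mode", "none"),
                untracked_products=tuple(r.get("untracked_products", ())),
            )
            for r in d["reactions"]
        ]
        act = d.get("activation")
        return cls(
            species=species,
            reactions=reactions,
            activation=None if act is None else ActivationParams.from_dict(act),
            lipidated_tf_mode=d.get("lipidated_tf_mode", False),
            label=d.get("label", ""),
        )


# ---------------------------------------------------------------------------
# rate-constant helpers
# ---------------------------------------------------------------------------

def km_to_off_rate(km: float, k_on: float, k_cat: float = 0.0, reaction_id=None) -> float:
    """Dissociation rate implied by a Michaelis/dissociation constant.

    K_m = (k_off + k_cat) / k_on  =>  k_off = K_m * k_on - k_cat.  On-rates in
    the source tables are assumed diffusion limited, and off-rates were
    back-calculated this way.  Raises ModelError when the result would be
    negative (K_m smaller than the purely catalytic bound).
    """
    if km < 0 or k_on < 0 or k_cat < 0:
        raise ModelError("km, k_on and k_cat must be non-negative")
    k_off = km * k_on - k_cat
    if k_off < 0:
        where = f" (reaction {reaction_id})" if reaction_id is not None else ""
        raise ModelError(
            f"K_m*k_on < k_cat{where}: implied off-rate would be negative"
        )
    return k_off


def effective_off_rate(
    rxn: ReactionDef,
    hm_off_rate: float,
    eps: float,
    lipidated_tf_mode: bool = False,
) -> float:
    """Epsilon-modulated dissociation rate eta * k_off_ref / eps.

    At eps = 1 this equals the fully-activated-platelet value; in
    ``lipidated_tf_mode`` the TF-dependent reactions return that value
    regardless of eps.
    """
    if rxn.epsilon_mode == "none":
        raise ModelError(f"reaction {rxn.id} has no epsilon coupling")
    if not 0.0 < eps <= 1.0:
        raise ModelError(f"eps must be in (0, 1], got {eps}")
    eta = 1.0 if rxn.eta is None else rxn.eta
    if lipidated_tf_mode and rxn.id in LIPIDATED_TF_REACTIONS:
        return eta * hm_off_rate
    return eta * hm_off_rate / eps


# ---------------------------------------------------------------------------
# name decomposition (complexes -> components -> conserved "atoms")
# ---------------------------------------------------------------------------

# protein-core atoms of each component token; activation-state variants share
# an atom so zymogen->enzyme conversions balance.  Cleavage fragments (FPA,
# FPB) map to nothing: peptide-bond accounting is out of scope.
_TOKEN_ATOMS: dict[str, dict[str, int]] = {
    "II": {"II": 1}, "IIa": {"II": 1}, "mIIa": {"II": 1},
    "VII": {"VII": 1}, "VIIa": {"VII": 1},
    "X": {"X": 1}, "Xa": {"X": 1},
    "IX": {"IX": 1}, "IXa": {"IX": 1},
    "V": {"V": 1}, "Va": {"V": 1},
    "VIII": {"VIII.1": 1, "VIII.2": 1},
    "VIIIa": {"VIII.1": 1, "VIII.2": 1},
    "VIIIa1-L": {"VIII.1": 1},
    "VIIIa2": {"VIII.2": 1},
    "XI": {"XI": 1}, "XIa": {"XI": 1},
    "XII": {"XII": 1}, "XIIa": {"XII": 1},
    "PK": {"PK": 1}, "K": {"PK": 1}, "K.Inhibited": {"PK": 1},
    "Fbg": {"Fbg": 1}, "Fbn1": {"Fbg": 1}, "Fbn2": {"Fbg": 1},
    "(Fbn1)2": {"Fbg": 2}, "(Fbn2)2": {"Fbg": 2},
    "Boc-VPR-MCA": {"BocVPR": 1, "AMC": 1},
    "Boc-VPR": {"BocVPR": 1},
    "AMC": {"AMC": 1},
    "FPA": {}, "FPB": {},
}


def _tokens(name: str) -> list[str]:
    return name.split("=")


def atoms_of(name: str) -> Counter:
    """Conserved-moiety composition of a species name.

    Complex names (components joined by '='), dimers and activation-state
    variants are decomposed onto a common set of protein-core atoms; unknown
    tokens count as their own atom.
    """
    out: Counter = Counter()
    for tok in _tokens(name):
        for atom, n in _TOKEN_ATOMS.get(tok, {tok: 1}).items():
            out[atom] += n
    return out


# ---------------------------------------------------------------------------
# compilation to a mass-action derivative evaluator
# ---------------------------------------------------------------------------

def _elementary_processes(model: ModelSpec):
    """Expand reactions into (k_base, eps_dynamic, r1, r2, stoich) tuples.

    ``stoich`` maps state names (species or untracked accumulators) to signed
    integers.  ``k_base`` already includes eta for epsilon-coupled steps;
    ``eps_dynamic`` marks steps whose rate is divided by the instantaneous
    eps at evaluation time.
    """
    names = set(model.species_names)
    procs = []

    def check(*ns):
        for n in ns:
            if n is not None and n not in names:
                raise ModelError(f"reaction references unknown species {n!r}")

    for r in model.reactions:
        k = r.rates
        coupled = r.epsilon_mode != "none"
        frozen = (
            model.activation is None
            or (model.lipidated_tf_mode and r.id in LIPIDATED_TF_REACTIONS)
        )
        eta = 1.0 if r.eta is None else r.eta

        def add(kval, reactants, stoich, eps_dyn=False):
            if kval is None:
                raise ModelError(f"reaction {r.id}: missing rate constant")
            if len(reactants) == 1:
                r1, r2 = reactants[0], None
            else:
                r1, r2 = reactants
            procs.append((float(kval), eps_dyn, r1, r2, dict(stoich)))

        def net(reactants, products):
            s: Counter = Counter()
            for p in products:
                s[p] += 1
            for x in reactants:
                s[x] -= 1
            return {n: v for n, v in s.items() if v != 0}

        if r.scheme == "reversible_binding":
            check(*r.reactants, r.complex_)
            add(k.k_on, r.reactants, net(r.reactants, [r.complex_]))
            k_off = eta * k.k_off if coupled else k.k_off
            add(k_off, (r.complex_,), net([r.complex_], r.reactants),
                eps_dyn=coupled and not frozen)
        elif r.scheme == "binding_catalysis":
            check(*r.reactants, r.complex_, *r.products)
            add(k.k_on, r.reactants, net(r.reactants, [r.complex_]))
            k_off = eta * k.k_off if coupled else k.k_off
            add(k_off, (r.complex_,), net([r.complex_], r.reactants),
                eps_dyn=coupled and not frozen)
            prods = list(r.products) + list(r.untracked_products)
            add(k.k_cat, (r.complex_,), net([r.complex_], prods))
        elif r.scheme == "bimolecular_irreversible":
            check(*r.reactants, *r.products)
            prods = list(r.products) + list(r.untracked_products)
            add(k.k_on, r.reactants, net(r.reactants, prods))
        elif r.scheme == "first_order":
            check(*r.reactants, *r.products)
            prods = list(r.products) + list(r.untracked_products)
            add(k.k_first, r.reactants, net(r.reactants, prods))
        elif r.scheme == "first_order_sink":
            check(*r.reactants)
            add(k.k_first, r.reactants, net(r.reactants, list(r.untracked_products)))
    return procs


class CompiledModel:
    """Callable mass-action derivative with platelet-activation dynamics.

    State vector layout: [species..., untracked accumulators..., eps, iia_max].
    The instance is callable as f(t, y) -> dy/dt and exposes the layout,
    initial state, conserved-moiety weights, and a Jacobian sparsity pattern.
    """

    def __init__(self, model: ModelSpec):
        self.model = model
        self.species_names = model.species_names
        n_sp = len(self.species_names)
        idx = model.species_index()
        if len(idx) != n_sp:
            raise ModelError("duplicate species names")

        procs = _elementary_processes(model)

        # untracked accumulators, in first-appearance order
        untracked: list[str] = []
        for r in model.reactions:
            for u in r.untracked_products:
                if u not in untracked:
                    untracked.append(u)
        self.untracked_names = untracked
        for u in untracked:
            idx = {**idx, u: n_sp + untracked.index(u)}

        self.n_species = n_sp
        self.n_untracked = len(untracked)
        self.i_eps = n_sp + self.n_untracked
        self.i_max = self.i_eps + 1
        self.n_state = self.i_max + 1
        self.i_iia = model.species_index().get("IIa")
        self.i_miia = model.species_index().get("mIIa")

        n_proc = len(procs)
        self._k_base = np.array([p[0] for p in procs])
        self._eps_mask = np.array([p[1] for p in procs], dtype=bool)
        self._any_dynamic = bool(self._eps_mask.any())
        self._r1 = np.array([idx[p[2]] for p in procs], dtype=np.intp)
        self._r2 = np.array([-1 if p[3] is None else idx[p[3]] for p in procs], dtype=np.intp)
        self._bi = np.flatnonzero(self._r2 >= 0)
        self._r2b = self._r2[self._bi]
        S = np.zeros((self.i_eps, n_proc))
        for j, p in enumerate(procs):
            for name, v in p[4].items():
                S[idx[name], j] = v
        self._S = S
        self._act = model.activation
        self._eps_floor = 1e-9

    # -- initial state ------------------------------------------------------

    def initial_state(self, eps0: Optional[float] = None) -> np.ndarray:
        y0 = np.zeros(self.n_state)
        y0[: self.n_species] = self.model.initial_concentrations()
        if self._act is not None:
            y0[self.i_eps] = self._act.eps0 if eps0 is None else eps0
            if self.i_iia is not None:
                x0 = y0[self.i_iia]
                if self._act.miia_weight and self.i_miia is not None:
                    x0 += self._act.miia_weight * y0[self.i_miia]
                y0[self.i_max] = x0  # running max starts at the initial signal
        else:
            y0[self.i_eps] = 1.0
        return y0

    # -- derivative ---------------------------------------------------------

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        c = y[: self.i_eps]
        if self._any_dynamic:
            eps = y[self.i_eps]
            eps = self._eps_floor if eps < self._eps_floor else (1.0 if eps > 1.0 else eps)
            k = self._k_base.copy()
            k[self._eps_mask] /= eps
        else:
            k = self._k_base
        f = k * c[self._r1]
        f[self._bi] *= c[self._r2b]
        dy = np.zeros(self.n_state)
        dy[: self.i_eps] = self._S @ f
        act = self._act
        if act is not None:
            m = y[self.i_max]
            x = y[self.i_iia] if self.i_iia is not None else 0.0
            dx = dy[self.i_iia] if self.i_iia is not None else 0.0
            if act.miia_weight and self.i_miia is not None:
                x = x + act.miia_weight * y[self.i_miia]
                dx = dx + act.miia_weight * dy[self.i_miia]
            # running max of the activating signal: integrate only its rises.
            # Exact for a single-peaked thrombin transient (M = x while x
            # rises, frozen once x starts to fall).
            dy[self.i_max] = dx if dx > 0.0 else 0.0
            h = m ** act.hill_n
            em = act.eps0 + (1.0 - act.eps0) * h / (act.ec50 ** act.hill_n + h)
            dy[self.i_eps] = act.k_act * (em - y[self.i_eps])
        return dy

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian of the derivative (dense, n_state x n_state)."""
        c = y[: self.i_eps]
        eps_used = 1.0
        if self._any_dynamic:
            eps = y[self.i_eps]
            eps_used = self._eps_floor if eps < self._eps_floor else (1.0 if eps > 1.0 else eps)
            k = self._k_base.copy()
            k[self._eps_mask] /= eps_used
        else:
            k = self._k_base
        n_proc = len(k)
        # dflux/dstate for every process
        Jf = np.zeros((n_proc, self.n_state))
        c1 = c[self._r1]
        partial_r1 = k.copy()
        partial_r1[self._bi] *= c[self._r2b]
        np.add.at(Jf, (np.arange(n_proc), self._r1), partial_r1)
        np.add.at(Jf, (self._bi, self._r2b), k[self._bi] * c1[self._bi])
        if self._any_dynamic and 0.0 < y[self.i_eps] <= 1.0:
            f = k * c1
            f[self._bi] *= c[self._r2b]
            Jf[self._eps_mask, self.i_eps] = -f[self._eps_mask] / eps_used
        J = np.zeros((self.n_state, self.n_state))
        J[: self.i_eps] = self._S @ Jf
        act = self._act
        if act is not None:
            m = y[self.i_max]
            J[self.i_eps, self.i_eps] = -act.k_act
            en, mn = act.ec50 ** act.hill_n, m ** act.hill_n
            if m > 0:
                dh = act.hill_n * en * mn / (m * (en + mn) ** 2)
                J[self.i_eps, self.i_max] = act.k_act * (1.0 - act.eps0) * dh
            if self.i_iia is None:
                return J
            x = y[self.i_iia]
            row = J[self.i_iia].copy()
            dx = float(self._S[self.i_iia] @ (k * c1 * np.where(self._r2 >= 0, c[np.maximum(self._r2, 0)], 1.0)))
            if act.miia_weight and self.i_miia is not None:
                x = x + act.miia_weight * y[self.i_miia]
                dx = dx + act.miia_weight * float(
                    self._S[self.i_miia] @ (k * c1 * np.where(self._r2 >= 0, c[np.maximum(self._r2, 0)], 1.0))
                )
                row += act.miia_weight * J[self.i_miia]
            gate = 1.0 if dx > 0.0 else 0.0
            J[self.i_max] = gate * row
        return J

    # -- structure ----------------------------------------------------------

    def jac_sparsity(self) -> sparse.csr_matrix:
        n = self.n_state
        J = sparse.lil_matrix((n, n), dtype=np.int8)
        rows = [np.flatnonzero(self._S[:, j]) for j in range(self._S.shape[1])]
        for j in range(self._S.shape[1]):
            cols = [self._r1[j]] + ([self._r2[j]] if self._r2[j] >= 0 else [])
            if self._eps_mask[j]:
                cols.append(self.i_eps)
            for i in rows[j]:
                for cjj in cols:
                    J[i, cjj] = 1
        if self._act is not None:
            J[self.i_eps, self.i_eps] = 1
            J[self.i_eps, self.i_max] = 1
            iia_cols = np.flatnonzero(np.asarray(J[self.i_iia].todense()).ravel())
            for cjj in iia_cols:
                J[self.i_max, cjj] = 1
            if self._act.miia_weight and self.i_miia is not None:
                for cjj in np.flatnonzero(np.asarray(J[self.i_miia].todense()).ravel()):
                    J[self.i_max, cjj] = 1
            J[self.i_max, self.i_max] = 1
            J[self.i_max, self.i_iia] = 1
        return J.tocsr()

    def moiety_weights(self, atom: str) -> np.ndarray:
        """Weight of each state element in the conservation total of ``atom``."""
        w = np.zeros(self.n_state)
        for i, name in enumerate(self.species_names + self.untracked_names):
            w[i] = atoms_of(name).get(atom, 0)
        return w


def assemble_rhs(model: ModelSpec) -> CompiledModel:
    """Compile a validated ModelSpec into a mass-action derivative evaluator."""
    return CompiledModel(model)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

#: moieties whose totals must be conserved along any trajectory
CONSERVED_MOIETIES = ("TF", "CTI", "AMC", "Fbg")


@dataclass
class ValidationReport:
    n_species: int
    n_reactions: int
    conserved_moieties: dict[str, float]  # moiety -> initial total (M)
    unbalanced: list[str] = field(default_factory=list)
    unknown_species: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.unbalanced and not self.unknown_species


def validate_model(model: ModelSpec) -> ValidationReport:
    """Structural report: counts, conserved moieties, imbalances.

    Report-only -- never raises.  A reaction referencing a species absent
    from the species list appears in ``unknown_species``; a reaction whose
    reactant and product sides disagree on protein-core atom composition
    appears in ``unbalanced``.
    """
    names = set(model.species_names)
    unknown: list[str] = []
    unbalanced: list[str] = []

    def atoms_sum(ns: Iterable[str]) -> Counter:
        out: Counter = Counter()
        for n in ns:
            out += atoms_of(n)
        return out

    for r in model.reactions:
        referenced = list(r.reactants) + list(r.products)
        if r.complex_:
            referenced.append(r.complex_)
        for n in referenced:
            if n not in names:
                unknown.append(f"reaction {r.id}: unknown species {n!r}")
        if r.scheme in ("reversible_binding", "binding_catalysis"):
            if atoms_sum(r.reactants) != atoms_sum([r.complex_]):
                unbalanced.append(f"reaction {r.id}: reactants vs complex")
        if r.scheme == "binding_catalysis":
            rhs = atoms_sum(list(r.products) + list(r.untracked_products))
            if atoms_sum([r.complex_]) != rhs:
                unbalanced.append(f"reaction {r.id}: complex vs products")
        if r.scheme in ("bimolecular_irreversible", "first_order", "first_order_sink"):
            rhs = atoms_sum(list(r.products) + list(r.untracked_products))
            if atoms_sum(r.reactants) != rhs:
                unbalanced.append(f"reaction {r.id}: reactants vs products")

    totals: dict[str, float] = {}
    for atom in CONSERVED_MOIETIES:
        tot = 0.0
        for s in model.species:
            tot += atoms_of(s.name).get(atom, 0) * s.initial_conc
        totals[atom] = tot

    return ValidationReport(
        n_species=len(model.species),
        n_reactions=len(model.reactions),
        conserved_moieties=totals,
        unbalanced=unbalanced,
        unknown_species=unknown,
    )
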