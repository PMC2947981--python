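"""Coarse-grained platelet activation state.

Platelet procoagulant function is represented by a single dimensionless
activation fraction ``eps`` (phosphatidylserine exposure), which rises from a
basal value ``eps0`` toward a thrombin-determined ceiling ``eps_max``.  The
ceiling is a Hill function of the *running maximum* of free thrombin seen so
far, so that platelets stay activated after the thrombin peak passes.  The
instantaneous state relaxes toward the ceiling with first-order kinetics:

    d(eps)/dt = k_act * (eps_max(IIa_max) - eps),   eps(0) = eps0

Membrane-dependent dissociation rates in the reaction network are divided by
``eps``, so activation tightens enzyme/substrate/cofactor complexes by up to
two orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import curve_fit


#: Thrombin concentration (M) at which maximal activation must saturate
#: (eps_max >= 0.99): platelets are fully activated above ~10 nM thrombin.
SATURATION_IIA = 1.0e-8
SATURATION_LEVEL = 0.99

#: Default Hill coefficient for PS exposure vs. thrombin.  Not directly
#: measured; chosen (with DEFAULT_EC50) so that eps_max stays near basal below
#: ~100 pM thrombin yet saturates at 10 nM -- the steep, switch-like PS
#: response reported for thrombin-stimulated platelets.
DEFAULT_HILL_N = 3.0

#: Half-maximal thrombin concentration (M).  Derived from the saturation
#: calibration: with eps0 = 0.01 the Hill term must reach 0.98/0.99 at 10 nM,
#: i.e. (10 nM / ec50)^n = 98, giving ec50 = 10 nM / 98**(1/3).
DEFAULT_EC50 = SATURATION_IIA / 98.0 ** (1.0 / DEFAULT_HILL_N)


@dataclass
class ActivationParams:
    """Parameters of the platelet activation model.

    eps0    -- basal activation fraction at t = 0 (1% PS exposure on resting
               platelets); set to 1.0 to emulate agonist pre-activation.
    k_act   -- relaxation rate (1/s); 1/k_act ~ 200 s matches the time scale
               of platelet intracellular calcium mobilization.
    hill_n  -- Hill coefficient of the PS-exposure dose response.
    ec50    -- thrombin concentration (M) at half-maximal incremental
               activation.
    miia_weight -- weight of meizothrombin in the activating "thrombin"
               signal (default 0: free IIa only drives activation).
    """

    eps0: float = 0.01
    k_act: float = 0.005
    hill_n: float = DEFAULT_HILL_N
    ec50: float = DEFAULT_EC50
    miia_weight: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eps0 <= 1.0:
            raise ValueError(f"eps0 must be in (0, 1], got {self.eps0}")
        if self.k_act <= 0:
            raise ValueError("k_act must be positive")
        if self.hill_n <= 0 or self.ec50 <= 0:
            raise ValueError("hill_n and ec50 must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationParams":
        return cls(**d)


@dataclass
class ActivationState:
    """Instantaneous activation fraction and the thrombin running maximum."""

    eps: float
    iia_max: float = 0.0


def eps_max(iia_max, p: ActivationParams):
    """Maximum attainable activation at a given (running-max) thrombin level.

    eps_max = eps0 + (1 - eps0) * x^n / (ec50^n + x^n),  x = iia_max (M).

    Monotone non-decreasing in ``iia_max``; equals eps0 at zero thrombin and
    approaches 1 at saturating thrombin.  Accepts scalars or arrays.
    """
    x = np.asarray(iia_max, dtype=float)
    if np.any(x < 0):
        raise ValueError("iia_max must be non-negative")
    h = x**p.hill_n / (p.ec50**p.hill_n + x**p.hill_n)
    out = p.eps0 + (1.0 - p.eps0) * h
    return float(out) if np.isscalar(iia_max) else out


def eps_trajectory(t, eps_max_const: float, p: ActivationParams):
    """Closed-form activation transient for a constant ceiling.

    Solves d(eps)/dt = k_act*(eps_max - eps), eps(0) = eps0:

        eps(t) = eps_max - (eps_max - eps0) * exp(-k_act * t)
    """
    t = np.asarray(t, dtype=float)
    out = eps_max_const - (eps_max_const - p.eps0) * np.exp(-p.k_act * t)
    return float(out) if out.ndim == 0 else out


class HillFitError(RuntimeError):
    """Raised when the PS-exposure Hill fit cannot be performed."""


def fit_hill(points, eps0: float = 0.01, k_act: float = 0.005) -> tuple[ActivationParams, float]:
    """Least-squares Hill fit of normalized PS exposure vs. thrombin.

    ``points`` is a sequence of (thrombin_M, normalized_exposure) pairs with
    exposure on [0, 1]; ``eps0`` is held fixed and only (hill_n, ec50) are
    fitted.  Returns the fitted parameters and the residual sum of squares.

    Raises HillFitError for fewer than 3 distinct thrombin values, for
    saturated (unidentifiable) data, or on optimizer failure.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise HillFitError("need at least 3 (thrombin, exposure) points")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise HillFitError("need at least 3 distinct thrombin concentrations")
    if np.all(y > 0.95):
        raise HillFitError("all points saturated: ec50 unidentifiable")

    def model(x, log_n, log_ec50):
        n, ec50 = np.exp(log_n), np.exp(log_ec50)
        h = x**n / (ec50**n + x**n)
        return eps0 + (1.0 - eps0) * h

    x0 = np.median(x[x > 0]) if np.any(x > 0) else 1e-9
    try:
        popt, _ = curve_fit(model, x, y, p0=[np.log(2.0), np.log(x0)], maxfev=20000)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
        raise HillFitError(f"Hill fit did not converge: {exc}") from exc
    n_fit, ec50_fit = float(np.exp(popt[0])), float(np.exp(popt[1]))
    params = ActivationParams(eps0=eps0, k_act=k_act, hill_n=n_fit, ec50=ec50_fit)
    rss = float(np.sum((model(x, *popt) - y) ** 2))
    return params, rss


def saturation_concentration(p: ActivationParams, level: float = SATURATION_LEVEL) -> float:
    """Smallest thrombin concentration (M) at which eps_max reaches ``level``.

    Analytic inversion of the Hill function; returns inf if ``level`` is not
    attainable (level > 1 or below eps0).
    """
    if level <= p.eps0:
        return 0.0
    h = (level - p.eps0) / (1.0 - p.eps0)
    if h >= 1.0:
        return float("inf")
    return float(p.ec50 * (h / (1.0 - h)) ** (1.0 / p.hill_n))
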