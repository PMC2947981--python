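"""Stiff ODE integration and assay-metric extraction.

The network spans rate scales from ~1e-4 1/s (slow first-order leaks) to
1e8 1/M/s (diffusion-limited association), so an implicit stiff integrator
is required.  Output is resampled onto a uniform grid (default one point per
60 s, matching one plate read per minute) before metrics are computed, so
simulated and experimental traces are processed identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .library import Scenario, apply_scenario
from .network import ModelSpec, assemble_rhs

logger = logging.getLogger("coagkin")

__all__ = [
    "SolverSettings",
    "TimeCourse",
    "AssayMetrics",
    "SimulationError",
    "MetricError",
    "simulate",
    "fractional_conversion",
    "initiation_time",
    "compute_metrics",
    "local_sensitivity",
]


class SimulationError(RuntimeError):
    """Integration failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:.1f} s)")
        self.last_time = last_time


class MetricError(ValueError):
    """A metric is undefined for the given trajectory."""


@dataclass
class SolverSettings:
    """Integrator configuration.

    abs_tol -- absolute tolerance (M); very small because species span many
        orders of magnitude down to sub-femtomolar.
    rel_tol -- relative tolerance.
    output_interval -- resampling grid spacing (s); 60 s = one plate read
        per minute.
    max_step -- optional cap on the internal step (s).
    method -- any stiff scipy.integrate.solve_ivp method ("BDF" or "LSODA").
    """

    abs_tol: float = 1e-30
    rel_tol: float = 1e-7
    output_interval: float = 60.0
    max_step: Optional[float] = None
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.abs_tol <= 0 or self.rel_tol <= 0 or self.output_interval <= 0:
            raise ValueError("tolerances and output_interval must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TimeCourse:
    """Solver output resampled on the uniform read grid.

    ``conc`` is species x time (M); ``untracked`` accumulates released
    species that are not part of the dynamic state (fibrinopeptides etc.).
    """

    times: np.ndarray  # s
    conc: np.ndarray  # (n_species, n_times) M
    eps: np.ndarray
    iia_max: np.ndarray
    species_names: list[str]
    untracked: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    untracked_names: list[str] = field(default_factory=list)
    model_label: str = ""
    scenario_label: str = ""
    nfev: int = 0

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def __getitem__(self, name: str) -> np.ndarray:
        if name in self.species_names:
            return self.conc[self.index(name)]
        if name in self.untracked_names:
            return self.untracked[self.untracked_names.index(name)]
        raise KeyError(name)

    def moiety_total(self, atom: str) -> np.ndarray:
        """Time series of a conserved-moiety total, including untracked."""
        from .network import atoms_of

        tot = np.zeros_like(self.times, dtype=float)
        for i, n in enumerate(self.species_names):
            w = atoms_of(n).get(atom, 0)
            if w:
                tot += w * self.conc[i]
        for i, n in enumerate(self.untracked_names):
            w = atoms_of(n).get(atom, 0)
            if w:
                tot += w * self.untracked[i]
        return tot

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.conc.T, columns=[f"{n}_M" for n in self.species_names])
        df.insert(0, "time_s", self.times)
        df["eps"] = self.eps
        df["iia_max_M"] = self.iia_max
        return df

    def to_tidy_frame(self) -> pd.DataFrame:
        n_t = len(self.times)
        return pd.DataFrame(
            {
                "time_s": np.tile(self.times, len(self.species_names)),
                "species": np.repeat(self.species_names, n_t),
                "conc_M": self.conc.reshape(-1),
            }
        )


def simulate(
    model: ModelSpec,
    scenario: Optional[Scenario] = None,
    settings: Optional[SolverSettings] = None,
) -> TimeCourse:
    """Integrate a model (optionally transformed by a scenario).

    Deterministic for fixed inputs.  Raises SimulationError on integrator
    failure, carrying the last good time.
    """
    settings = settings or SolverSettings()
    horizon = scenario.horizon if scenario is not None else 14400.0
    m = apply_scenario(model, scenario) if scenario is not None else model
    cm = assemble_rhs(m)
    y0 = cm.initial_state()
    t_eval = np.arange(0.0, horizon + 0.5 * settings.output_interval, settings.output_interval)
    t_eval = t_eval[t_eval <= horizon]
    if t_eval[-1] < horizon:
        t_eval = np.append(t_eval, horizon)

    kwargs = dict(
        method=settings.method,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        t_eval=t_eval,
        dense_output=False,
    )
    if settings.max_step is not None:
        kwargs["max_step"] = settings.max_step
    if settings.method in ("LSODA", "BDF", "Radau"):
        kwargs["jac"] = cm.jac
    sol = solve_ivp(cm, (0.0, horizon), y0, **kwargs)
    if not sol.success:
        raise SimulationError(
            f"stiff integration failed: {sol.message}; nfev={sol.nfev}",
            last_time=float(sol.t[-1]) if len(sol.t) else 0.0,
        )
    logger.info(
        "simulate[%s|%s]: %d reads, nfev=%d, njev=%d",
        m.label, settings.method, len(sol.t), sol.nfev, sol.njev,
    )
    y = sol.y
    n_sp = cm.n_species
    return TimeCourse(
        times=sol.t,
        conc=y[:n_sp],
        eps=y[cm.i_eps],
        iia_max=y[cm.i_max],
        species_names=cm.species_names,
        untracked=y[n_sp : n_sp + cm.n_untracked],
        untracked_names=cm.untracked_names,
        model_label=m.label,
        scenario_label=scenario.label if scenario is not None else "",
        nfev=int(sol.nfev),
    )


# ---------------------------------------------------------------------------
# assay metrics
# ---------------------------------------------------------------------------

def fractional_conversion(tc: TimeCourse) -> np.ndarray:
    """Fractional conversion C(t) = [AMC](t) / S0 of the fluorogenic substrate.

    S0 is the total substrate moiety at t = 0, so C is the simulated analogue
    of the experimental (F - F_min)/(F_max - F_min) under complete-conversion
    normalization.
    """
    if "AMC" not in tc.species_names:
        raise MetricError("model has no detection chemistry (AMC absent)")
    s0 = float(tc.moiety_total("AMC")[0])
    if s0 <= 0:
        raise MetricError("initial fluorogenic substrate is zero")
    return tc["AMC"] / s0


def _interp_crossing(times: np.ndarray, series: np.ndarray, level: float) -> Optional[float]:
    above = series >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    c0, c1 = series[i - 1], series[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (level - c0) * (t1 - t0) / (c1 - c0))


def initiation_time(
    times: np.ndarray,
    conversion: np.ndarray,
    criterion: str = "threshold_5pct",
    threshold: float = 0.05,
    smooth_window: int = 5,
) -> Optional[float]:
    """Initiation time in minutes, or None if the criterion is never met.

    threshold_5pct -- first crossing of ``threshold`` (default 5% substrate
        conversion), located by linear interpolation between read points.
    d2max -- time of the maximal central-difference second derivative of the
        conversion trace after a moving-average smoothing (window in reads);
        None when the trace never accelerates (no positive second derivative
        away from the smoothing-affected edges), as for a flat or purely
        saturating signal.
    """
    times = np.asarray(times, float)
    conversion = np.asarray(conversion, float)
    decreasing = np.diff(conversion) < -1e-9
    if decreasing.any():
        logger.warning(
            "conversion series is non-monotone at %d points; metrics computed anyway",
            int(decreasing.sum()),
        )
    if criterion == "threshold_5pct":
        t = _interp_crossing(times, conversion, threshold)
        return None if t is None else t / 60.0
    if criterion == "d2max":
        w = max(1, int(smooth_window))
        if len(conversion) < 2 * w + 3:
            return None
        kernel = np.ones(w) / w
        smoothed = np.convolve(conversion, kernel, mode="same")
        d2 = np.zeros_like(smoothed)
        d2[1:-1] = smoothed[2:] - 2 * smoothed[1:-1] + smoothed[:-2]
        interior = d2[w:-w]
        if interior.max() <= 0.0:
            return None
        return float(times[w + int(np.argmax(interior))]) / 60.0
    raise ValueError(f"unknown criterion {criterion!r}")


@dataclass
class AssayMetrics:
    """Summary metrics of one simulated (or measured) well."""

    conversion: np.ndarray
    t_i_5pct: Optional[float]  # min
    t_i_d2max: Optional[float]  # min
    iia_at_ti: Optional[float]  # M
    peak_iia: float  # M
    time_of_10nM_iia: Optional[float]  # min
    pre_first_read: bool = False

    def to_dict(self) -> dict:
        return {
            "t_i_5pct_min": self.t_i_5pct,
            "t_i_d2max_min": self.t_i_d2max,
            "iia_at_ti_nM": None if self.iia_at_ti is None else self.iia_at_ti * 1e9,
            "peak_iia_nM": self.peak_iia * 1e9,
            "time_of_10nM_iia_min": self.time_of_10nM_iia,
            "pre_first_read": self.pre_first_read,
        }


def compute_metrics(tc: TimeCourse, output_interval: float = 60.0) -> AssayMetrics:
    conv = fractional_conversion(tc)
    ti = initiation_time(tc.times, conv, "threshold_5pct")
    ti_d2 = initiation_time(tc.times, conv, "d2max")
    iia = tc["IIa"]
    iia_at_ti = None
    if ti is not None:
        iia_at_ti = float(np.interp(ti * 60.0, tc.times, iia))
    t10 = _interp_crossing(tc.times, iia, 1e-8)
    return AssayMetrics(
        conversion=conv,
        t_i_5pct=ti,
        t_i_d2max=ti_d2,
        iia_at_ti=iia_at_ti,
        peak_iia=float(iia.max()),
        time_of_10nM_iia=None if t10 is None else t10 / 60.0,
        pre_first_read=bool(ti is not None and ti * 60.0 < output_interval),
    )


# ---------------------------------------------------------------------------
# local sensitivity
# ---------------------------------------------------------------------------

def _perturbed_model(model: ModelSpec, parameter: str, factor: float) -> ModelSpec:
    """Return a copy of ``model`` with one parameter scaled by ``factor``.

    Parameter ids: "rxn<id>.<rate>" (e.g. "rxn29.k_first", "rxn17.k_on") or
    "init.<species>" for an initial concentration.
    """
    if parameter.startswith("init."):
        name = parameter[5:]
        found = False
        species = []
        for sp in model.species:
            if sp.name == name:
                sp = dataclasses.replace(sp, initial_conc=sp.initial_conc * factor)
                found = True
            species.append(sp)
        if not found:
            raise KeyError(f"unknown species {name!r}")
        return dataclasses.replace(model, species=species)
    if parameter.startswith("rxn"):
        rid_s, _, rate_name = parameter[3:].partition(".")
        rid = int(rid_s)
        reactions = []
        found = False
        for r in model.reactions:
            if r.id == rid:
                value = getattr(r.rates, rate_name)
                if value is None:
                    raise KeyError(f"reaction {rid} has no rate {rate_name!r}")
                rates = dataclasses.replace(r.rates, **{rate_name: value * factor})
                r = dataclasses.replace(r, rates=rates)
                found = True
            reactions.append(r)
        if not found:
            raise KeyError(f"no reaction with id {rid}")
        return dataclasses.replace(model, reactions=reactions)
    raise KeyError(f"cannot parse parameter id {parameter!r}")


@dataclass
class SensitivityResult:
    parameter: str
    delta: float
    coefficient: Optional[float]  # d ln T_i / d ln k
    one_sided: bool
    ti_plus: Optional[float]
    ti_minus: Optional[float]
    ti_control: Optional[float]


def local_sensitivity(
    model: ModelSpec,
    scenario: Scenario,
    parameter: str,
    delta: float = 0.05,
    settings: Optional[SolverSettings] = None,
    scheme: str = "central",
) -> SensitivityResult:
    """Normalized local sensitivity of T_i to one parameter.

    Central-difference estimate of d ln T_i / d ln k using multiplicative
    perturbations (1 +/- delta).  If one perturbed run never initiates, a
    one-sided estimate against the unperturbed run is returned and flagged.
    """
    if not 0.0 < delta <= 0.5:
        raise ValueError("delta must be in (0, 0.5]")

    def run(m: ModelSpec) -> Optional[float]:
        tc = simulate(m, scenario, settings)
        return initiation_time(tc.times, fractional_conversion(tc))

    ti_plus = run(_perturbed_model(model, parameter, 1.0 + delta))
    ti_minus = (
        None if scheme == "forward" else run(_perturbed_model(model, parameter, 1.0 - delta))
    )
    ti_control = None
    one_sided = False
    coeff: Optional[float] = None
    if scheme == "forward" or ti_minus is None or ti_plus is None:
        ti_control = run(model)
        one_sided = scheme != "forward"
        if ti_plus is not None and ti_control is not None:
            coeff = (np.log(ti_plus) - np.log(ti_control)) / np.log(1.0 + delta)
        elif ti_minus is not None and ti_control is not None:
            coeff = (np.log(ti_control) - np.log(ti_minus)) / -np.log(1.0 - delta)
    else:
        coeff = (np.log(ti_plus) - np.log(ti_minus)) / (
            np.log(1.0 + delta) - np.log(1.0 - delta)
        )
    return SensitivityResult(
        parameter=parameter,
        delta=delta,
        coefficient=None if coeff is None else float(coeff),
        one_sided=one_sided,
        ti_plus=ti_plus,
        ti_minus=ti_minus,
        ti_control=ti_control,
    )
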