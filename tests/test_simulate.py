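"""Integration, assay metrics and local sensitivity."""

import numpy as np
import pytest

from coagkin import (
    Scenario,
    SolverSettings,
    TimeCourse,
    compute_metrics,
    fractional_conversion,
    initiation_time,
    local_sensitivity,
    simulate,
)
from coagkin.simulate import MetricError

ZYMOGENS = ("VII", "VIIa", "X", "IX", "II", "VIII", "V", "XII", "PK", "XI")


def _detection_timecourse(amc):
    """Minimal TimeCourse carrying detection chemistry only."""
    amc = np.asarray(amc, float)
    n = len(amc)
    s0 = 2e-6
    conc = np.vstack([s0 - amc, np.zeros(n), amc, np.zeros(n)])
    return TimeCourse(
        times=np.arange(n) * 60.0,
        conc=conc,
        eps=np.full(n, 0.01),
        iia_max=np.zeros(n),
        species_names=["Boc-VPR-MCA", "Boc-VPR-MCA=IIa", "AMC", "IIa"],
    )


def test_conversion_endpoints():
    tc = _detection_timecourse([0.0, 1e-6, 2e-6])
    conv = fractional_conversion(tc)
    assert conv[0] == 0.0
    assert conv[1] == pytest.approx(0.5)
    assert conv[2] == pytest.approx(1.0)


def test_conversion_requires_substrate():
    tc = _detection_timecourse([0.0])
    tc.conc[:] = 0.0
    with pytest.raises(MetricError):
        fractional_conversion(tc)


def test_threshold_initiation_time_linear_ramp():
    # C(t) = t/4800 crosses 0.05 at t = 240 s = 4 min
    t = np.arange(0, 4801, 60.0)
    assert initiation_time(t, t / 4800.0) == pytest.approx(4.0)


def test_initiation_time_none_when_saturating_below_threshold():
    t = np.arange(0, 14401, 60.0)
    c = 0.04 * (1 - np.exp(-t / 1000))
    assert initiation_time(t, c) is None
    assert initiation_time(t, c, criterion="d2max") is None


def test_d2max_on_logistic_follows_threshold_crossing():
    """For a logistic centred at 60 min, the 5% crossing precedes the point
    of maximal acceleration (which sits at ~21% conversion)."""
    t = np.arange(0, 14401, 60.0)
    a, t0 = 0.01, 3600.0
    c = 1.0 / (1.0 + np.exp(-a * (t - t0)))
    ti_thr = initiation_time(t, c)
    ti_d2 = initiation_time(t, c, criterion="d2max")
    # analytic: threshold at t0 - ln(19)/a, d2-max at C = (3-sqrt(3))/6
    assert ti_thr == pytest.approx((t0 - np.log(19) / a) / 60.0, abs=0.2)
    c_star = (3 - np.sqrt(3)) / 6
    t_star = t0 - np.log(1 / c_star - 1) / a
    assert ti_d2 == pytest.approx(t_star / 60.0, abs=2.0)
    assert ti_thr < ti_d2
    assert 50 < ti_thr < 70 and 50 < ti_d2 < 70


def test_all_zymogens_zeroed_gives_flat_zero_thrombin(pp_model):
    sc = Scenario(knockouts={z: 0.0 for z in ZYMOGENS}, horizon=3600.0)
    tc = simulate(pp_model, sc)
    assert np.all(tc["IIa"] == 0.0)
    assert np.all(fractional_conversion(tc) == 0.0)


def test_simulation_is_deterministic(pp_model):
    sc = Scenario(horizon=1800.0)
    a = simulate(pp_model, sc)
    b = simulate(pp_model, sc)
    assert np.array_equal(a.conc, b.conc)
    assert np.array_equal(a.eps, b.eps)


def test_initiation_time_robust_to_tighter_tolerance(pp_model, tc_resting):
    ti_ref = initiation_time(tc_resting.times, fractional_conversion(tc_resting))
    tight = SolverSettings(rel_tol=1e-9)
    tc = simulate(pp_model, Scenario(), tight)
    ti = initiation_time(tc.times, fractional_conversion(tc))
    assert abs(ti - ti_ref) < 0.1


def test_concentrations_stay_nonnegative(tc_resting, tc_whole_blood_tf):
    for tc in (tc_resting, tc_whole_blood_tf):
        peak = tc.conc.max(axis=1)
        floor = tc.conc.min(axis=1)
        assert np.all(floor >= -1e-12 * np.maximum(peak, 1e-30))


def test_eps_stays_within_bounds(tc_resting):
    assert tc_resting.eps[0] == pytest.approx(0.01)
    assert np.all(tc_resting.eps >= 0.01 - 1e-9)
    assert np.all(tc_resting.eps <= 1.0 + 1e-9)
    # running max is non-decreasing
    assert np.all(np.diff(tc_resting.iia_max) >= -1e-20)


def test_metrics_summary(tc_resting):
    met = compute_metrics(tc_resting)
    assert met.t_i_5pct is not None and not met.pre_first_read
    assert met.iia_at_ti > 0 and met.peak_iia > met.iia_at_ti
    assert met.time_of_10nM_iia is not None
    d = met.to_dict()
    assert d["t_i_5pct_min"] == met.t_i_5pct
    assert d["peak_iia_nM"] == pytest.approx(met.peak_iia * 1e9)


def test_sensitivity_xiia_source_shortens_initiation(pp_model):
    """A faster XIIa leak must shorten T_i (negative log-sensitivity)."""
    res = local_sensitivity(pp_model, Scenario(), "rxn29.k_first", delta=0.05)
    assert res.coefficient is not None and res.coefficient < 0
    assert not res.one_sided
    fwd = local_sensitivity(
        pp_model, Scenario(), "rxn29.k_first", delta=0.05, scheme="forward"
    )
    assert fwd.coefficient == pytest.approx(res.coefficient, rel=0.2)


def test_sensitivity_parameter_addressing(pp_model):
    with pytest.raises(KeyError):
        local_sensitivity(pp_model, Scenario(), "rxn99.k_on")
    with pytest.raises(KeyError):
        local_sensitivity(pp_model, Scenario(), "init.Ghost")
    with pytest.raises(ValueError):
        local_sensitivity(pp_model, Scenario(), "rxn29.k_first", delta=0.9)
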