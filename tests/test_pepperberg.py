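"""Saturation-time measurement, Pepperberg curves, linear fits, shapes."""

import math

import numpy as np
import pytest

import rodcascade as rc
from rodcascade.pepperberg import (
    PepperbergCurve,
    curve_shape,
    default_window,
    fit_linear,
    measure_tsat,
    pepperberg_curve,
)
from rodcascade.presets import apply_preset


class _SyntheticResponse:
    """Analytic stand-in trajectory: J/J_dark = 0 until T, then
    1 - exp(-(t-T)/tau).  The criterion crossing has a closed form."""

    def __init__(self, T=1.0, tau=0.3, j_dark=14.0, t_max=10.0, n=2001):
        self.T, self.tau, self.j_dark = T, tau, j_dark
        self.t = np.linspace(0.0, t_max, n)
        self.j = self.current_at(self.t)

    def current_at(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.T, 0.0,
                       self.j_dark * (1.0 - np.exp(-(t - self.T) / self.tau)))
        return float(out) if out.ndim == 0 else out


@pytest.mark.parametrize("criterion", [0.02, 0.10, 0.20])
def test_tsat_matches_closed_form_crossing(criterion):
    r = _SyntheticResponse(T=1.2, tau=0.25)
    expect = r.T + r.tau * math.log(1.0 / (1.0 - criterion))
    assert measure_tsat(r, criterion) == pytest.approx(expect, abs=1e-6)


def test_subsaturating_response_returns_none():
    r = _SyntheticResponse()
    r.j = r.j_dark * (0.5 + 0.1 * np.sin(r.t))     # never below 20%
    assert measure_tsat(r, 0.20) is None


def test_trajectory_ending_below_criterion_raises():
    r = _SyntheticResponse(T=1.0, tau=0.3, t_max=1.05)
    with pytest.raises(RuntimeError, match="t_max"):
        measure_tsat(r, 0.20)


def test_higher_criterion_crosses_later(wt):
    resp = rc.simulate_flash(wt, float(np.exp(7.0)), 10.0)
    assert measure_tsat(resp, 0.20) > measure_tsat(resp, 0.02)


def test_invalid_criterion_and_origin_rejected():
    r = _SyntheticResponse()
    with pytest.raises(ValueError):
        measure_tsat(r, 1.5)
    with pytest.raises(ValueError):
        measure_tsat(r, 0.1, origin="nonsense")


# ------------------------------------------------------------- curves

def test_empty_phi_list_gives_empty_curve(wt):
    curve = pepperberg_curve(wt, [], 0.10)
    assert len(curve) == 0 and curve.non_saturating_phi.size == 0


def test_curve_tsat_monotone_in_flash_strength(fig3_result):
    for label, curve in fig3_result.curves.items():
        assert np.all(np.diff(curve.t_sat) > 0), label


def test_rgs9_overexpression_shortens_saturation_everywhere(fig3_result):
    c_wt = fig3_result.curves["WT@0.1"]
    c_4x = fig3_result.curves["RGS9_4x@0.1"]
    common = np.intersect1d(c_wt.phi, c_4x.phi)
    t_wt = dict(zip(c_wt.phi, c_wt.t_sat))
    t_4x = dict(zip(c_4x.phi, c_4x.t_sat))
    assert common.size >= 8
    assert all(t_4x[p] < t_wt[p] for p in common)


# --------------------------------------------------------------- fits

def test_ols_recovers_exactly_collinear_points():
    ln_phi = np.linspace(5.0, 8.0, 7)
    tau, intercept = 0.25, -1.0
    curve = PepperbergCurve(
        phi=np.exp(ln_phi), t_sat=tau * ln_phi + intercept,
        criterion=0.02, origin="mid_flash",
    )
    fit = fit_linear(curve, window=(5.0, 8.0))
    assert fit.tau_d == pytest.approx(tau, abs=1e-12)
    assert fit.ln_phi0 == pytest.approx(-intercept / tau, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0)


def test_fit_requires_three_window_points():
    curve = PepperbergCurve(
        phi=np.exp([5.0, 6.0, 9.0]), t_sat=np.array([0.5, 0.9, 2.0]),
        criterion=0.02, origin="mid_flash",
    )
    with pytest.raises(ValueError, match=">= 3"):
        fit_linear(curve, window=(5.5, 8.0))


def test_degenerate_flat_curve_rejected():
    ln_phi = np.linspace(5.0, 8.0, 5)
    curve = PepperbergCurve(
        phi=np.exp(ln_phi), t_sat=np.full(5, 2.0) - 0.01 * ln_phi,
        criterion=0.02, origin="mid_flash",
    )
    with pytest.raises(ValueError, match="slope"):
        fit_linear(curve, window=(5.0, 8.0))


def test_default_window_starts_above_just_saturating(fig3_result):
    curve = fig3_result.curves["WT@0.1"]
    lo, hi = default_window(curve)
    assert lo == pytest.approx(curve.ln_phi[0] + 0.5)
    assert hi == 8.0


def test_fitted_slope_matches_front_end_eigenvalue_oracle(wt, fig3_result):
    """The fitted WT Pepperberg slope estimates the slowest shutoff time
    constant of the linearized transducin/PDE/RGS9 subsystem."""
    fit = fig3_result.fits["WT@0.1"]
    tau_eigen = rc.tau_e_star(wt)
    assert fit.tau_d == pytest.approx(tau_eigen, rel=0.10)


# -------------------------------------------------------------- shapes

def test_perfectly_linear_curve_has_no_bend_or_plateau():
    ln_phi = np.linspace(5.0, 16.0, 20)
    curve = PepperbergCurve(
        phi=np.exp(ln_phi), t_sat=0.3 * ln_phi - 1.0,
        criterion=0.20, origin="mid_flash",
    )
    shape = curve_shape(curve)
    assert shape["bend_onset_ln_phi"] is None
    assert shape["plateau_onset_ln_phi"] is None
    assert shape["max_local_slope_s"] == pytest.approx(0.3)


def test_short_curve_returns_explicit_nulls():
    curve = PepperbergCurve(
        phi=np.exp([5.0, 6.0]), t_sat=np.array([0.4, 0.7]),
        criterion=0.20, origin="mid_flash",
    )
    shape = curve_shape(curve)
    assert all(v is None for v in shape.values())


def test_max_local_slope_at_least_fitted_slope(fig5_shapes):
    for name, entry in fig5_shapes.items():
        if entry["fit"] is None:
            continue
        assert entry["shape"]["max_local_slope_s"] >= entry["fit"].tau_d, name


def test_wt_bend_onset_in_upward_bend_regime(fig5_shapes):
    """The WT curve leaves its linear domain in the ln Phi ~ 8-12 band
    (between the linear exemplar at 8 and deep-bend exemplar at 14)."""
    bend = fig5_shapes["WT"]["shape"]["bend_onset_ln_phi"]
    assert bend is not None and 8.0 <= bend <= 12.0
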