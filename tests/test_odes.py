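"""Right-hand sides: conservation, closed-form chain solutions, and the
linearized front-end eigenstructure."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import rodcascade as rc
from rodcascade.odes import (
    RodState,
    front_end_jacobian,
    front_end_rhs,
    full_rhs,
    messenger_rhs,
    rhodopsin_rhs,
    simplified_front_end_rhs,
)
from rodcascade.rate_laws import cng_current, exchanger_current, phospho_rates
from rodcascade.equilibria import dark_messengers


def test_dark_rhodopsin_chain_is_inert(wt):
    lam = phospho_rates(0.05, wt)
    mu = np.asarray(wt.mu_vector())
    dr = rhodopsin_rhs(np.zeros(wt.n_sites + 1), lam, mu)
    assert np.all(dr == 0.0)


def test_first_state_decays_with_closed_form_at_clamped_calcium(wt):
    """With Ca2+ (hence lambda) frozen, r1(t) = Phi e^{-(lambda1+mu1) t}."""
    lam = phospho_rates(0.0, wt)          # frozen at maximal rates
    mu = np.asarray(wt.mu_vector())
    phi = 1.0
    y0 = np.zeros(wt.n_sites + 1)
    y0[0] = phi
    sol = solve_ivp(
        lambda t, y: rhodopsin_rhs(y, lam, mu), (0, 0.2), y0,
        rtol=1e-10, atol=1e-14, dense_output=True,
    )
    for t in (0.01, 0.05, 0.1, 0.2):
        assert sol.sol(t)[0] == pytest.approx(
            phi * np.exp(-(lam[0] + mu[0]) * t), rel=1e-7
        )


def test_total_rhodopsin_decays_only_by_arrestin_capture(wt):
    rng = np.random.default_rng(7)
    r = rng.uniform(0, 2, wt.n_sites + 1)
    lam = phospho_rates(0.08, wt)
    mu = np.asarray(wt.mu_vector())
    dr = rhodopsin_rhs(r, lam, mu)
    # the phosphorylation terms telescope; only arrestin removes R*
    assert dr.sum() == pytest.approx(-(mu * r).sum(), rel=1e-12)


def test_front_end_conserves_all_three_pools_exactly(wt):
    rng = np.random.default_rng(11)
    t_free, t_star, e_free, te, rgs9, rgs9_te = rng.uniform(0.1, 50, 6)
    d = front_end_rhs(t_free, t_star, e_free, te, rgs9, rgs9_te, 12.3, wt)
    d_t, d_tstar, d_e, d_te, d_rgs9, d_rgs9_te = d
    assert d_t + d_tstar + d_te + d_rgs9_te == pytest.approx(0.0, abs=1e-12)
    assert d_e + d_te + d_rgs9_te == pytest.approx(0.0, abs=1e-12)
    assert d_rgs9 + d_rgs9_te == pytest.approx(0.0, abs=1e-12)


def test_dark_front_end_is_inert(wt):
    d = front_end_rhs(wt.T0, 0.0, wt.E0, 0.0, wt.RGS9_0, 0.0, 0.0, wt)
    assert all(v == 0.0 for v in d)


def test_linearized_front_end_matches_finite_difference_jacobian(wt):
    """The analytic 3x3 Jacobian of the activated subsystem agrees with a
    finite-difference linearization of the full RHS about the dark state."""
    cg, ca = dark_messengers(wt)
    y0 = RodState.dark(cg, ca, wt).to_vector()
    m = wt.n_sites + 1
    idx = [3 + m, 5 + m, 7 + m]          # T*, T*--E, RGS9--T*--E
    eps = 1e-7
    J = np.empty((3, 3))
    f0 = full_rhs(0.0, y0, wt)
    for col, i in enumerate(idx):
        y = y0.copy()
        y[i] += eps
        J[:, col] = (full_rhs(0.0, y, wt)[idx] - f0[idx]) / eps
    analytic = front_end_jacobian(wt)
    assert np.allclose(J, analytic, rtol=1e-5, atol=1e-6)
    ev_num = np.sort(np.linalg.eigvals(J).real)
    ev_ana = np.sort(np.linalg.eigvals(analytic).real)
    assert np.allclose(ev_num, ev_ana, rtol=1e-5)


def test_messenger_rhs_vanishes_at_dark_state(wt):
    cg, ca = dark_messengers(wt)
    dcg, dca = messenger_rhs(cg, ca, 0.0, wt)
    assert abs(dcg) < 1e-9 * max(cg, 1.0)
    assert abs(dca) < 1e-9 * max(ca, 1.0)


def test_full_effector_activation_gives_maximal_hydrolysis(wt):
    cg = 2.0
    dcg, _ = messenger_rhs(cg, 0.05, wt.E_tot, wt)
    expected = rc.cyclase_rate(0.05, wt) - wt.k_sigma_hyd * wt.E_tot * cg
    assert dcg == pytest.approx(expected, rel=1e-12)


def test_calcium_derivative_zero_at_flux_balance(wt):
    """dCa/dt vanishes exactly at the Ca2+ solving (f_Ca/2) J_cG = J_ex,
    found independently by a scalar root search."""
    from scipy.optimize import brentq
    cg = 1.5

    def g(ca):
        return 0.5 * wt.f_Ca * cng_current(cg, ca, wt) - exchanger_current(ca, wt)

    ca_star = brentq(g, 1e-9, 10.0, xtol=1e-14)
    _, dca = messenger_rhs(cg, ca_star, 0.0, wt)
    assert abs(dca) < 1e-9


def test_simplified_estar_decays_single_exponentially(wt):
    """With no R* input and no T*, E* decays as e^{-k_E t}."""
    m = wt.n_sites + 1
    e0 = 3.0
    sol = solve_ivp(
        lambda t, y: np.array(
            simplified_front_end_rhs(y[0], y[1], 0.0, wt)
        ),
        (0, 1.5), [0.0, e0], rtol=1e-10, atol=1e-14, dense_output=True,
    )
    for t in (0.2, 0.7, 1.5):
        assert sol.sol(t)[1] == pytest.approx(
            e0 * np.exp(-wt.k_E * t), rel=1e-7
        )


def test_full_model_approaches_simplified_when_rgs9_step_dominates(wt):
    """When RGS9 binding is effectively irreversible and GTP hydrolysis in
    the bound complex is fast, the explicit RGS9 shutoff reduces to
    first-order E* decay at rate k_E = k_f [RGS9]0.  The trajectory gap is
    controlled by the occupancy ratio k_f [RGS9]0 / k_cat and shrinks as
    the hydrolysis step speeds up."""
    phi = float(np.exp(6.0))
    k_f = 0.08
    k_e = k_f * wt.RGS9_0
    p_simp = wt.replace(k_E=k_e)
    r_simp = rc.simulate_flash(p_simp, phi, 4.0, variant="simplified")
    t = np.linspace(0.01, 4.0, 200)
    m = wt.n_sites + 1
    ys = np.stack([r_simp.state_at(ti) for ti in t])
    e_simp = ys[:, 3 + m]
    gaps = []
    for k_cat in (50.0, 200.0, 800.0):
        p_full = wt.replace(k_f=k_f, k_b=1e-4, k_cat=k_cat)
        r_full = rc.simulate_flash(p_full, phi, 4.0)
        yf = np.stack([r_full.state_at(ti) for ti in t])
        e_full = yf[:, 5 + m] + yf[:, 7 + m]
        gaps.append(np.max(np.abs(e_full - e_simp)) / np.max(e_simp))
    assert gaps[-1] < 0.02
    assert gaps[0] > gaps[1] > gaps[2]
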