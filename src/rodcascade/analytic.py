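"""Closed-form theory of the Pepperberg relation.

In the linear domain the saturation time obeys

    T_sat = tau_E* ln(Phi) - tau_E* ln(Phi_0),      Phi_0 = E*_char / (nu_RE tau_R*)

where tau_E* is the dominant (T*--E shutoff) time constant, tau_R* the mean
R* lifetime, nu_RE the lumped R* -> E* activation gain, and E*_char the
activated-effector level at the moment the photocurrent re-crosses the
criterion fraction ``eps`` of the dark current.  E*_char follows from the
quasi-steady saturation balance of cGMP synthesis and hydrolysis:

    alpha - k_hyd E_tot cg_sat - k_sigma_hyd E*_char cg_sat = 0

with (cg_sat, ca_sat) the messenger levels solving the exit-of-saturation
system.  The family of lines over varying tau_E* passes through the common
point (ln Phi_0, 0), and C = -tau_E* ln Phi_0 is the constant offset of the
classical T_sat = tau_E* ln(Phi) + C form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import equilibria
from .odes import front_end_jacobian
from .parameters import Params
from .rate_laws import cyclase_rate, phospho_rates

__all__ = [
    "SaturationSolution",
    "saturation_state",
    "e_char",
    "tau_e_star",
    "tau_r_star",
    "nu_re",
    "phi_naught",
    "tsat_closed",
    "tsat_two_exponential",
    "solve_saturation",
]


@dataclass(frozen=True)
class SaturationSolution:
    """Bundle of closed-form saturation quantities."""

    cg_sat: float        # uM
    ca_sat: float        # uM
    e_char: float        # uM
    phi0: float          # photoisomerizations
    c_const: float       # s, C = -tau_E* ln(Phi_0)
    epsilon: float

    def to_dict(self) -> dict:
        return {
            "cg_sat_uM": self.cg_sat,
            "ca_sat_uM": self.ca_sat,
            "e_char_uM": self.e_char,
            "phi0": self.phi0,
            "ln_phi0": math.log(self.phi0),
            "c_const_s": self.c_const,
            "eps": self.epsilon,
        }


def saturation_state(p: Params, eps: float | None = None) -> tuple[float, float]:
    """(cGMP, Ca2+) at the exit of saturation, J = eps * J_max."""
    if eps is None:
        eps = p.epsilon
    return equilibria.saturation_messengers(p, eps)


def e_char(
    p: Params, eps: float | None = None, alpha_mode: str = "ca_sat"
) -> float:
    """Characteristic activated-effector level E*_char at T_sat, uM.

    ``alpha_mode`` selects the cyclase rate used in the quasi-steady
    balance: ``"ca_sat"`` evaluates alpha at the solved (near-minimal)
    saturation Ca2+; ``"max"`` uses the strict low-Ca2+ limit alpha_max.
    The basal-hydrolysis term k_hyd E_tot cg_sat is retained in both.
    """
    if eps is None:
        eps = p.epsilon
    cg_sat, ca_sat = saturation_state(p, eps)
    if alpha_mode == "ca_sat":
        alpha = cyclase_rate(ca_sat, p)
    elif alpha_mode == "max":
        alpha = p.alpha_max if p.alpha_freeze is None else p.alpha_freeze
    else:
        raise ValueError(f"alpha_mode must be 'ca_sat' or 'max' (got {alpha_mode!r})")
    val = (alpha - p.k_hyd * p.E_tot * cg_sat) / (p.k_sigma_hyd * cg_sat)
    if val <= 0:
        raise RuntimeError(
            "inconsistent parameters: basal hydrolysis exceeds cyclase "
            "synthesis at the saturation state (E*_char <= 0)"
        )
    return val


def tau_e_star(p: Params) -> float:
    """Dominant T*--E shutoff time constant from the linearized front end, s.

    Slowest decay eigenvalue of the (T*, T*--E, RGS9--T*--E) subsystem
    about the dark state.
    """
    lam = np.linalg.eigvals(front_end_jacobian(p))
    return float(1.0 / np.min(-lam.real))


def tau_r_star(p: Params, ca: float | None = None) -> float:
    """Mean lifetime of the unphosphorylated R* state, 1/(lambda_1 + mu_1), s.

    Evaluated by default at the saturation Ca2+ (Ca2+ is near-minimal
    throughout saturation, so the phosphorylation rates sit at their maxima).
    """
    if ca is None:
        _, ca = saturation_state(p, p.epsilon)
    lam = phospho_rates(ca, p)
    mu = p.mu_vector()
    return float(1.0 / (lam[0] + mu[0]))


def nu_re(p: Params) -> float:
    """Lumped R* -> E* activation gain, s^-1.

    When not supplied explicitly, nu_RE is derived from the front end as
    nu_RT multiplied by the steady coupling efficiency of T* into T*--E,
    k_TE E0 / (k_TE E0 + k_f RGS9_0); with the packaged defaults the
    coupling is nearly complete and nu_RE is close to nu_RT.
    """
    if p.nu_RE is not None:
        return p.nu_RE
    coupling = p.k_TE * p.E0 / (p.k_TE * p.E0 + p.k_f * p.RGS9_0)
    return p.nu_RT * coupling


def phi_naught(p: Params, eps: float | None = None) -> tuple[float, float]:
    """Just-saturating flash strength Phi_0 and the constant C, (count, s).

    Phi_0 = E*_char / (nu_RE tau_R*) with E*_char converted to molecule
    count; C = -tau_E* ln(Phi_0).
    """
    if eps is None:
        eps = p.epsilon
    ec_molecules = e_char(p, eps) / p.uM_per_molecule
    phi0 = ec_molecules / (nu_re(p) * tau_r_star(p))
    c = -tau_e_star(p) * math.log(phi0)
    return phi0, c


def solve_saturation(p: Params, eps: float | None = None) -> SaturationSolution:
    """All closed-form saturation quantities for a parameter set."""
    if eps is None:
        eps = p.epsilon
    cg_sat, ca_sat = saturation_state(p, eps)
    phi0, c = phi_naught(p, eps)
    return SaturationSolution(
        cg_sat=cg_sat, ca_sat=ca_sat, e_char=e_char(p, eps),
        phi0=phi0, c_const=c, epsilon=eps,
    )


def tsat_closed(
    p: Params, phi: float, eps: float | None = None
) -> tuple[float, bool]:
    """Closed-form saturation time tau_E* ln(Phi / Phi_0), s.

    Returns ``(t_sat, saturating)``; a flash at or below Phi_0 yields
    ``(0.0, False)``.
    """
    phi0, _ = phi_naught(p, eps)
    if phi <= phi0:
        return 0.0, False
    return tau_e_star(p) * math.log(phi / phi0), True


def tsat_two_exponential(
    p: Params, phi: float, eps: float | None = None
) -> float:
    """Saturation time from the un-approximated two-exponential balance, s.

    Solves  E*(T) = nu_RE Phi tau_R* tau_E* / (tau_E* - tau_R*)
                    (e^{-T/tau_E*} - e^{-T/tau_R*})  =  E*_char
    numerically for T; for tau_R* << tau_E* this approaches the closed form.
    """
    if eps is None:
        eps = p.epsilon
    tr, te = tau_r_star(p), tau_e_star(p)
    ec = e_char(p, eps) / p.uM_per_molecule   # molecule count
    amp = nu_re(p) * phi * tr * te / (te - tr)

    def f(t: float) -> float:
        return amp * (math.exp(-t / te) - math.exp(-t / tr)) - ec

    t_peak = (te * tr / (te - tr)) * math.log(te / tr)
    if f(t_peak) <= 0:
        raise ValueError(
            f"flash phi = {phi!r} never drives E* above E*_char; "
            "no saturation time"
        )
    hi = t_peak
    while f(hi) > 0:
        hi *= 2.0
    return brentq(f, t_peak, hi, xtol=1e-12, rtol=8.9e-16)
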