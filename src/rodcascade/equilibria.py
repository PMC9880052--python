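"""Algebraic steady states of the second-messenger subsystem.

Two 2x2 systems in (cGMP, Ca2+) recur throughout the package:

* the dark steady state, where cyclase synthesis balances basal hydrolysis
  and the Ca2+ influx through the CNG channels balances exchanger extrusion;
* the quasi-steady saturation state, where the residual photocurrent equals
  a small fraction ``eps`` of the dark current while the Ca2+ fluxes balance.

Both reduce to a scalar root-find and are solved to near machine precision.
"""

from __future__ import annotations

from scipy.optimize import brentq

from .parameters import Params
from .rate_laws import (
    channel_affinity,
    cng_current,
    cyclase_rate,
    exchanger_current,
)

__all__ = ["dark_messengers", "dark_current", "saturation_messengers"]

_XTOL = 1e-14
_RTOL = 8.881784197001252e-16  # 4 * machine epsilon, brentq minimum


def dark_messengers(p: Params) -> tuple[float, float]:
    """Dark-adapted (cGMP, Ca2+) in uM.

    Eliminates cGMP through the synthesis/hydrolysis balance
    ``alpha(Ca) = k_hyd * E_tot * cg`` and solves the Ca2+ flux balance
    ``(f_Ca/2) J_cG = J_ex`` by bracketing + Brent's method.  The residual
    function is strictly decreasing in Ca2+, so the root is unique.
    """
    beta_dark = p.k_hyd * p.E_tot

    def cg_of(ca: float) -> float:
        return cyclase_rate(ca, p) / beta_dark

    def g(ca: float) -> float:
        return 0.5 * p.f_Ca * cng_current(cg_of(ca), ca, p) - exchanger_current(ca, p)

    lo, hi = 1e-9, 1.0
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError(
                "dark steady state: no Ca2+ flux balance below 1 M "
                f"(residual at {hi / 2} uM = {g(hi / 2)!r} pA)"
            )
    ca = brentq(g, lo, hi, xtol=_XTOL, rtol=_RTOL)
    return cg_of(ca), ca


def dark_current(p: Params) -> float:
    """Total circulating current in darkness J_dark = J_cG + J_ex, pA."""
    cg, ca = dark_messengers(p)
    return cng_current(cg, ca, p) + exchanger_current(ca, p)


def saturation_messengers(p: Params, eps: float) -> tuple[float, float]:
    """Quasi-steady (cGMP, Ca2+) at the moment the response exits saturation.

    Solves  (1 + f_Ca/2) J_cG = eps * J_max  together with the Ca2+ flux
    balance (f_Ca/2) J_cG = J_ex, taking J_max as the dark current.  The
    exchanger relation inverts in closed form for Ca2+, after which cGMP
    follows from the channel Hill law at the (now known) channel affinity.
    """
    if not (0.0 < eps < 1.0):
        raise ValueError(f"eps must lie in (0, 1) (got {eps!r})")
    j_max = dark_current(p)
    j_cg = eps * j_max / (1.0 + 0.5 * p.f_Ca)
    j_ex = 0.5 * p.f_Ca * j_cg
    if j_ex >= p.j_ex_sat:
        raise RuntimeError(
            "saturation state: required exchange current exceeds j_ex_sat"
        )
    ca = p.K_ex * j_ex / (p.j_ex_sat - j_ex)
    q = j_cg / p.j_cg_max
    if q >= 1.0:
        raise RuntimeError("saturation state: required J_cG exceeds j_cg_max")
    cg = channel_affinity(ca, p) * (q / (1.0 - q)) ** (1.0 / p.m_cG)
    return cg, ca
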