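"""Pointwise biochemical rate laws of the phototransduction cascade.

All functions are pure: identical inputs produce bitwise-identical outputs.
Calcium and cGMP are in uM, currents in pA, rates in s^-1.
"""

from __future__ import annotations

import math

import numpy as np

from .parameters import Params

__all__ = [
    "cyclase_rate",
    "channel_affinity",
    "cng_current",
    "exchanger_current",
    "rk_fraction",
    "phospho_rates",
]


def _check_nonneg(value: float, name: str) -> None:
    if not (value >= 0):
        raise ValueError(f"{name} must be non-negative (got {value!r})")


def cyclase_rate(ca: float, p: Params) -> float:
    """cGMP synthesis rate by the two GCAP-regulated cyclase activities, uM/s.

    Strictly decreasing in Ca2+, from ``alpha_max`` (Ca2+ -> 0) to
    ``alpha_min`` (Ca2+ -> infinity).  A GCAPs-knockout parameter set
    (``alpha_freeze`` set) returns a Ca-independent constant rate.
    """
    _check_nonneg(ca, "ca")
    if p.alpha_freeze is not None:
        return p.alpha_freeze
    if math.isinf(ca):
        return p.alpha_min
    g1 = p.beta / (1.0 + (ca / p.K_cyc1) ** p.m_cyc1)
    g2 = (1.0 - p.beta) / (1.0 + (ca / p.K_cyc2) ** p.m_cyc2)
    return p.alpha_min + (p.alpha_max - p.alpha_min) * (g1 + g2)


def channel_affinity(ca: float, p: Params) -> float:
    """Ca2+/calmodulin-modulated channel K_1/2 for cGMP, uM.

    Rises monotonically from ``K_cG_min`` (low Ca2+) to ``K_cG_max``
    (high Ca2+).  A calmodulin-site-null channel (``cam_null``) is pinned
    at ``K_cG_min``.
    """
    _check_nonneg(ca, "ca")
    if p.cam_null:
        return p.K_cG_min
    if math.isinf(ca):
        return p.K_cG_max
    w = p.K_CaM ** p.m_CaM / (p.K_CaM ** p.m_CaM + ca ** p.m_CaM)
    return p.K_cG_max + (p.K_cG_min - p.K_cG_max) * w


def cng_current(cg: float, ca: float, p: Params) -> float:
    """Current through the CNG channels, pA (Hill function of cGMP)."""
    _check_nonneg(cg, "cg")
    _check_nonneg(ca, "ca")
    if math.isinf(cg):
        return p.j_cg_max
    k = channel_affinity(ca, p)
    cgm = cg ** p.m_cG
    return p.j_cg_max * cgm / (k ** p.m_cG + cgm)


def exchanger_current(ca: float, p: Params) -> float:
    """Na+/Ca2+,K+ exchange current, pA (Michaelis form in Ca2+)."""
    _check_nonneg(ca, "ca")
    if math.isinf(ca):
        return p.j_ex_sat
    return p.j_ex_sat * ca / (p.K_ex + ca)


def rk_fraction(ca: float, p: Params) -> float:
    """Free fraction of rhodopsin kinase, [RK]/[RK]_tot in (0, 1].

    Recoverin binds two Ca2+ ions and then sequesters RK both in the
    cytosol and at the disc membrane; the coupled equilibria reduce to a
    quadratic in x = [Rec]/[Rec]_tot.  The coefficients are

        C1 = (Ca/K1)^2 (1/K3 + M/(K2 K4)) Rec_tot
        C2 = 1 + (Ca/K1)^2 (1 + M/K2)

    and x solves  C1 C2 x^2 + [C1 (RK_tot/Rec_tot - 1) + C2] x - 1 = 0,
    after which [RK]/[RK]_tot = 1/(1 + C1 x).

    With a > 0 and constant term -1 the quadratic has exactly one positive
    root, and it lies in (0, 1] because the polynomial is >= 0 at x = 1.
    The root is evaluated in the cancellation-free form.
    """
    _check_nonneg(ca, "ca")
    if p.Rec_tot == 0.0:  # recoverin knockout: all RK free
        return 1.0
    ca2 = (ca / p.K1) ** 2
    c1 = ca2 * (1.0 / p.K3 + p.M_rec / (p.K2 * p.K4)) * p.Rec_tot
    c2 = 1.0 + ca2 * (1.0 + p.M_rec / p.K2)
    if c1 == 0.0:  # ca == 0: no Ca-loaded recoverin, all RK free
        return 1.0
    a = c1 * c2
    b = c1 * (p.RK_tot / p.Rec_tot - 1.0) + c2
    disc = math.sqrt(b * b + 4.0 * a)
    if b >= 0.0:
        x = 2.0 / (b + disc)
    else:
        x = (-b + disc) / (2.0 * a)
    return 1.0 / (1.0 + c1 * x)


def phospho_rates(ca: float, p: Params) -> np.ndarray:
    """Ca-dependent phosphorylation rates lambda_j(Ca), s^-1, j = 1..n+1.

    Each per-state maximal rate is scaled by the free-RK fraction; the
    final (arrestin-quenched) state has rate 0 at every Ca2+.
    """
    frac = rk_fraction(ca, p)
    return np.asarray(p.lambda_max, dtype=float) * frac
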