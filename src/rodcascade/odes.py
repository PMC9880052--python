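"""Right-hand sides of the coupled phototransduction ODE system.

Two variants are provided:

* the **full** front end with explicit RGS9 dynamics — transducin (T, T*),
  effector subunits (E), the T*--E complex and its RGS9-bound form — coupled
  to the multi-state rhodopsin phosphorylation chain and the cGMP/Ca2+
  messenger equations;
* the **simplified** front end in which activated effector E* shuts off with
  a single first-order rate ``k_E`` (validation variant).

State layout (full variant), all concentrations in uM::

    y = [cg, ca, r_1 .. r_{n+1}, T, T*, E, T*--E, RGS9, RGS9--T*--E]

Three pools are conserved exactly by construction:
T + T* + T*--E + RGS9--T*--E,  E + T*--E + RGS9--T*--E,
and RGS9 + RGS9--T*--E.

The flash itself is *not* part of the right-hand side: a flash of strength
Phi photoisomerizations is an instantaneous jump of r_1, applied by the
simulator as a discontinuous initial condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import Params
from .rate_laws import (
    cng_current,
    cyclase_rate,
    exchanger_current,
    phospho_rates,
)

__all__ = [
    "RodState",
    "rhodopsin_rhs",
    "front_end_rhs",
    "simplified_front_end_rhs",
    "messenger_rhs",
    "full_rhs",
    "simplified_rhs",
    "n_states",
    "n_states_simplified",
    "front_end_jacobian",
]


@dataclass
class RodState:
    """Instantaneous concentrations of all dynamic species, uM."""

    cg: float
    ca: float
    r: np.ndarray           # R* phosphorylation states 1..n+1
    t_free: float
    t_star: float
    e_free: float
    te_complex: float
    rgs9_free: float
    rgs9_te_complex: float

    @property
    def e_star(self) -> float:
        """Total catalytically active effector: T*--E plus its RGS9-bound form.

        An effector subunit is taken to hydrolyze cGMP for as long as it is
        complexed with T*, including while RGS9-bound, until GTP hydrolysis
        returns it to the basal pool.
        """
        return self.te_complex + self.rgs9_te_complex

    def to_vector(self) -> np.ndarray:
        return np.concatenate((
            [self.cg, self.ca],
            self.r,
            [self.t_free, self.t_star, self.e_free,
             self.te_complex, self.rgs9_free, self.rgs9_te_complex],
        ))

    @classmethod
    def from_vector(cls, y: np.ndarray, n_sites: int) -> "RodState":
        m = n_sites + 1
        return cls(
            cg=float(y[0]), ca=float(y[1]),
            r=np.asarray(y[2:2 + m], dtype=float),
            t_free=float(y[2 + m]), t_star=float(y[3 + m]),
            e_free=float(y[4 + m]), te_complex=float(y[5 + m]),
            rgs9_free=float(y[6 + m]), rgs9_te_complex=float(y[7 + m]),
        )

    @classmethod
    def dark(cls, cg: float, ca: float, p: Params) -> "RodState":
        return cls(
            cg=cg, ca=ca, r=np.zeros(p.n_sites + 1),
            t_free=p.T0, t_star=0.0, e_free=p.E0, te_complex=0.0,
            rgs9_free=p.RGS9_0, rgs9_te_complex=0.0,
        )


def n_states(p: Params) -> int:
    """Dimension of the full state vector."""
    return 2 + (p.n_sites + 1) + 6


def n_states_simplified(p: Params) -> int:
    """Dimension of the simplified-variant state vector [.., T*, E*]."""
    return 2 + (p.n_sites + 1) + 2


def rhodopsin_rhs(r: np.ndarray, lam: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Time derivative of the R* phosphorylation chain.

    dr_1/dt = -(lambda_1 + mu_1) r_1 ;
    dr_j/dt = lambda_{j-1} r_{j-1} - (lambda_j + mu_j) r_j  for j >= 2.
    """
    dr = -(lam + mu) * r
    dr[1:] += lam[:-1] * r[:-1]
    return dr


def front_end_rhs(
    t_free: float,
    t_star: float,
    e_free: float,
    te: float,
    rgs9: float,
    rgs9_te: float,
    activation: float,
    p: Params,
) -> tuple[float, float, float, float, float, float]:
    """Transducin/PDE/RGS9 kinetics with explicit RGS9 dynamics.

    ``activation`` is the instantaneous rhodopsin catalytic activity
    sum_j nu_j [R*_j] in uM/s at full transducin availability; it is scaled
    by the free-transducin fraction T/T0 inside this function.
    """
    act = activation * (t_free / p.T0)
    v_te = p.k_TE * e_free * t_star          # T* + E -> T*--E
    v_f = p.k_f * rgs9 * te                  # RGS9 + T*--E -> RGS9--T*--E
    v_b = p.k_b * rgs9_te                    # dissociation
    v_cat = p.k_cat * rgs9_te                # GTP hydrolysis: complex decays

    d_t = -act + v_cat
    d_tstar = act - v_te
    d_e = -v_te + v_cat
    d_te = v_te - v_f + v_b
    d_rgs9 = v_cat + v_b - v_f
    d_rgs9_te = v_f - v_b - v_cat
    return d_t, d_tstar, d_e, d_te, d_rgs9, d_rgs9_te


def simplified_front_end_rhs(
    t_star: float, e_star: float, activation: float, p: Params
) -> tuple[float, float]:
    """First-order-shutoff variant: E* decays at rate ``k_E`` = 1/tau_E*."""
    act = activation * (p.T0 - t_star) / p.T0
    v_te = p.k_TE * (p.E0 - e_star) * t_star
    return act - v_te, v_te - p.k_E * e_star


def messenger_rhs(
    cg: float, ca: float, e_star: float, p: Params
) -> tuple[float, float]:
    """cGMP and Ca2+ balance equations.

    d[cGMP]/dt = alpha(Ca) - k_hyd (E_tot - E*) cg - k_sigma_hyd E* cg
    d[Ca2+]/dt = eta ( (f_Ca/2) J_cG - J_ex )
    """
    dcg = (
        cyclase_rate(ca, p)
        - p.k_hyd * (p.E_tot - e_star) * cg
        - p.k_sigma_hyd * e_star * cg
    )
    j_cg = cng_current(cg, ca, p)
    j_ex = exchanger_current(ca, p)
    dca = p.eta * (0.5 * p.f_Ca * j_cg - j_ex)
    return dcg, dca


def full_rhs(t: float, y: np.ndarray, p: Params) -> np.ndarray:
    """Complete right-hand side for the full (RGS9-explicit) model."""
    m = p.n_sites + 1
    cg = max(float(y[0]), 0.0)
    ca = max(float(y[1]), 0.0)
    r = y[2:2 + m]
    t_free, t_star, e_free, te, rgs9, rgs9_te = (float(v) for v in y[2 + m:])

    lam = phospho_rates(ca, p)
    mu = np.asarray(p.mu_vector())
    dr = rhodopsin_rhs(r, lam, mu)

    activation = float(np.dot(p.nu, r))
    d_fe = front_end_rhs(
        t_free, t_star, e_free, te, rgs9, rgs9_te, activation, p
    )
    e_star = te + rgs9_te
    dcg, dca = messenger_rhs(cg, ca, e_star, p)

    out = np.empty(y.shape[0])
    out[0], out[1] = dcg, dca
    out[2:2 + m] = dr
    out[2 + m:] = d_fe
    return out


def simplified_rhs(t: float, y: np.ndarray, p: Params) -> np.ndarray:
    """Right-hand side for the first-order-shutoff validation variant."""
    m = p.n_sites + 1
    cg = max(float(y[0]), 0.0)
    ca = max(float(y[1]), 0.0)
    r = y[2:2 + m]
    t_star, e_star = float(y[2 + m]), float(y[3 + m])

    lam = phospho_rates(ca, p)
    mu = np.asarray(p.mu_vector())
    dr = rhodopsin_rhs(r, lam, mu)

    activation = float(np.dot(p.nu, r))
    d_tstar, d_estar = simplified_front_end_rhs(t_star, e_star, activation, p)
    dcg, dca = messenger_rhs(cg, ca, e_star, p)

    out = np.empty(y.shape[0])
    out[0], out[1] = dcg, dca
    out[2:2 + m] = dr
    out[2 + m] = d_tstar
    out[3 + m] = d_estar
    return out


def front_end_jacobian(p: Params, scale_rgs9: float = 1.0) -> np.ndarray:
    """Jacobian of the (T*, T*--E, RGS9--T*--E) subsystem linearized about dark.

    In the small-flash limit (T ~ T0, E ~ E0, RGS9 ~ RGS9_0) the activated
    front-end species obey a linear cascade whose slowest eigenvalue sets the
    dominant shutoff time constant and hence the Pepperberg slope.
    """
    u = p.k_f * p.RGS9_0 * scale_rgs9
    return np.array([
        [-p.k_TE * p.E0, 0.0, 0.0],
        [p.k_TE * p.E0, -u, p.k_b],
        [0.0, u, -(p.k_b + p.k_cat)],
    ])
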