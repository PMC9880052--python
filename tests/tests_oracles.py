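"""Independent numerical oracles used by the test suite.

These deliberately avoid the implementation paths they check: the recoverin
quadratic is solved by plain bisection rather than the closed-form root.
"""

from __future__ import annotations


def rk_fraction_bisect(ca: float, p) -> float:
    """Free-RK fraction via 80-step bisection of the recoverin quadratic."""
    if p.Rec_tot == 0.0 or ca == 0.0:
        return 1.0
    ca2 = (ca / p.K1) ** 2
    c1 = ca2 * (1.0 / p.K3 + p.M_rec / (p.K2 * p.K4)) * p.Rec_tot
    c2 = 1.0 + ca2 * (1.0 + p.M_rec / p.K2)

    def f(x: float) -> float:
        return c1 * c2 * x * x + (c1 * (p.RK_tot / p.Rec_tot - 1.0) + c2) * x - 1.0

    lo, hi = 0.0, 1.0
    assert f(lo) < 0 <= f(hi)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 1.0 / (1.0 + c1 * 0.5 * (lo + hi))
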