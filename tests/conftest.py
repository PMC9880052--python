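"""Shared fixtures: the wild-type parameter set and cached pipeline runs.

The expensive simulate→measure→fit pipelines (expression-series and
criterion-study protocols) are session-scoped so that unit, property and
acceptance tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import rodcascade as rc
from rodcascade.experiments import run_experiment
from rodcascade.pepperberg import curve_shape, fit_linear, pepperberg_curve
from rodcascade.presets import apply_preset


@pytest.fixture(scope="session")
def wt() -> rc.Params:
    return rc.default_params()


@pytest.fixture(scope="session")
def dark_wt(wt):
    return rc.dark_steady_state(wt)


@pytest.fixture(scope="session")
def fig3_result(wt):
    """RGS9 expression series, 10% criterion (slope-calibration protocol)."""
    return run_experiment("fig3_rgs9", wt)


@pytest.fixture(scope="session")
def fig2_result(wt):
    """WT criterion study: 2% and 20% recovery measured on the same flashes."""
    return run_experiment("fig2_criterion", wt)


@pytest.fixture(scope="session")
def fig5_shapes(wt):
    """Bend/plateau shape summaries for the PDE expression series."""
    res = run_experiment("fig5_pde", wt)
    out = {}
    for label, curve in res.curves.items():
        name = label.split("@")[0]
        fit = res.fits.get(label)
        out[name] = {
            "curve": curve,
            "fit": fit,
            "shape": res.shapes[label],
        }
    return out


@pytest.fixture(scope="session")
def fig6_result(wt):
    """Rhodopsin-kinase series (0.3x, WT, S561L), 10% criterion."""
    return run_experiment("fig6_rk", wt)


@pytest.fixture(scope="session")
def fig7_results(wt):
    """GCAP2 and full-GCAPs knockouts against WT."""
    return {
        "gcap2": run_experiment("fig7a_gcap2ko", wt),
        "gcaps": run_experiment("fig7b_gcapsko", wt),
    }


@pytest.fixture(scope="session")
def wt_bright_response(wt):
    """A deeply saturating WT flash (ln Phi = 8) integrated for 60 s."""
    return rc.simulate_flash(wt, float(np.exp(8.0)), 60.0)
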