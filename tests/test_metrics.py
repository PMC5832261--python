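"""Metric-layer checks on geometric oracles and surrogate trains."""

import numpy as np
import pandas as pd
import pytest

from restidyn.metrics import (CoverageError, SpaceOfStates, UnimodalityError,
                              der_slope, er_to_rd_beats, fit_monoexponential,
                              loop_width, major_axis_slope, shift,
                              space_of_states)


def _space_from_xy(x, y, direction=None, mode="vs_CL", meta=None):
    d = direction if direction is not None else np.zeros(len(x), int)
    return SpaceOfStates(mode=mode, points=pd.DataFrame(
        {"x_ms": x, "APD_ms": y, "direction": d}), meta=meta or {})


def test_lag1_pairing_and_bookkeeping_identity(surrogate_fixtures):
    """vs_CL and vs_DI spaces from one train satisfy
    x_DI = x_CL - APD_{n-1} pointwise."""
    train = surrogate_fixtures["random_memory"]
    sp_cl = space_of_states(train, "vs_CL")
    sp_di = space_of_states(train, "vs_DI")
    apd = train.apd
    assert sp_cl.x == pytest.approx(train.cl[:-1])
    assert sp_cl.apd == pytest.approx(apd[1:])
    assert sp_di.x == pytest.approx(sp_cl.x - apd[:-1])


def test_constant_train_collapses_to_a_point(surrogate_fixtures):
    train = surrogate_fixtures["constant"]
    for mode in ("vs_CL", "vs_DI"):
        sp = space_of_states(train, mode, discard=100)
        assert np.ptp(sp.x) < 0.5 and np.ptp(sp.apd) < 0.5
        assert shift(sp) == pytest.approx(0.0, abs=0.5)


def test_shift_on_synthetic_ellipse_matches_geometry():
    """The vertical chord of a rotated ellipse through its center has a
    closed form: the two boundary points with x = 0 sit at parameter
    tan(phi) = (a cos th)/(b sin th), so the width is 2|y(phi)|."""
    th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    a, b, rot = 30.0, 5.0, 0.5
    x = a * np.cos(th) * np.cos(rot) - b * np.sin(th) * np.sin(rot) + 350.0
    y = a * np.cos(th) * np.sin(rot) + b * np.sin(th) * np.cos(rot) + 230.0
    direction = np.sign(np.gradient(x))
    sp = _space_from_xy(x, y, direction, meta={"law": "periodic",
                                               "CL_star": 350.0})
    phi = np.arctan2(a * np.cos(rot), b * np.sin(rot))
    expected = 2 * abs(a * np.cos(phi) * np.sin(rot)
                       + b * np.sin(phi) * np.cos(rot))
    assert shift(sp, 350.0) == pytest.approx(expected, rel=0.05)
    # major axis slope of the same ellipse ~ tan(rot) for a >> b
    slope, degenerate = major_axis_slope(sp)
    assert not degenerate
    assert slope == pytest.approx(np.tan(rot), abs=0.03)


def test_shift_requires_coverage():
    sp = _space_from_xy([300.0, 301.0], [200.0, 201.0],
                        meta={"law": "random"})
    with pytest.raises(CoverageError):
        shift(sp, reference_x=390.0)


def test_slopes_on_exact_line():
    x = np.linspace(300, 400, 50)
    y = 0.5 * x + 40.0
    sp = _space_from_xy(x, y)
    ols, max_local = der_slope(sp)
    assert ols == pytest.approx(0.5, abs=1e-9)
    assert max_local == pytest.approx(0.5, abs=1e-9)
    slope, degenerate = major_axis_slope(sp)
    assert slope == pytest.approx(0.5, abs=1e-6)


def test_der_slope_rejects_loops():
    th = np.linspace(0, 2 * np.pi, 300, endpoint=False)
    x = 30 * np.cos(th) + 350
    y = 20 * np.sin(th) + 230
    sp = _space_from_xy(x, y, np.sign(np.gradient(x)))
    assert loop_width(sp) > 2.0
    with pytest.raises(UnimodalityError):
        der_slope(sp)


def test_monoexponential_recovery():
    x = np.linspace(0, 10, 50)
    y = 3.0 * np.exp(-x / 2.5) + 1.0
    a, tau, c, r2 = fit_monoexponential(x, y)
    assert (a, tau, c) == pytest.approx((3.0, 2.5, 1.0), rel=1e-6)
    assert r2 > 1 - 1e-12
    rng = np.random.default_rng(7)
    noisy = y + rng.normal(0, 0.01 * np.ptp(y), size=y.size)
    _, tau_n, _, _ = fit_monoexponential(x, noisy)
    assert tau_n == pytest.approx(2.5, rel=0.05)
    a0, _, c0, _ = fit_monoexponential(x, np.full_like(x, 5.0))
    assert abs(a0) < 1e-6 and c0 == pytest.approx(5.0, abs=1e-6)


def test_er_to_rd_step_relaxation(params, control_state):
    state0, _ = control_state
    assert er_to_rd_beats(params, 350.0, 350.0) == 0
    nb = er_to_rd_beats(params, 350.0, 370.0, tol=2.0, horizon=60,
                        cond_state=state0)
    assert 0 < nb < 30
    # infinite tolerance -> immediate recovery
    assert er_to_rd_beats(params, 350.0, 370.0, tol=np.inf, horizon=60,
                          cond_state=state0) == 0
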