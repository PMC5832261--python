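"""Perturbation-layer checks: alternans detection, Nb, CL-change stats."""

import numpy as np
import pytest

from restidyn import (constant_schedule, detect_alternans, drop_beat,
                      periodic_schedule, random_schedule, run_train)
from restidyn.stability import (NOT_RECOVERED, cl_change_statistics,
                                missing_beat_experiment)


def test_detect_alternans_on_constructed_series():
    steady = np.full(100, 230.0)
    res = detect_alternans(steady)
    assert not res["present"]
    alt = np.tile([200.0, 260.0], 50)
    res = detect_alternans(alt)
    assert res["present"] and res["sustained"]
    assert res["amplitude"] == pytest.approx(60.0)
    # decaying alternans: present but not sustained
    n = np.arange(120)
    decay = 230 + 40 * (-1.0) ** n * np.exp(-n / 15)
    res = detect_alternans(decay, min_run=40)
    assert res["present"] and not res["sustained"]
    with pytest.raises(ValueError):
        detect_alternans([230.0, 231.0])


def test_detect_alternans_fixture(surrogate_fixtures):
    train = surrogate_fixtures["alternans"]
    res = detect_alternans(train.apd[5:])
    assert res["present"] and res["sustained"]
    assert res["amplitude"] == pytest.approx(
        train.meta["injected_alternans_amp"], rel=0.05)


def test_missing_beat_prefix_equality_and_recovery(params, control_state):
    """Intact and perturbed runs agree exactly before the drop; control
    recovers afterwards."""
    state0, _ = control_state
    sched = constant_schedule(350.0, 70)
    res = missing_beat_experiment(params, sched, 10, follow=50,
                                  initial_state=state0)
    intact = run_train(params, sched, initial_state=state0)
    perturbed = run_train(params, drop_beat(sched, 10),
                          initial_state=state0)
    assert perturbed.apd[:9] == pytest.approx(intact.apd[:9])
    assert np.isnan(perturbed.apd[9])           # the withheld beat
    assert np.isfinite(res.nb) and 1 <= res.nb <= 15
    assert not res.alternans["sustained"]
    # dropping nothing recovers immediately
    res0 = missing_beat_experiment(params, sched, 10, follow=50,
                                   initial_state=state0,
                                   intact_train=intact)
    assert res0.delta_apd[5:] == pytest.approx(
        np.zeros(45), abs=1e-6) or res0.nb <= res.nb


def test_missing_beat_requires_room_for_follow_window(params):
    with pytest.raises(ValueError):
        missing_beat_experiment(params, constant_schedule(350.0, 30), 10,
                                follow=50)


def test_cl_change_statistics_constant_is_zero():
    with pytest.raises(ValueError):
        cl_change_statistics(constant_schedule(350, 1),
                             constant_schedule(350, 1))
    stats = cl_change_statistics(
        periodic_schedule(350.0, 0.0, 2.4, 500),
        random_schedule(350.0, 0.0, 500, 3),
        thresholds=[0.0, 10.0])
    assert stats.table["A_p"].to_numpy() == pytest.approx([0.0, 0.0])


def test_cl_change_statistics_match_analytic_distributions():
    """Periodic |dCL| follows |clv*(sin(wN) - sin(w(N-1)))|; random |dCL|
    follows the triangular difference of two uniforms."""
    clv, omega, n = 35.0, 2.4, 40_000
    per = periodic_schedule(350.0, clv, omega, n)
    rnd = random_schedule(350.0, clv, n, seed=11)
    thresholds = np.array([10.0, 30.0, 50.0])
    stats = cl_change_statistics(per, rnd, thresholds)
    # analytic periodic exceedance over a dense phase grid
    nn = np.arange(2, 200_002)
    dper = np.abs(clv * (np.sin(omega * nn) - np.sin(omega * (nn - 1))))
    expect_p = [np.mean(dper > th) for th in thresholds]
    assert stats.table["A_p"].to_numpy() == pytest.approx(expect_p, abs=0.01)
    # difference of two U(-clv, clv): P(|D| > t) = (1 - t/(2 clv))^2
    expect_r = [(1 - th / (2 * clv)) ** 2 for th in thresholds]
    assert stats.table["A_r"].to_numpy() == pytest.approx(expect_r, abs=0.02)
    # monotone non-increasing exceedance
    assert np.all(np.diff(stats.table["A_p"]) <= 1e-12)
    assert np.all(np.diff(stats.table["A_r"]) <= 1e-12)


def test_cl_change_statistics_requires_matching_parameters():
    with pytest.raises(ValueError):
        cl_change_statistics(periodic_schedule(350.0, 35.0, 2.4, 100),
                             random_schedule(300.0, 35.0, 100, 1))
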