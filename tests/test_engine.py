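"""Beat-engine contracts: APD detection, snapshots, restitution protocols."""

import numpy as np
import pytest

from restidyn import (ModelParams, classic_er, condition, constant_schedule,
                      measure_apd, rd_curve, restore_and_stimulate,
                      run_train, snapshot)
from restidyn.engine import dynamic_er_family
from restidyn.pacing import periodic_schedule


def test_measure_apd_on_synthetic_ramp_trace():
    """Instant rise at t=10 to +40 mV, linear fall to -80 mV at t=310:
    -60 mV is 100 of the 120 mV drop, so the crossing is at
    t = 10 + 300 * (100/120) = 260 and APD = 250 ms."""
    t = np.array([0.0, 9.9, 10.0, 10.1] + list(np.arange(11.0, 320.0)))
    v = np.full_like(t, -80.0)
    v[t < 10.0] = -80.0
    rise = t >= 10.0
    v[rise] = 40.0 - (40.0 - (-80.0)) * (t[rise] - 10.0) / 300.0
    v[t < 10] = -80.0
    t_up, apd = measure_apd((t, v), stim_time=5.0)
    assert t_up == pytest.approx(10.0, abs=0.5)
    assert apd == pytest.approx(250.0, abs=1.0)


def test_measure_apd_subthreshold_returns_sentinel():
    t = np.arange(0.0, 100.0)
    v = -80.0 + 20.0 * np.exp(-((t - 10) / 5.0) ** 2)   # peaks at -60
    t_up, apd = measure_apd((t, v), stim_time=5.0)
    assert np.isnan(t_up) and np.isnan(apd)


def test_monotone_repolarization_has_single_crossing(params, control_state):
    state0, _ = control_state
    train = run_train(params, constant_schedule(350.0, 1),
                      initial_state=state0, record_traces=True,
                      trace_dt=0.2)
    v = train.traces["Vm_mV"].to_numpy()
    t = train.traces["t_ms"].to_numpy()
    after_peak = t > t[np.argmax(v)]
    crossings = np.sum((v[after_peak][:-1] > -60) & (v[after_peak][1:] <= -60))
    assert crossings == 1
    # offline and in-line APD measurements agree
    t_up, apd = measure_apd(train.traces, stim_time=0.0)
    assert apd == pytest.approx(train.apd[0], abs=0.5)


def test_steady_state_convergence_and_di_bookkeeping(control_train):
    tail = control_train.apd[-20:]
    assert np.std(tail) < 0.5
    ok = control_train.captured
    assert np.all(control_train.di[ok] == pytest.approx(
        control_train.cl[ok] - control_train.apd[ok]))


def test_snapshot_restore_determinism(params, control_state):
    """Restoring the end-of-cycle state replays the same APD (< 0.1 ms)."""
    state0, apd_cond = control_state
    apd1 = restore_and_stimulate(state0.copy(), 350.0, params)
    apd2 = restore_and_stimulate(state0.copy(), 350.0, params)
    assert apd1 == apd2           # bitwise-deterministic kernel
    assert apd1 == pytest.approx(apd_cond, abs=0.1)
    # restores never mutate the snapshot
    keep = state0.copy()
    restore_and_stimulate(state0, 330.0, params)
    assert np.array_equal(state0, keep)


def test_restitution_brackets_reference_apd(params, control_state):
    """Test beats at CL* +- 20 ms bracket the steady APD (monotone ER)."""
    state0, apd_cond = control_state
    lo = restore_and_stimulate(state0, 330.0, params)
    mid = restore_and_stimulate(state0, 350.0, params)
    hi = restore_and_stimulate(state0, 370.0, params)
    assert lo < mid < hi
    assert mid == pytest.approx(apd_cond, abs=0.5)


def test_rd_curve_monotone_and_plateauing(params):
    """Steady APD is non-decreasing in CL and saturates at long CL."""
    curve = rd_curve(params, cl_min=320.0, cl_max=1400.0, step=120.0,
                     n_cond=150, n_avg=10)
    assert np.all(curve.points["captured"])
    apd = curve.apd
    assert np.all(np.diff(apd) > -0.5)
    # plateau: the last 120-ms step changes APD by < 3 ms
    assert abs(apd[-1] - apd[-2]) < 3.0


def test_classic_er_conditioning_point_is_steady_state(
        params, control_state):
    state0, apd_cond = control_state
    er_cl, er_di = classic_er(params, 350.0, test_range=20.0, step=10.0,
                              cond_state=(state0, apd_cond))
    at_cond = er_cl.points.loc[er_cl.points["x_ms"] == 350.0, "APD_ms"]
    assert float(at_cond.iloc[0]) == pytest.approx(apd_cond, abs=1.0)
    # the two curves come from one sweep: x_DI = x_CL - APD_cond
    assert er_di.x == pytest.approx(er_cl.x - apd_cond)
    assert er_di.apd == pytest.approx(er_cl.apd)
    # restitution is increasing around the conditioning point
    assert 0.0 < er_cl.slope_at(350.0) < 1.5


def test_dynamic_er_family_degenerates_under_constant_pacing(
        params, control_state):
    state0, _ = control_state
    fam = dynamic_er_family(params, constant_schedule(350.0, 20),
                            test_range=20.0, step=20.0, stride=10,
                            initial_state=state0)
    assert len(fam) == 2
    apd_at_350 = [
        float(er_cl.points.loc[er_cl.points["x_ms"] == 350.0, "APD_ms"].iloc[0])
        for _, er_cl, _ in fam]
    assert np.ptp(apd_at_350) < 1.0


def test_train_csv_roundtrip(tmp_path, control_train):
    path = tmp_path / "train.csv"
    control_train.to_csv(path)
    import pandas as pd
    back = pd.read_csv(path)
    assert len(back) == control_train.n_beats
    assert back["APD_ms"].iloc[-1] == pytest.approx(
        control_train.apd[-1])
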