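"""Cell-model level checks: fixed point, invariants, thresholds, scaling.

The equation set is validated two ways: against an independent stiff-solver
integration of the same right-hand side (consistency of the fast fixed-step
scheme), and against published emergent behaviour of the epicardial TP06
myocyte (resting potential, 1 Hz APD, upstroke velocity).
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from restidyn import (INITIAL_STATE, ModelParams, condition, derivatives,
                      find_threshold, run_train, scale_conductances,
                      constant_schedule)
from restidyn.engine import stimulus_for
from restidyn.tp06 import (InvalidStateError, elicits_ap, resting_state,
                           validate_state)


def test_quiescent_model_relaxes_to_fixed_point(params):
    """Without stimulation the model settles and derivatives vanish."""
    rest = resting_state(params, quiescence_ms=10_000.0)
    dy = derivatives(rest, 0.0, params)
    # V and gates equilibrate tightly; the Ca/Na/K pools keep a slow
    # residual drift (SR refilling), so their bound is scale-relative
    assert abs(dy[0]) < 1e-4                      # mV/ms
    assert np.all(np.abs(dy[1:14]) < 5e-6)        # 1/ms
    assert np.all(np.abs(dy[14:]) / rest[14:] < 2e-4)
    assert rest[0] == pytest.approx(-86.2, abs=1.0)   # published resting V_m


def test_trajectory_respects_state_invariants(params):
    """Gates stay in [0,1] and concentrations positive while pacing."""
    train = run_train(params, constant_schedule(400.0, 5),
                      record_traces=True)
    validate_state(train.final_state)   # raises on violation
    assert np.all(train.traces["Ca_i"] > 0)


def test_one_hz_ap_matches_published_epicardial_behaviour(params):
    """APD and upstroke velocity at CL 1000 ms in the published range."""
    train = run_train(params, constant_schedule(1000.0, 5))
    # epicardial TP06 APD ~301 ms at 1 Hz (to -60 mV here, a near-90%
    # repolarization level for this morphology)
    assert train.apd[-1] == pytest.approx(301.0, abs=8.0)
    assert 250.0 < train.beats["dvdt_max"].iloc[-1] < 400.0
    assert np.all(train.captured)


def test_fixed_step_scheme_agrees_with_stiff_solver(params, control_state):
    """Integrating the same RHS with scipy BDF reproduces the AP waveform."""
    state0, _ = control_state
    stim = stimulus_for(params)

    def rhs(t, y):
        i = -stim.amplitude if t < stim.duration else 0.0
        return derivatives(y, t, params, i_stim=i)

    sol = solve_ivp(rhs, (0.0, 300.0), state0, method="BDF",
                    rtol=1e-6, atol=1e-9, max_step=1.0,
                    t_eval=np.arange(0.0, 300.0, 1.0))
    assert sol.success
    train = run_train(params, constant_schedule(350.0, 1),
                      initial_state=state0, record_traces=True,
                      trace_dt=1.0)
    v_fast = np.interp(sol.t, train.traces["t_ms"], train.traces["Vm_mV"])
    # compare away from the upstroke, where any sub-ms timing offset
    # dominates pointwise differences
    mask = (sol.t > 10.0)
    assert np.max(np.abs(v_fast[mask] - sol.y[0][mask])) < 2.0


def test_threshold_bisection_matches_brute_force_scan(params):
    th = find_threshold(INITIAL_STATE, params)
    # brute-force fine scan oracle
    amps = np.arange(0.5, 30.0, 0.25)
    fired = [elicits_ap(INITIAL_STATE, params, float(a)) for a in amps]
    first = amps[int(np.argmax(fired))]
    assert th == pytest.approx(first, abs=max(0.25, 0.01 * th) + 0.01 * th)
    assert elicits_ap(INITIAL_STATE, params, 2.0 * th)
    assert not elicits_ap(INITIAL_STATE, params, 0.5 * th)


def test_conductance_scaling_identity_composition_and_errors(params):
    assert scale_conductances(params, {"I_Kr": 1.0}).as_array() == pytest.approx(
        params.as_array())
    a = scale_conductances(scale_conductances(params, {"I_Ks": 0.5}),
                           {"I_Ks": 0.8})
    b = scale_conductances(params, {"I_Ks": 0.4})
    assert a["g_Ks"] == pytest.approx(b["g_Ks"])
    with pytest.raises(KeyError):
        scale_conductances(params, {"I_bogus": 2.0})
    with pytest.raises(ValueError):
        scale_conductances(params, {"I_Kr": -1.0})


def test_invalid_states_are_rejected(params):
    bad = INITIAL_STATE.copy()
    bad[0] = np.nan
    with pytest.raises(InvalidStateError):
        derivatives(bad, 0.0, params)
    short = INITIAL_STATE[:-1]
    with pytest.raises(InvalidStateError):
        validate_state(short)
    neg = INITIAL_STATE.copy()
    neg[14] = -1e-4
    with pytest.raises(InvalidStateError):
        validate_state(neg)


def test_state_json_roundtrip(params):
    from restidyn.tp06 import state_from_json, state_to_json
    s = state_from_json(state_to_json(INITIAL_STATE))
    assert s == pytest.approx(INITIAL_STATE)
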