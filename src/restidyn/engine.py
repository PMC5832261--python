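"""Beat-by-beat driver: pacing trains, APD detection, restitution protocols.

Conventions
-----------
Beat ``n`` (1-based) is stimulated at t(n-1) = sum of the preceding cycle
lengths, so the first stimulus fires at t = 0 -- the natural convention for
runs launched from a snapshot taken at the end of a conditioning cycle
(the saved state is the instant the next stimulus is due).  ``CL_n`` is the
cycle *initiated* by beat n (the interval from its stimulus to the next),
``APD_n`` is measured from the upstroke (max dV/dt) to the downward -60 mV
crossing, and ``DI_n = CL_n - APD_n`` is the diastole closing cycle n.
With this bookkeeping the interval immediately preceding beat n is
``CL_{n-1}``, which is what restitution pairs APD_n against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .pacing import PacingSchedule, constant_schedule
from .tp06 import (INITIAL_STATE, ModelParams, StimulusSpec, find_threshold,
                   pack_clamps, validate_state)

#: default integration step (ms); the operator-split scheme is stable and
#: converged for the TP06 stiffness at this step
DT_DEFAULT = 0.02

#: default trace sampling interval (ms)
TRACE_DT = 0.5


class IntegrationError(RuntimeError):
    pass


class EmptyTrainError(ValueError):
    pass


_threshold_cache: dict = {}


def stimulus_for(params: ModelParams, spec: StimulusSpec | None = None,
                 dt: float = DT_DEFAULT) -> StimulusSpec:
    """Resolve the stimulus amplitude (1.5x threshold) for a parameter set.

    The capture threshold is found by bisection from the model's reference
    near-resting state and cached per parameter set.
    """
    spec = spec or StimulusSpec()
    if spec.threshold_amplitude is not None:
        return spec
    key = (params.as_array().tobytes(), spec.duration, dt)
    if key not in _threshold_cache:
        _threshold_cache[key] = find_threshold(
            INITIAL_STATE, params, duration=spec.duration, dt=dt)
    return StimulusSpec(duration=spec.duration,
                        amplitude_factor=spec.amplitude_factor,
                        threshold_amplitude=_threshold_cache[key])


@dataclass
class APTrain:
    """Per-beat records of a simulated pacing train.

    ``beats`` columns: index, CL_ms, t_stim_ms, stim_enabled, captured,
    upstroke_ms, APD_ms, DI_ms, dvdt_max.  APD is NaN for non-captured or
    still-depolarized (merged) beats.  ``final_state`` is the full 19-value
    state at the end of the last cycle -- the snapshot used to continue or
    branch the simulation.
    """

    beats: pd.DataFrame
    final_state: np.ndarray
    traces: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def apd(self) -> np.ndarray:
        return self.beats["APD_ms"].to_numpy()

    @property
    def cl(self) -> np.ndarray:
        return self.beats["CL_ms"].to_numpy()

    @property
    def di(self) -> np.ndarray:
        return self.beats["DI_ms"].to_numpy()

    @property
    def captured(self) -> np.ndarray:
        return self.beats["captured"].to_numpy().astype(bool)

    @property
    def n_beats(self) -> int:
        return len(self.beats)

    def to_csv(self, path) -> None:
        self.beats.to_csv(path, index=False)

    def tail_apd(self, n: int) -> np.ndarray:
        return self.apd[-n:]


def snapshot(train: APTrain) -> np.ndarray:
    """State vector at the end of the train's last cycle (copy)."""
    return train.final_state.copy()


def run_train(params: ModelParams, schedule: PacingSchedule, clamps=(),
              initial_state=None, record_traces: bool = False,
              dt: float = DT_DEFAULT, stimulus: StimulusSpec | None = None,
              trace_dt: float = TRACE_DT) -> APTrain:
    """Integrate the model through a pacing schedule.

    Returns an :class:`APTrain`; a non-captured enabled beat is recorded,
    not raised (capture failure is data near alternans/block).
    """
    y = (INITIAL_STATE.copy() if initial_state is None
         else validate_state(initial_state).copy())
    stim = stimulus_for(params, stimulus, dt)
    flags, coefs, ncoef, vlo, vhi, blank = pack_clamps(clamps)

    cl = schedule.cl
    enabled = schedule.stim_enabled.astype(np.int64)

    if record_traces:
        stride = max(1, int(round(trace_dt / dt)))
        cap = int(np.sum(np.round(cl / dt)) // stride) + cl.size + 2
        rec_t = np.empty(cap)
        rec_v = np.empty(cap)
        rec_i = np.empty((3, cap))
        rec_cai = np.empty(cap)
    else:
        stride = 0
        rec_t = np.empty(0)
        rec_v = np.empty(0)
        rec_i = np.empty((3, 0))
        rec_cai = np.empty(0)

    captured, t_up, apd, dvdt_max, t_stim, nrec = _kernel.run_schedule(
        y, params.as_array(), cl, enabled, stim.amplitude, stim.duration,
        dt, flags, coefs, ncoef, vlo, vhi, blank,
        stride, rec_t, rec_v, rec_i, rec_cai)

    if not np.all(np.isfinite(y)):
        raise IntegrationError("non-finite state at end of schedule; "
                               "the integration diverged")

    di = np.where(np.isfinite(apd), cl - apd, np.nan)
    beats = pd.DataFrame({
        "index": np.arange(1, cl.size + 1),
        "CL_ms": cl,
        "t_stim_ms": t_stim,
        "stim_enabled": enabled.astype(bool),
        "captured": captured.astype(bool),
        "upstroke_ms": t_up,
        "APD_ms": apd,
        "DI_ms": di,
        "dvdt_max": dvdt_max,
    })
    traces = None
    if record_traces:
        traces = pd.DataFrame({
            "t_ms": rec_t[:nrec], "Vm_mV": rec_v[:nrec],
            "I_CaL": rec_i[0, :nrec], "I_Kr": rec_i[1, :nrec],
            "I_Ks": rec_i[2, :nrec], "Ca_i": rec_cai[:nrec],
        })
    meta = {"schedule": dict(schedule.meta), "dt": dt,
            "stim_amplitude": stim.amplitude,
            "stim_duration": stim.duration,
            "n_clamps": len(tuple(clamps))}
    return APTrain(beats=beats, final_state=y, traces=traces, meta=meta)


def measure_apd(trace, stim_time: float, window: float = 20.0):
    """Upstroke time and APD_-60mV from a sampled (t, V_m) trace.

    ``trace`` is anything with columns/keys ``t_ms`` and ``Vm_mV`` (or a
    (t, v) tuple).  The upstroke is the quadratically refined argmax of the
    finite-difference dV/dt within ``window`` ms of ``stim_time``; APD is
    the linearly interpolated downward -60 mV crossing minus the upstroke
    time.  Returns (nan, nan) on capture failure and (t_up, nan) if V never
    falls back to -60 mV (merged beat).
    """
    if isinstance(trace, tuple):
        t, v = np.asarray(trace[0], float), np.asarray(trace[1], float)
    else:
        t, v = (np.asarray(trace["t_ms"], float),
                np.asarray(trace["Vm_mV"], float))
    sel = (t >= stim_time) & (t <= stim_time + window)
    if sel.sum() < 3:
        return np.nan, np.nan
    iw = np.flatnonzero(sel)
    if v[iw].max() <= 0.0:            # sub-threshold deflection
        return np.nan, np.nan
    dv = np.gradient(v[iw], t[iw])
    k = int(np.argmax(dv))
    t_up = t[iw[k]]
    if 0 < k < len(dv) - 1:
        den = dv[k - 1] - 2 * dv[k] + dv[k + 1]
        if den < 0:
            step = 0.5 * (t[iw[k + 1]] - t[iw[k - 1]]) / 2
            delta = step * (dv[k - 1] - dv[k + 1]) / den
            if abs(delta) < (t[iw[k + 1]] - t[iw[k - 1]]):
                t_up = t[iw[k]] + delta
    after = np.flatnonzero((t > t_up) & (v > 0))
    if after.size == 0:
        return t_up, np.nan
    below = np.flatnonzero((t > t[after[0]]) & (v <= -60.0))
    if below.size == 0:
        return t_up, np.nan               # merged beat
    i1 = below[0]
    i0 = i1 - 1
    frac = (v[i0] + 60.0) / (v[i0] - v[i1])
    t_cross = t[i0] + frac * (t[i1] - t[i0])
    return t_up, t_cross - t_up


def restore_and_stimulate(state, test_cl: float, params: ModelParams,
                          clamps=(), dt: float = DT_DEFAULT,
                          stimulus: StimulusSpec | None = None) -> float:
    """APD of a test beat delivered ``test_cl`` ms after a restored snapshot.

    The snapshot is the state at a cycle end, so the launch stimulus fires
    immediately (the last conditioning beat) and the test beat follows one
    cycle of length ``test_cl``; its APD is returned.  Replaying the
    conditioning CL reproduces the steady APD to solver tolerance.
    """
    sched = PacingSchedule(np.array([float(test_cl), test_cl + 150.0]),
                           np.ones(2, dtype=bool), {"law": "restore-test"})
    train = run_train(params, sched, clamps=clamps, initial_state=state,
                      dt=dt, stimulus=stimulus)
    return float(train.apd[1])


@dataclass
class RestitutionCurve:
    """(x, APD) pairs with mode tag ``vs_CL`` or ``vs_DI``."""

    mode: str
    points: pd.DataFrame        # columns x_ms, APD_ms, captured
    conditioning: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return self.points["x_ms"].to_numpy()

    @property
    def apd(self) -> np.ndarray:
        return self.points["APD_ms"].to_numpy()

    def slope_at(self, x0: float) -> float:
        """Local slope dAPD/dx at x0 (central difference on the grid)."""
        ok = self.points["captured"].to_numpy().astype(bool)
        x, y = self.x[ok], self.apd[ok]
        if x.size < 3:
            raise ValueError("too few captured points for a local slope")
        order = np.argsort(x)
        x, y = x[order], y[order]
        g = np.gradient(y, x)
        return float(np.interp(x0, x, g))

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df["mode"] = self.mode
        df.to_csv(path, index=False)


def _curve(mode, xs, apds, captured, conditioning):
    df = pd.DataFrame({"x_ms": xs, "APD_ms": apds, "captured": captured})
    df = df.sort_values("x_ms", ignore_index=True)
    return RestitutionCurve(mode=mode, points=df, conditioning=conditioning)


def condition(params: ModelParams, cl: float, n_cond: int, clamps=(),
              initial_state=None, dt: float = DT_DEFAULT) -> APTrain:
    """Constant-CL conditioning train (returns the full APTrain)."""
    return run_train(params, constant_schedule(cl, n_cond), clamps=clamps,
                     initial_state=initial_state, dt=dt)


def rd_curve(params: ModelParams, cl_min: float = 300.0,
             cl_max: float = 1400.0, step: float = 20.0, n_cond: int = 300,
             n_avg: int = 20, dt: float = DT_DEFAULT,
             initial_state=None) -> RestitutionCurve:
    """Rate-dependence curve: steady APD versus constant pacing CL.

    Per CL the model is conditioned for ``n_cond`` beats and APD averaged
    over the last ``n_avg``.  A CL where 1:1 capture fails in the averaging
    window is flagged (captured=False), never dropped.
    """
    cls = np.arange(cl_min, cl_max + 0.5 * step, step)
    apds, flags = [], []
    for cl in cls:
        train = condition(params, float(cl), n_cond, initial_state=initial_state,
                          dt=dt)
        tail = train.apd[-n_avg:]
        ok = bool(np.all(np.isfinite(tail)) and
                  np.all(train.captured[-n_avg:]))
        apds.append(np.nanmean(tail) if np.any(np.isfinite(tail)) else np.nan)
        flags.append(ok)
    return _curve("vs_CL", cls, apds, flags,
                  {"protocol": "RD", "n_cond": n_cond, "n_avg": n_avg})


def classic_er(params: ModelParams, cl_star: float, test_range: float = 20.0,
               step: float = 5.0, n_cond: int = 300, clamps=(),
               dt: float = DT_DEFAULT, initial_state=None,
               cond_state=None):
    """Classic (S1-S2 style) restitution from a fixed conditioned state.

    Conditions at CL* (or reuses ``cond_state``), snapshots the state just
    before the last conditioning beat, then for every test CL in
    [CL* - range, CL* + range] restores the snapshot, lets the last
    conditioning cycle run with length ``test CL`` and measures the APD of
    the following (test) beat.  Returns (ER_CL, ER_DI) curves built from
    the same sweep: APD_test vs test CL, and vs DI = test CL - APD_cond.
    """
    if cond_state is None:
        cond = condition(params, cl_star, n_cond, clamps=clamps,
                         initial_state=initial_state, dt=dt)
        state0 = snapshot(cond)
        apd_cond = float(cond.apd[-1])
    else:
        state0, apd_cond = cond_state
    test_cls = np.arange(cl_star - test_range, cl_star + test_range + 0.5 * step,
                         step)
    xs_cl, xs_di, apds, flags = [], [], [], []
    measure_cl = cl_star + test_range + 50.0
    for tcl in test_cls:
        sched = PacingSchedule(np.array([tcl, measure_cl]),
                               np.ones(2, dtype=bool),
                               {"law": "er-test", "CL_star": cl_star})
        tr = run_train(params, sched, clamps=clamps, initial_state=state0,
                       dt=dt)
        xs_cl.append(tcl)
        xs_di.append(tcl - apd_cond)
        apds.append(tr.apd[1])
        flags.append(bool(tr.captured[1] and np.isfinite(tr.apd[1])))
    conditioning = {"protocol": "classic_ER", "CL_star": cl_star,
                    "APD_cond": apd_cond, "n_cond": n_cond,
                    "test_range": test_range}
    return (_curve("vs_CL", xs_cl, apds, flags, conditioning),
            _curve("vs_DI", xs_di, apds, flags, conditioning))


def dynamic_er_family(params: ModelParams, schedule: PacingSchedule,
                      test_range: float = 35.0, step: float = 17.5,
                      stride: int = 10, clamps=(), initial_state=None,
                      dt: float = DT_DEFAULT):
    """Classic-ER sweeps launched every ``stride``-th beat of a dynamic train.

    Returns a list of (beat_index, ER_CL, ER_DI); the vertical spread of the
    family at CL* is the hysteresis shift of the space of states.
    """
    y = (INITIAL_STATE.copy() if initial_state is None
         else validate_state(initial_state).copy())
    cl_star = schedule.meta.get("CL_star", float(np.mean(schedule.cl)))
    out = []
    apd_last = np.nan
    for start in range(0, schedule.n_beats, stride):
        chunk = PacingSchedule(schedule.cl[start:start + stride],
                               schedule.stim_enabled[start:start + stride],
                               dict(schedule.meta))
        tr = run_train(params, chunk, clamps=clamps, initial_state=y, dt=dt)
        y = tr.final_state
        finite = tr.apd[np.isfinite(tr.apd)]
        apd_last = float(finite[-1]) if finite.size else apd_last
        if np.isfinite(apd_last):
            er_cl, er_di = classic_er(
                params, cl_star, test_range=test_range, step=step,
                clamps=clamps, dt=dt, cond_state=(y.copy(), apd_last))
            out.append((start + stride, er_cl, er_di))
    return out
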