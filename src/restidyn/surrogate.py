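"""Fast beat-to-beat map surrogate with restitution and short-term memory.

A two-variable iterated map stands in for the ionic model when testing the
metric and stability layers: APD follows an exponential restitution of the
preceding diastolic interval, minus a slowly accumulating memory term,

    APD_{n+1} = APD_max - a * exp(-DI_n / tau_r) - gamma * M_n + eps_n
    M_{n+1}   = M_n * exp(-CL_n / tau_m)
                + (1 - exp(-CL_n / tau_m)) * APD_n / APD_max

With ``gamma = 0`` the map is memoryless: APD is a pure function of the
preceding DI, so the (DI, APD) space of states is a single curve and no
CL-hysteresis can develop.  With ``gamma > 0`` the memory integrates recent
activation history and fast periodic pacing opens a loop in (CL, APD) --
the structural phenomenon the metric layer quantifies.  The surrogate is a
test fixture, not a calibrated model of any myocyte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import APTrain
from .pacing import (PacingSchedule, alternating_schedule, constant_schedule,
                     periodic_schedule, random_schedule)


class InvalidFixtureError(ValueError):
    pass


@dataclass(frozen=True)
class SurrogateParams:
    """Map coefficients (ms except the dimensionless memory gain scale)."""

    apd_max: float = 270.0   # asymptotic APD, ms
    a: float = 150.0         # restitution depth, ms
    tau_r: float = 60.0      # restitution time constant, ms
    gamma: float = 0.0       # memory gain, ms (0 = memoryless)
    tau_m: float = 3000.0    # memory decay constant, ms
    noise_sd: float = 0.0    # additive APD noise, ms

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_m <= 0:
            raise InvalidFixtureError("time constants must be positive")
        if self.gamma < 0 or self.noise_sd < 0:
            raise InvalidFixtureError("gamma and noise_sd must be >= 0")


def memoryless_fixed_point(params: SurrogateParams, cl: float,
                           tol: float = 1e-10) -> float:
    """Fixed point of the gamma = 0 map at constant CL, by bisection on
    APD = APD_max - a * exp(-(CL - APD) / tau_r)."""
    def g(apd):
        return params.apd_max - params.a * np.exp(-(cl - apd) / params.tau_r) - apd

    lo, hi = 1.0, min(params.apd_max, cl - 1e-6)
    if g(lo) < 0 or g(hi) > 0:
        raise InvalidFixtureError("no 1:1 fixed point bracketed at this CL")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def surrogate_train(params: SurrogateParams, schedule: PacingSchedule,
                    seed: int | None = 0, apd0: float | None = None,
                    m0: float = 0.0) -> APTrain:
    """Iterate the map through a pacing schedule; returns an APTrain.

    Beats whose diastolic interval would be non-positive are flagged as
    capture failures (APD = NaN) and the memory variable coasts.  The beat
    records use the same conventions as the ODE engine, so every metric
    code path is shared.
    """
    rng = np.random.default_rng(seed)
    cl = schedule.cl
    enabled = schedule.stim_enabled
    n = cl.size
    apd = np.full(n, np.nan)
    mem = np.zeros(n + 1)
    mem[0] = m0
    apd_prev = params.apd_max - params.a if apd0 is None else apd0
    captured = np.zeros(n, dtype=bool)
    di_prev = None
    for k in range(n):
        if not enabled[k]:
            mem[k + 1] = mem[k] * np.exp(-cl[k] / params.tau_m)
            di_prev = None if di_prev is None else di_prev + cl[k]
            continue
        if k == 0 or di_prev is None:
            val = apd_prev
        else:
            eps = rng.normal(0.0, params.noise_sd) if params.noise_sd else 0.0
            val = (params.apd_max - params.a * np.exp(-di_prev / params.tau_r)
                   - params.gamma * mem[k] + eps)
        if val <= 0:
            raise InvalidFixtureError(
                "surrogate produced non-positive APD; adjust parameters")
        di = cl[k] - val
        if di <= 0:
            captured[k] = False
            mem[k + 1] = mem[k] * np.exp(-cl[k] / params.tau_m)
            di_prev = None
            continue
        apd[k] = val
        captured[k] = True
        decay = np.exp(-cl[k] / params.tau_m)
        mem[k + 1] = mem[k] * decay + (1 - decay) * val / params.apd_max
        apd_prev = val
        di_prev = di
    di_arr = np.where(np.isfinite(apd), cl - apd, np.nan)
    t_stim = np.concatenate([[0.0], np.cumsum(cl)[:-1]])
    beats = pd.DataFrame({
        "index": np.arange(1, n + 1),
        "CL_ms": cl,
        "t_stim_ms": t_stim,
        "stim_enabled": enabled,
        "captured": captured,
        "upstroke_ms": t_stim,
        "APD_ms": apd,
        "DI_ms": di_arr,
        "dvdt_max": np.zeros(n),
    })
    meta = {"schedule": dict(schedule.meta), "surrogate": True,
            "params": params.__dict__ if hasattr(params, "__dict__")
            else {f: getattr(params, f) for f in params.__dataclass_fields__}}
    return APTrain(beats=beats, final_state=np.zeros(19), meta=meta)


def fixture_suite(n_beats: int = 400, cl_star: float = 350.0,
                  clv: float = 35.0, seed: int = 1234) -> dict:
    """Deterministic canned trains for exercising the metric layer.

    Keys: ``constant``, ``periodic_fast`` / ``periodic_slow`` (omega 2.4 /
    0.1), ``random``, ``alternating``, each in memoryless and ``*_memory``
    variants, plus an ``alternans`` train with an injected period-2
    oscillation of known amplitude.
    """
    p0 = SurrogateParams()
    pm = SurrogateParams(gamma=60.0, tau_m=2000.0)
    scheds = {
        "constant": constant_schedule(cl_star, n_beats),
        "periodic_fast": periodic_schedule(cl_star, clv, 2.4, n_beats),
        "periodic_slow": periodic_schedule(cl_star, clv, 0.1, n_beats),
        "random": random_schedule(cl_star, clv, n_beats, seed),
        "alternating": alternating_schedule(cl_star, clv, n_beats),
    }
    out = {}
    for name, sched in scheds.items():
        out[name] = surrogate_train(p0, sched, seed=seed)
        out[name + "_memory"] = surrogate_train(pm, sched, seed=seed)
    alt = surrogate_train(p0, scheds["constant"], seed=seed)
    amp = 30.0
    signs = np.where(np.arange(alt.n_beats) % 2 == 0, 0.5, -0.5)
    alt.beats["APD_ms"] = alt.beats["APD_ms"] + amp * signs
    alt.beats["DI_ms"] = alt.beats["CL_ms"] - alt.beats["APD_ms"]
    alt.meta["injected_alternans_amp"] = amp
    out["alternans"] = alt
    return out
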