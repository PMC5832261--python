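"""Perturbation experiments: missing beats, alternans, protocol switches.

The central assay perturbs a pacing train by withholding a single stimulus
(the pacing clock keeps running) and counts the beats Nb until the APD
sequence rejoins the unperturbed reference within a tolerance.  Sustained
APD alternans (period-2 repolarization) triggered by the missing beat is
the instability endpoint; switching from constant to dynamic pacing can
quench it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_train
from .pacing import PacingSchedule, abs_cl_changes, constant_schedule, drop_beat

#: sentinel Nb when the perturbed train never rejoins (e.g. sustained
#: alternans)
NOT_RECOVERED = math.inf


@dataclass
class PerturbationResult:
    nb: float                     # beats to recovery (NOT_RECOVERED if never)
    delta_apd: np.ndarray         # per-beat APD difference after the drop
    alternans: dict               # {present, amplitude, sustained, ...}
    drop_index: int
    meta: dict = field(default_factory=dict)


def detect_alternans(apd_series, amp_tol: float = 2.0, min_run: int = 40):
    """Detect beat-to-beat APD alternation.

    A qualifying run is a maximal stretch of consecutive APD differences
    that alternate in sign and each exceed ``amp_tol`` in magnitude.
    ``present`` requires the longest run to span at least ``min_run``
    beats; ``sustained`` additionally requires it to reach the end of the
    series.  ``amplitude`` is the mean |difference| over that run.
    """
    a = np.asarray(apd_series, float)
    a = a[np.isfinite(a)]
    if a.size < 3:
        raise ValueError("need at least 3 finite APDs")
    d = np.diff(a)
    qual = np.abs(d) > amp_tol
    runs = []           # (start, length in diffs)
    start = None
    for k in range(len(d)):
        if start is None:
            if qual[k]:
                start = k
        else:
            if not (qual[k] and d[k] * d[k - 1] < 0):
                runs.append((start, k - start))
                start = k if qual[k] else None
    if start is not None:
        runs.append((start, len(d) - start))
    if not runs:
        return {"present": False, "amplitude": 0.0, "sustained": False,
                "run_start": -1, "run_beats": 0}
    start, length = max(runs, key=lambda r: r[1])
    run_beats = length + 1
    amplitude = float(np.mean(np.abs(d[start:start + length])))
    present = run_beats >= min_run
    sustained = present and (start + length == len(d))
    return {"present": bool(present), "amplitude": amplitude,
            "sustained": bool(sustained), "run_start": int(start),
            "run_beats": int(run_beats)}


def missing_beat_experiment(params, schedule: PacingSchedule,
                            drop_index: int, tol: float = 2.0,
                            follow: int = 50, sustain: int = 10,
                            initial_state=None, clamps=(),
                            dt: float = 0.02,
                            intact_train=None) -> PerturbationResult:
    """Paired intact/perturbed runs differing only in one withheld stimulus.

    ``delta_apd[k-1]`` is APD(perturbed) - APD(intact) at stimulus index
    ``drop_index + k``; Nb is the first k whose |delta| stays below ``tol``
    for ``sustain`` consecutive beats.  If the perturbed tail sustains
    alternans, Nb is the NOT_RECOVERED sentinel.
    """
    if drop_index + follow > schedule.n_beats:
        raise ValueError(
            f"need {follow} beats after the drop; schedule has only "
            f"{schedule.n_beats - drop_index}")
    intact = intact_train if intact_train is not None else run_train(
        params, schedule, clamps=clamps, initial_state=initial_state, dt=dt)
    perturbed = run_train(params, drop_beat(schedule, drop_index),
                          clamps=clamps, initial_state=initial_state, dt=dt)
    sl = slice(drop_index, drop_index + follow)
    delta = perturbed.apd[sl] - intact.apd[sl]
    alt = detect_alternans(perturbed.apd[drop_index:], min_run=min(
        40, max(3, schedule.n_beats - drop_index - 1)))
    ok = np.abs(delta) < tol
    nb = NOT_RECOVERED
    if not (alt["present"] and alt["sustained"]):
        for k in range(len(ok) - sustain + 1):
            if np.all(ok[k:k + sustain]):
                nb = float(k)
                break
    return PerturbationResult(nb=nb, delta_apd=delta, alternans=alt,
                              drop_index=drop_index,
                              meta={"tol": tol, "follow": follow})


def average_delta_profile(params, schedule: PacingSchedule,
                          drop_positions, follow: int = 50,
                          initial_state=None, clamps=(), dt: float = 0.02):
    """Mean APD-displacement profile over several single-drop experiments.

    Returns (mean_profile, per_drop DataFrame of Nb and alternans flags).
    The intact reference is computed once; every perturbed run shares its
    schedule (and hence seed) with it.
    """
    intact = run_train(params, schedule, clamps=clamps,
                       initial_state=initial_state, dt=dt)
    profiles, rows = [], []
    for pos in drop_positions:
        res = missing_beat_experiment(
            params, schedule, int(pos), follow=follow, clamps=clamps,
            initial_state=initial_state, dt=dt, intact_train=intact)
        profiles.append(res.delta_apd)
        rows.append({"drop_index": int(pos), "nb": res.nb,
                     "alternans_present": res.alternans["present"],
                     "alternans_sustained": res.alternans["sustained"]})
    return np.nanmean(np.vstack(profiles), axis=0), pd.DataFrame(rows)


def mean_nb(per_drop: pd.DataFrame) -> float:
    """Mean Nb over drop positions, ignoring not-recovered sentinels."""
    nb = per_drop["nb"].to_numpy(float)
    finite = nb[np.isfinite(nb)]
    return float(np.mean(finite)) if finite.size else NOT_RECOVERED


def switch_experiment(params, constant_cl: float, constant_beats: int,
                      dynamic: PacingSchedule, drop_index: int,
                      clamps_after_switch=(), amp_tol: float = 2.0,
                      guard: int = 10, initial_state=None,
                      dt: float = 0.02):
    """Drop a beat during constant pacing, then switch to dynamic pacing.

    The constant phase (with the missing beat) must establish alternans
    before the switch, else the experiment is flagged invalid.  Clamps in
    ``clamps_after_switch`` take effect only from the switch onward
    (time-dependence removed at the moment of switching).  Returns a dict
    with ``quenched`` (alternans gone well before the end of the dynamic
    phase) and ``beats_to_quench``.
    """
    sched_const = drop_beat(constant_schedule(constant_cl, constant_beats),
                            drop_index)
    pre = run_train(params, sched_const, initial_state=initial_state, dt=dt)
    pre_apd = pre.apd[drop_index:]
    pre_alt = detect_alternans(pre_apd, amp_tol=amp_tol,
                               min_run=min(20, max(3, len(pre_apd) - 1)))
    post = run_train(params, dynamic, clamps=clamps_after_switch,
                     initial_state=pre.final_state, dt=dt)
    apd_post = post.apd[np.isfinite(post.apd)]
    d = np.diff(apd_post)
    qual = np.zeros(len(d), dtype=bool)
    for k in range(len(d)):
        if abs(d[k]) <= amp_tol:
            continue
        left = k > 0 and abs(d[k - 1]) > amp_tol and d[k] * d[k - 1] < 0
        right = (k + 1 < len(d) and abs(d[k + 1]) > amp_tol and
                 d[k] * d[k + 1] < 0)
        qual[k] = left or right
    if np.any(qual):
        last = int(np.flatnonzero(qual)[-1])
        beats_to_quench = last + 2
        quenched = beats_to_quench <= len(apd_post) - guard
    else:
        beats_to_quench = 0
        quenched = True
    return {"valid": bool(pre_alt["present"]), "quenched": bool(quenched),
            "beats_to_quench": int(beats_to_quench),
            "pre_alternans": pre_alt,
            "pre_train": pre, "post_train": post}


@dataclass
class CLChangeStats:
    """Exceedance fractions of |CL(N) - CL(N-1)| for two pacing laws."""

    table: pd.DataFrame       # threshold_ms, A_p, A_r, ratio

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold_ms"].to_numpy()


def cl_change_statistics(periodic: PacingSchedule, random: PacingSchedule,
                         thresholds=None) -> CLChangeStats:
    """Fraction of beats with |CL change| above each threshold, per law.

    ``ratio`` is A_periodic / A_random, with infinity where the random
    fraction is zero but the periodic one is not, and NaN where both are
    zero.
    """
    for key in ("CL_star", "clv"):
        pv, rv = periodic.meta.get(key), random.meta.get(key)
        if pv is not None and rv is not None and pv != rv:
            raise ValueError(f"schedules disagree on {key}: {pv} vs {rv}")
    dp = abs_cl_changes(periodic)
    dr = abs_cl_changes(random)
    if dp.size == 0 or dr.size == 0:
        raise ValueError("schedules too short for CL-change statistics")
    if thresholds is None:
        thresholds = np.arange(0.0, 71.0, 1.0)
    thresholds = np.asarray(thresholds, float)
    a_p = np.array([np.mean(dp > th) for th in thresholds])
    a_r = np.array([np.mean(dr > th) for th in thresholds])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a_p / a_r
    ratio[(a_r == 0) & (a_p > 0)] = np.inf
    ratio[(a_r == 0) & (a_p == 0)] = np.nan
    return CLChangeStats(table=pd.DataFrame({
        "threshold_ms": thresholds, "A_p": a_p, "A_r": a_r,
        "ratio": ratio}))
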