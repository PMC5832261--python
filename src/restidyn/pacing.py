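"""Pacing laws: beat-timing schedules for constant and dynamic stimulation.

A schedule is an ordered list of cycle lengths CL(N), N = 1..n_beats, with
stimulus times t(N) = sum_{i<=N} CL(i).  The three dynamic laws are

* random:    CL(N) = CL* + clv * U(-1, 1)          (uniform, seeded)
* periodic:  CL(N) = CL* + clv * sin(omega * N)
* alternating: CL(N) = CL* + (-1)**N * clv

where CL* is the central cycle length (ms), clv the half-range of
variability (ms) and omega the angular frequency in rad/beat, so that
2*pi/omega beats complete one oscillation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InvalidProtocolError(ValueError):
    """Raised when pacing-law parameters could produce non-positive CLs."""


@dataclass
class PacingSchedule:
    """Ordered beat plan.

    Attributes
    ----------
    cl : per-beat cycle length (ms); ``cl[N-1]`` is CL(N).
    stim_time : cumulative stimulus clock, t(N) = sum CL(i).
    stim_enabled : False marks a beat whose stimulus is withheld (the
        pacing clock is *not* reset -- a missing beat, not a pause).
    meta : law name and parameters (CL*, clv, omega, seed, ...).
    """

    cl: np.ndarray
    stim_enabled: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cl = np.asarray(self.cl, dtype=np.float64)
        self.stim_enabled = np.asarray(self.stim_enabled, dtype=bool)
        if self.cl.ndim != 1 or self.cl.size == 0:
            raise InvalidProtocolError("schedule needs at least one beat")
        if self.cl.size != self.stim_enabled.size:
            raise InvalidProtocolError("cl and stim_enabled length mismatch")
        if np.any(self.cl <= 0):
            raise InvalidProtocolError("cycle lengths must be positive")

    @property
    def n_beats(self) -> int:
        return int(self.cl.size)

    @property
    def stim_time(self) -> np.ndarray:
        return np.cumsum(self.cl)

    def copy(self) -> "PacingSchedule":
        return PacingSchedule(self.cl.copy(), self.stim_enabled.copy(),
                              dict(self.meta))

    # --- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "index": np.arange(1, self.n_beats + 1),
            "CL_ms": self.cl,
            "stim_time_ms": self.stim_time,
            "stim_enabled": self.stim_enabled.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta=None) -> "PacingSchedule":
        df = pd.read_csv(path)
        return cls(df["CL_ms"].to_numpy(),
                   df["stim_enabled"].to_numpy().astype(bool),
                   meta or {})

    def to_json(self) -> str:
        return json.dumps({
            "meta": self.meta,
            "CL_ms": self.cl.tolist(),
            "stim_enabled": self.stim_enabled.astype(int).tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "PacingSchedule":
        d = json.loads(text)
        return cls(np.array(d["CL_ms"]),
                   np.array(d["stim_enabled"], dtype=bool), d.get("meta", {}))


def _check_variability(cl_star: float, clv: float) -> None:
    if cl_star <= 0:
        raise InvalidProtocolError("CL* must be positive")
    if clv < 0:
        raise InvalidProtocolError("clv must be non-negative")
    if clv >= cl_star:
        raise InvalidProtocolError(
            "clv >= CL* would allow non-positive cycle lengths")


def constant_schedule(cl: float, n_beats: int) -> PacingSchedule:
    """n_beats at a fixed cycle length."""
    if cl <= 0 or n_beats < 1:
        raise InvalidProtocolError("need cl > 0 and n_beats >= 1")
    return PacingSchedule(np.full(n_beats, float(cl)),
                          np.ones(n_beats, dtype=bool),
                          {"law": "constant", "CL_star": float(cl)})


def random_schedule(cl_star: float, clv: float, n_beats: int,
                    seed: int) -> PacingSchedule:
    """Uniform random CLs on [CL* - clv, CL* + clv], i.i.d. per beat."""
    _check_variability(cl_star, clv)
    rng = np.random.default_rng(seed)
    cl = cl_star + clv * rng.uniform(-1.0, 1.0, size=n_beats)
    return PacingSchedule(cl, np.ones(n_beats, dtype=bool),
                          {"law": "random", "CL_star": float(cl_star),
                           "clv": float(clv), "seed": int(seed)})


def periodic_schedule(cl_star: float, clv: float, omega: float,
                      n_beats: int, phase: int = 1) -> PacingSchedule:
    """Sinusoidal CLs, CL(N) = CL* + clv * sin(omega * N), N starting at
    ``phase`` (default 1, matching the cumulative-time convention)."""
    _check_variability(cl_star, clv)
    if omega < 0:
        raise InvalidProtocolError("omega must be non-negative")
    n = np.arange(phase, phase + n_beats, dtype=np.float64)
    cl = cl_star + clv * np.sin(omega * n)
    return PacingSchedule(cl, np.ones(n_beats, dtype=bool),
                          {"law": "periodic", "CL_star": float(cl_star),
                           "clv": float(clv), "omega": float(omega),
                           "phase": int(phase)})


def alternating_schedule(cl_star: float, clv: float,
                         n_beats: int) -> PacingSchedule:
    """CL alternates CL* - clv, CL* + clv, ... (N = 1 gives the short CL)."""
    _check_variability(cl_star, clv)
    n = np.arange(1, n_beats + 1)
    cl = cl_star + ((-1.0) ** n) * clv
    return PacingSchedule(cl, np.ones(n_beats, dtype=bool),
                          {"law": "alternating", "CL_star": float(cl_star),
                           "clv": float(clv)})


def drop_beat(schedule: PacingSchedule, beat_index: int) -> PacingSchedule:
    """Withhold the stimulus of one beat (1-based index); timing unchanged.

    The surrounding inter-stimulus gap becomes CL(N) + CL(N+1) because the
    pacing clock keeps running.  Idempotent; re-enabling restores the
    original schedule.
    """
    if not 1 <= beat_index <= schedule.n_beats:
        raise IndexError(f"beat_index {beat_index} out of range "
                         f"1..{schedule.n_beats}")
    out = schedule.copy()
    out.stim_enabled[beat_index - 1] = False
    out.meta.setdefault("dropped_beats", [])
    if beat_index not in out.meta["dropped_beats"]:
        out.meta["dropped_beats"] = sorted(
            out.meta["dropped_beats"] + [beat_index])
    return out


def switch_schedule(constant_part: tuple, dynamic_part: PacingSchedule
                    ) -> PacingSchedule:
    """Concatenate a constant run-in with a dynamic schedule.

    ``constant_part`` is (CL, duration_ms); the constant phase lasts
    floor(duration / CL) beats, then the dynamic schedule continues on the
    same stimulus clock.  ``meta['switch_beat']`` records the 1-based index
    of the first dynamic beat.
    """
    cl0, duration = constant_part
    if cl0 <= 0 or duration < cl0:
        raise InvalidProtocolError("constant part needs cl > 0 and at "
                                   "least one beat")
    n0 = int(np.floor(duration / cl0))
    cl = np.concatenate([np.full(n0, float(cl0)), dynamic_part.cl])
    enabled = np.concatenate([np.ones(n0, dtype=bool),
                              dynamic_part.stim_enabled])
    meta = {"law": "composite", "constant_CL": float(cl0),
            "constant_beats": n0, "switch_beat": n0 + 1,
            "dynamic": dict(dynamic_part.meta)}
    return PacingSchedule(cl, enabled, meta)


def abs_cl_changes(schedule: PacingSchedule) -> np.ndarray:
    """|CL(N) - CL(N-1)| for N = 2..n_beats."""
    return np.abs(np.diff(schedule.cl))
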