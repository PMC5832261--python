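"""Spaces of states and hysteresis metrics for dynamic restitution.

A *space of states* is the point cloud {(CL_{n-1}, APD_n)} (or with the
preceding diastolic interval as abscissa) generated by a beat-to-beat
variable pacing train.  Under constant pacing it degenerates to one point;
under fast periodic pacing the CL-representation opens into a clockwise
hysteresis loop whose vertical width at CL* (the *shift*) measures
short-term AP memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class EmptySpaceError(ValueError):
    pass


class CoverageError(ValueError):
    """Not enough points near the requested reference abscissa."""


class UnimodalityError(ValueError):
    """The cloud forms a loop; use major_axis_slope instead of an OLS fit."""


@dataclass
class SpaceOfStates:
    """Lag-1 point cloud of a pacing train.

    ``points`` columns: ``x_ms`` (CL_{n-1} or DI_{n-1}), ``APD_ms``
    (APD_n) and ``direction`` (+1 where the abscissa was increasing,
    -1 decreasing, 0 undefined).
    """

    mode: str                   # "vs_CL" | "vs_DI"
    points: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def x(self) -> np.ndarray:
        return self.points["x_ms"].to_numpy()

    @property
    def apd(self) -> np.ndarray:
        return self.points["APD_ms"].to_numpy()

    @property
    def direction(self) -> np.ndarray:
        return self.points["direction"].to_numpy()

    def to_csv(self, path) -> None:
        df = self.points.copy()
        df["mode"] = self.mode
        df.to_csv(path, index=False)


def space_of_states(train, mode: str = "vs_CL",
                    discard: int = 0) -> SpaceOfStates:
    """Build the lag-1 space of states from an AP train.

    For beat n the abscissa is the cycle length (or diastolic interval)
    closing at beat n's stimulus, i.e. the previous record's CL/DI; the
    ordinate is APD_n.  ``discard`` drops initial transient beats.
    Capture-failure (NaN APD) records are skipped.
    """
    if mode not in ("vs_CL", "vs_DI"):
        raise ValueError("mode must be 'vs_CL' or 'vs_DI'")
    beats = train.beats.iloc[discard:]
    cl = beats["CL_ms"].to_numpy()
    apd = beats["APD_ms"].to_numpy()
    xprev = cl[:-1] if mode == "vs_CL" else (cl[:-1] - apd[:-1])
    y = apd[1:]
    xprev2 = np.concatenate([[np.nan], xprev[:-1]])
    ok = np.isfinite(xprev) & np.isfinite(y)
    if not np.any(ok):
        raise EmptySpaceError("no finite lag-1 pairs in train")
    with np.errstate(invalid="ignore"):
        direction = np.sign(xprev - xprev2)
    direction[~np.isfinite(direction)] = 0.0
    df = pd.DataFrame({"x_ms": xprev[ok], "APD_ms": y[ok],
                       "direction": direction[ok].astype(int)})
    meta = dict(getattr(train, "meta", {}).get("schedule", {}))
    return SpaceOfStates(mode=mode, points=df, meta=meta)


def _branches(space: SpaceOfStates):
    up = space.points[space.points["direction"] > 0]
    down = space.points[space.points["direction"] < 0]
    return up, down


def _branch_interp(branch: pd.DataFrame, x0: float) -> float:
    b = branch.sort_values("x_ms")
    x = b["x_ms"].to_numpy()
    y = b["APD_ms"].to_numpy()
    if x.size < 2 or not (x.min() - 1e-9 <= x0 <= x.max() + 1e-9):
        raise CoverageError(f"branch does not cover x = {x0}")
    return float(np.interp(x0, x, y))


def loop_width(space: SpaceOfStates) -> float:
    """Mean vertical separation of the two branches over the central 50%
    of the common x-range (the unimodal-vs-loop statistic)."""
    up, down = _branches(space)
    if len(up) < 2 or len(down) < 2:
        return 0.0
    lo = max(up["x_ms"].min(), down["x_ms"].min())
    hi = min(up["x_ms"].max(), down["x_ms"].max())
    if hi <= lo:
        return 0.0
    xs = np.linspace(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo), 21)
    seps = [abs(_branch_interp(up, x) - _branch_interp(down, x)) for x in xs]
    return float(np.mean(seps))


def shift(space: SpaceOfStates, reference_x: float | None = None,
          tol_bin: float = 2.0, method: str | None = None) -> float:
    """Vertical width of the space of states at the reference abscissa.

    Periodic sources: |up-branch - down-branch| interpolated at the
    reference (hysteresis width).  Random sources: max - min APD among
    points within ``tol_bin`` ms of the reference.  Constant sources: 0.
    """
    law = space.meta.get("law", None)
    method = method or {"periodic": "branches", "random": "bin",
                        "alternating": "bin"}.get(law, None)
    if reference_x is None:
        reference_x = space.meta.get("CL_star")
        if space.mode == "vs_DI" or reference_x is None:
            reference_x = float(np.median(space.x))
    if method is None:
        if law == "constant" or np.ptp(space.x) < 1e-9:
            return 0.0
        method = "bin"
    if method == "branches":
        up, down = _branches(space)
        return abs(_branch_interp(up, reference_x) -
                   _branch_interp(down, reference_x))
    if method == "bin":
        sel = np.abs(space.x - reference_x) <= tol_bin
        if sel.sum() < 2:
            raise CoverageError(
                f"fewer than 2 points within {tol_bin} ms of {reference_x}")
        return float(np.ptp(space.apd[sel]))
    raise ValueError(f"unknown shift method {method!r}")


def der_slope(space: SpaceOfStates, loop_tol: float = 2.0,
              window: int = 5, min_span: float = 2.0):
    """Slope statistics of a unimodal dynamic-restitution cloud.

    Returns (ols_slope, max_local_slope).  The OLS slope is the
    least-squares regression of APD on x over all points; the local slope
    is the maximum windowed finite-difference slope along the x-sorted
    cloud.  Windows narrower than ``min_span`` ms are skipped: where many
    beats share nearly the same abscissa, a finite-difference slope
    amplifies millisecond-level APD scatter into arbitrarily large values.
    Raises :class:`UnimodalityError` when the cloud is a loop (width >
    ``loop_tol`` ms) -- use :func:`major_axis_slope` there.
    """
    if loop_width(space) > loop_tol:
        raise UnimodalityError(
            "space of states forms a hysteresis loop; its slope is "
            "summarized by major_axis_slope")
    x, y = space.x, space.apd
    if x.size < 2 or np.ptp(x) < 1e-12:
        raise ValueError("degenerate cloud: no x spread")
    ols = float(np.polyfit(x, y, 1)[0])
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    local = []
    for i in range(len(xs) - window + 1):
        xi, yi = xs[i:i + window], ys[i:i + window]
        if np.ptp(xi) < min_span:
            continue
        local.append(np.polyfit(xi, yi, 1)[0])
    max_local = float(np.max(local)) if local else ols
    return ols, max_local


def major_axis_slope(space: SpaceOfStates, degenerate_tol: float = 1e-9):
    """Slope of the first principal axis of the mean-centered cloud.

    Both axes are in ms (no standardization), so for a loop this is the
    hysteresis major-axis slope; for points on a line it equals the OLS
    slope.  Returns (slope, degenerate_flag); a rank-deficient cloud falls
    back to OLS with the flag set.
    """
    x = space.x - space.x.mean()
    y = space.apd - space.apd.mean()
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, int(np.argmax(evals))]
    if abs(v[0]) < degenerate_tol:
        return float(np.polyfit(space.x, space.apd, 1)[0]), True
    return float(v[1] / v[0]), False


def fit_monoexponential(x, y, p0=None):
    """Nonlinear least squares of y = a * exp(-x / tau) + c.

    Returns (a, tau, c, r_squared).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need at least 4 points")
    if p0 is None:
        c0 = float(y[np.argmax(x)])
        a0 = float(y[np.argmin(x)] - c0)
        if abs(a0) < 1e-12:
            a0 = max(1e-12, float(np.ptp(y)))
        tau0 = float(np.ptp(x)) / 2 or 1.0
        p0 = (a0, tau0, c0)

    def model(xx, a, tau, c):
        return a * np.exp(-xx / tau) + c

    popt, _ = curve_fit(model, x, y, p0=p0, maxfev=20000,
                        bounds=([-np.inf, 1e-9, -np.inf],
                                [np.inf, np.inf, np.inf]))
    resid = y - model(x, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return popt[0], popt[1], popt[2], r2


def er_to_rd_beats(params, cl_cond: float, cl_target: float,
                   tol: float = 2.0, n_cond: int = 300, sustain: int = 10,
                   horizon: int = 200, dt: float = 0.02,
                   cond_state=None) -> int:
    """Beats for APD to relax to the new steady state after a CL step.

    Conditions at ``cl_cond``, steps to constant ``cl_target`` and returns
    the first beat index whose APD is within ``tol`` ms of the target
    steady-state APD, sustained for ``sustain`` beats.
    """
    from .engine import condition, run_train, snapshot
    from .pacing import constant_schedule

    if cl_target == cl_cond:
        return 0
    if cond_state is None:
        cond = condition(params, cl_cond, n_cond, dt=dt)
        state0 = snapshot(cond)
    else:
        state0 = np.asarray(cond_state, float).copy()
    step_train = run_train(params, constant_schedule(cl_target, horizon),
                           initial_state=state0, dt=dt)
    if not np.all(step_train.captured):
        raise RuntimeError("capture loss after the CL step")
    apd_ss = float(np.mean(step_train.apd[-10:]))
    dev = np.abs(step_train.apd - apd_ss) < tol
    for k in range(len(dev) - sustain + 1):
        if np.all(dev[k:k + sustain]):
            return k
    return horizon
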