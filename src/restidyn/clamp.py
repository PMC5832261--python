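"""Time-dependence removal: polynomial voltage clamps for plateau currents.

A clamp freezes the gating kinetics of one of I_CaL, I_Kr or I_Ks by
replacing the current with a polynomial fit of its I--V trajectory recorded
during a steady-state AP.  The fit only uses samples later than a blanking
window (default 9 ms) after the upstroke, because the early spike-and-notch
phase is dominated by fast kinetics and the I--V loop is strongly
multivalued there.  During simulation the clamp is likewise inactive inside
the blanking window of each AP, and the polynomial is evaluated at the
nearest boundary of its fitted voltage range outside it (no extrapolation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .tp06 import ModelParams

_CLAMPABLE = ("I_CaL", "I_Kr", "I_Ks")


class ClampFitError(RuntimeError):
    """No candidate polynomial order met the RMSE tolerance."""


@dataclass(frozen=True)
class ClampedCurrent:
    """A fitted voltage-only replacement for one plateau current."""

    current_name: str
    coefficients: tuple          # low -> high degree
    fit_order: int
    v_range: tuple               # (V_min, V_max) of the fitted samples, mV
    blank_ms: float = 9.0
    reference_cl: float = 350.0
    rmse: float = field(default=np.nan, compare=False)

    def __post_init__(self):
        if self.current_name not in _CLAMPABLE:
            raise ValueError(f"cannot clamp {self.current_name}; choose "
                             f"from {_CLAMPABLE}")

    def __call__(self, v):
        v = np.clip(v, self.v_range[0], self.v_range[1])
        return np.polynomial.polynomial.polyval(v, self.coefficients)

    def to_json(self) -> str:
        return json.dumps({
            "current_name": self.current_name,
            "coefficients": list(self.coefficients),
            "fit_order": self.fit_order,
            "v_range": list(self.v_range),
            "blank_ms": self.blank_ms,
            "reference_cl": self.reference_cl,
            "rmse": self.rmse,
        })

    @classmethod
    def from_json(cls, text: str) -> "ClampedCurrent":
        d = json.loads(text)
        return cls(current_name=d["current_name"],
                   coefficients=tuple(d["coefficients"]),
                   fit_order=d["fit_order"], v_range=tuple(d["v_range"]),
                   blank_ms=d["blank_ms"], reference_cl=d["reference_cl"],
                   rmse=d.get("rmse", np.nan))


def fit_current_clamp(params: ModelParams, current_name: str,
                      reference_cl: float = 350.0, n_cond: int = 300,
                      blank_ms: float = 9.0, orders=range(3, 13),
                      rmse_tol: float = 0.02, cond_state=None,
                      dt: float = 0.02) -> ClampedCurrent:
    """Fit a voltage polynomial to a current recorded during a steady AP.

    The model is conditioned at ``reference_cl`` (or continued from
    ``cond_state``), one further beat is simulated with trace recording,
    and I(V) samples with t > ``blank_ms`` after the upstroke are fitted
    with polynomials of increasing order.  The lowest order whose RMSE is
    below ``rmse_tol`` times the current's peak-to-peak range wins.  Where
    the I--V trajectory is still multivalued after blanking, least squares
    averages the branches.
    """
    from .engine import condition, run_train, snapshot
    from .pacing import constant_schedule

    if cond_state is None:
        cond = condition(params, reference_cl, n_cond, dt=dt)
        state0 = snapshot(cond)
    else:
        state0 = np.asarray(cond_state, dtype=float).copy()

    train = run_train(params, constant_schedule(reference_cl, 1),
                      initial_state=state0, record_traces=True, dt=dt,
                      trace_dt=0.1)
    t_up = float(train.beats["upstroke_ms"].iloc[0])
    if not np.isfinite(t_up):
        raise ClampFitError("reference beat did not capture")
    tr = train.traces
    sel = tr["t_ms"].to_numpy() > t_up + blank_ms
    v = tr["Vm_mV"].to_numpy()[sel]
    i = tr[current_name].to_numpy()[sel]
    span = float(i.max() - i.min())
    tol = rmse_tol * span

    best = None
    for order in orders:
        coefs = np.polynomial.polynomial.polyfit(v, i, order)
        resid = np.polynomial.polynomial.polyval(v, coefs) - i
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        if best is None or rmse < best[1]:
            best = (coefs, rmse, order)
        if rmse <= tol:
            return ClampedCurrent(
                current_name=current_name, coefficients=tuple(coefs),
                fit_order=order, v_range=(float(v.min()), float(v.max())),
                blank_ms=blank_ms, reference_cl=reference_cl, rmse=rmse)
    raise ClampFitError(
        f"no order in {list(orders)} met RMSE tolerance {tol:.4g} "
        f"(best: order {best[2]}, RMSE {best[1]:.4g})")
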