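"""ten Tusscher--Panfilov 2006 (TP06) human ventricular myocyte model.

The model describes a single (non-propagated) epicardial ventricular cell
with 19 state variables: membrane potential, 12 Hodgkin-Huxley gating
variables, the ryanodine-receptor availability variable, and the Na+/K+/Ca2+
concentrations in the cytosol, sarcoplasmic reticulum and dyadic subspace.
Equations and constants follow the published CellML encoding of the
epicardial variant.

Units: time ms, voltage mV, concentrations mM, currents A/F (pA/pF),
conductances nS/pF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel

#: Canonical state ordering. Index 0 is V_m; 1..13 are dimensionless
#: activation/inactivation variables (incl. the RyR availability R');
#: 14..18 are ionic concentrations in mM.
STATE_NAMES = (
    "V",      # membrane potential, mV
    "Xr1",    # I_Kr activation
    "Xr2",    # I_Kr inactivation
    "Xs",     # I_Ks activation
    "m",      # I_Na activation
    "h",      # I_Na fast inactivation
    "j",      # I_Na slow inactivation
    "d",      # I_CaL activation
    "f",      # I_CaL voltage inactivation (slow)
    "f2",     # I_CaL voltage inactivation (fast)
    "fCass",  # I_CaL Ca-dependent inactivation
    "s",      # I_to inactivation
    "r",      # I_to activation
    "Rbar",   # RyR availability (R')
    "Ca_i",   # cytosolic Ca2+, mM
    "Ca_SR",  # SR Ca2+, mM
    "Ca_ss",  # dyadic subspace Ca2+, mM
    "Na_i",   # intracellular Na+, mM
    "K_i",    # intracellular K+, mM
)

N_STATES = 19

#: Epicardial steady-pacing initial condition (1 Hz), from the published
#: CellML parameterization.  Any long conditioning train re-converges the
#: state, so this only needs to be a reasonable starting point.
INITIAL_STATE = np.array([
    -85.23,      # V
    0.00621,     # Xr1
    0.4712,      # Xr2
    0.0095,      # Xs
    0.00172,     # m
    0.7444,      # h
    0.7045,      # j
    3.373e-5,    # d
    0.7888,      # f
    0.9755,      # f2
    0.9953,      # fCass
    0.999998,    # s
    2.42e-8,     # r
    0.9073,      # Rbar
    0.000126,    # Ca_i
    3.64,        # Ca_SR
    0.00036,     # Ca_ss
    8.604,       # Na_i
    136.89,      # K_i
])

_GATE_SLICE = slice(1, 14)
_CONC_SLICE = slice(14, 19)

# Parameter vector layout (shared with the compiled kernel).
PARAM_NAMES = (
    "g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL", "g_bNa", "g_bCa",
    "g_pCa", "g_pK", "P_NaK", "K_NaCa", "Vmax_up", "V_rel", "V_leak",
    "V_xfer", "Na_o", "K_o", "Ca_o", "K_mk", "K_mNa", "K_mNai", "K_mCa",
    "k_sat", "gamma", "K_pCa", "k1_prime", "k2_prime", "k3", "k4", "EC",
    "max_sr", "min_sr", "Buf_c", "K_buf_c", "Buf_sr", "K_buf_sr", "Buf_ss",
    "K_buf_ss", "V_c", "V_sr", "V_ss", "Cm", "F", "R", "T", "p_KNa", "K_up",
)

_DEFAULTS = {
    "g_Na": 14.838, "g_K1": 5.405, "g_to": 0.294, "g_Kr": 0.153,
    "g_Ks": 0.392, "g_CaL": 3.98e-5, "g_bNa": 2.9e-4, "g_bCa": 5.92e-4,
    "g_pCa": 0.1238, "g_pK": 0.0146, "P_NaK": 2.724, "K_NaCa": 1000.0,
    "Vmax_up": 0.006375, "V_rel": 0.102, "V_leak": 3.6e-4, "V_xfer": 0.0038,
    "Na_o": 140.0, "K_o": 5.4, "Ca_o": 2.0, "K_mk": 1.0, "K_mNa": 40.0,
    "K_mNai": 87.5, "K_mCa": 1.38, "k_sat": 0.1, "gamma": 0.35,
    "K_pCa": 5e-4, "k1_prime": 0.15, "k2_prime": 0.045, "k3": 0.06,
    "k4": 0.005, "EC": 1.5, "max_sr": 2.5, "min_sr": 1.0, "Buf_c": 0.2,
    "K_buf_c": 0.001, "Buf_sr": 10.0, "K_buf_sr": 0.3, "Buf_ss": 0.4,
    "K_buf_ss": 2.5e-4, "V_c": 0.016404, "V_sr": 0.001094, "V_ss": 5.468e-5,
    "Cm": 0.185, "F": 96485.3415, "R": 8314.472, "T": 310.0, "p_KNa": 0.03,
    "K_up": 2.5e-4,
}

#: Conductances that may be scaled via :func:`scale_conductances`, keyed by
#: the current they gate.
SCALABLE = {
    "I_Na": "g_Na", "I_K1": "g_K1", "I_to": "g_to", "I_Kr": "g_Kr",
    "I_Ks": "g_Ks", "I_CaL": "g_CaL", "I_pCa": "g_pCa", "I_pK": "g_pK",
}


class InvalidStateError(ValueError):
    """Raised when a state vector violates the model invariants."""


class ThresholdSearchError(RuntimeError):
    """Raised when the stimulus-threshold bisection cannot bracket capture."""


@dataclass(frozen=True)
class ModelParams:
    """TP06 parameter set (epicardial defaults).

    ``values`` maps parameter names to values in model units; any name not
    present falls back to the published default.  Instances are immutable;
    use :func:`scale_conductances` to derive modified sets.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown TP06 parameters: {sorted(unknown)}")

    def __getitem__(self, name: str) -> float:
        return self.values.get(name, _DEFAULTS[name])

    def as_array(self) -> np.ndarray:
        """Pack into the flat vector consumed by the compiled kernel."""
        return np.array([self[n] for n in PARAM_NAMES], dtype=np.float64)

    def with_values(self, **kwargs) -> "ModelParams":
        merged = dict(self.values)
        merged.update(kwargs)
        return ModelParams(values=merged)

    def to_json(self) -> str:
        return json.dumps({n: self[n] for n in PARAM_NAMES}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls(values=json.loads(text))


@dataclass(frozen=True)
class StimulusSpec:
    """Square current pulse: 3 ms at 1.5x the capture threshold by default."""

    duration: float = 3.0          # ms
    amplitude_factor: float = 1.5  # multiple of threshold
    threshold_amplitude: float | None = None  # A/F; resolved lazily

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.amplitude_factor < 1:
            raise ValueError("amplitude_factor must be >= 1")

    @property
    def amplitude(self) -> float:
        if self.threshold_amplitude is None:
            raise ValueError("threshold_amplitude not resolved yet")
        return self.amplitude_factor * self.threshold_amplitude


def validate_state(state: np.ndarray) -> np.ndarray:
    """Check the 19-variable state invariants and return a float64 copy."""
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (N_STATES,):
        raise InvalidStateError(f"state must have shape (19,), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise InvalidStateError("state contains non-finite entries")
    gates = state[_GATE_SLICE]
    if np.any(gates < -1e-9) or np.any(gates > 1 + 1e-9):
        raise InvalidStateError("gating variables must lie in [0, 1]")
    if np.any(state[_CONC_SLICE] <= 0):
        raise InvalidStateError("ionic concentrations must be positive")
    return state


def scale_conductances(params: ModelParams, factors: dict) -> ModelParams:
    """Multiply maximal conductances by per-current factors.

    ``factors`` maps current names (e.g. ``"I_Kr"``) to positive multipliers.
    Scaling is multiplicative, so composing two calls multiplies factors.
    """
    updates = {}
    for current, factor in factors.items():
        if current not in SCALABLE:
            raise KeyError(
                f"unknown or non-scalable current {current!r}; "
                f"choose from {sorted(SCALABLE)}"
            )
        if not factor > 0:
            raise ValueError(f"scale factor for {current} must be > 0")
        pname = SCALABLE[current]
        updates[pname] = params[pname] * factor
    return params.with_values(**updates)


def derivatives(state, t, params: ModelParams, i_stim: float = 0.0,
                clamps=()) -> np.ndarray:
    """Time-derivatives of the 19 TP06 state variables.

    ``i_stim`` follows the membrane-current sign convention (a depolarizing
    stimulus is negative).  ``clamps`` is a sequence of
    :class:`~restidyn.clamp.ClampedCurrent`; a clamped current is replaced by
    its fitted voltage polynomial (the caller is responsible for honoring the
    post-upstroke blanking window -- pass no clamps to get native gating).
    """
    state = validate_state(state)
    flags, coefs, ncoef, vlo, vhi, _blank = pack_clamps(clamps)
    out = np.empty(_kernel.EVAL_LEN, dtype=np.float64)
    _kernel.tp06_eval(state, params.as_array(), float(i_stim),
                      flags, coefs, ncoef, vlo, vhi, out)
    return out[:N_STATES].copy()


def membrane_currents(state, params: ModelParams, i_stim: float = 0.0) -> dict:
    """Individual membrane currents (A/F) at a given state."""
    state = validate_state(state)
    flags, coefs, ncoef, vlo, vhi, _blank = pack_clamps(())
    out = np.empty(_kernel.EVAL_LEN, dtype=np.float64)
    _kernel.tp06_eval(state, params.as_array(), float(i_stim),
                      flags, coefs, ncoef, vlo, vhi, out)
    names = ("I_CaL", "I_Kr", "I_Ks", "I_Na", "I_K1", "I_to", "I_NaCa",
             "I_NaK", "I_pCa", "I_pK", "I_bNa", "I_bCa")
    return {n: out[_kernel.CUR_OFF + k] for k, n in enumerate(names)}


def pack_clamps(clamps):
    """Pack ClampedCurrent objects into the kernel's fixed-size arrays."""
    flags = np.zeros(3, dtype=np.int64)
    coefs = np.zeros((3, _kernel.MAX_COEF), dtype=np.float64)
    ncoef = np.zeros(3, dtype=np.int64)
    vlo = np.zeros(3, dtype=np.float64)
    vhi = np.zeros(3, dtype=np.float64)
    blank = np.full(3, 9.0, dtype=np.float64)
    for c in clamps:
        idx = _kernel.CLAMP_INDEX[c.current_name]
        n = len(c.coefficients)
        if n > _kernel.MAX_COEF:
            raise ValueError("clamp polynomial order too high for kernel")
        flags[idx] = 1
        coefs[idx, :n] = c.coefficients
        ncoef[idx] = n
        vlo[idx], vhi[idx] = c.v_range
        blank[idx] = c.blank_ms
    return flags, coefs, ncoef, vlo, vhi, blank


def resting_state(params: ModelParams, quiescence_ms: float = 10_000.0,
                  dt: float = 0.02, initial=None) -> np.ndarray:
    """Relax the model without stimulation and return the final state."""
    from .engine import run_train  # local import to avoid a cycle
    from .pacing import constant_schedule

    y0 = INITIAL_STATE.copy() if initial is None else validate_state(initial).copy()
    sched = constant_schedule(quiescence_ms, 1)
    sched.stim_enabled[:] = False
    train = run_train(params, sched, initial_state=y0, dt=dt,
                      stimulus=StimulusSpec(threshold_amplitude=0.0))
    return train.final_state


def elicits_ap(state, params: ModelParams, amplitude: float,
               duration: float = 3.0, dt: float = 0.02) -> bool:
    """True if a single pulse of given amplitude (A/F) captures an AP."""
    y = validate_state(state).copy()
    cl = np.array([40.0])
    enabled = np.ones(1, dtype=np.int64)
    flags, coefs, ncoef, vlo, vhi, blank = pack_clamps(())
    res = _kernel.run_schedule(
        y, ModelParams().as_array() if params is None else params.as_array(),
        cl, enabled, float(amplitude), float(duration), dt,
        flags, coefs, ncoef, vlo, vhi, blank,
        0, np.empty(0), np.empty(0), np.empty((3, 0)), np.empty(0))
    return bool(res[0][0])


def find_threshold(state, params: ModelParams, duration: float = 3.0,
                   upper: float = 200.0, rel_tol: float = 0.01,
                   dt: float = 0.02) -> float:
    """Minimal stimulus amplitude (A/F) capturing an AP, by bisection.

    Capture means V_m exceeds 0 mV within 20 ms of pulse onset.  The search
    bisects [0, ``upper``] down to ``rel_tol`` relative width and returns the
    midpoint of the final bracket.
    """
    state = validate_state(state)
    lo, hi = 0.0, float(upper)
    if not elicits_ap(state, params, hi, duration, dt):
        raise ThresholdSearchError(
            f"no capture at the upper search bound {upper} A/F")
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if elicits_ap(state, params, mid, duration, dt):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def state_to_json(state) -> str:
    state = validate_state(state)
    return json.dumps(dict(zip(STATE_NAMES, state.tolist())), indent=1)


def state_from_json(text: str) -> np.ndarray:
    d = json.loads(text)
    return validate_state(np.array([d[n] for n in STATE_NAMES]))
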