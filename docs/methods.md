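# Methods

## The model

All electrophysiology in this package is the ten Tusscher–Panfilov 2006
(TP06) human ventricular myocyte, epicardial variant, as a single
(non-propagated) cell: 19 state variables — membrane potential V_m, twelve
Hodgkin–Huxley gating variables, the ryanodine-receptor availability
variable R', and the Na⁺/K⁺/Ca²⁺ concentrations of cytosol, sarcoplasmic
reticulum (SR) and dyadic subspace.  The equations and constants were
transcribed from the published CellML encoding of the epicardial
parameterization (`src/restidyn/_kernel.py`; the parameter roster and
state ordering are in `src/restidyn/tp06.py`).  Units are ms, mV, mM and
A/F throughout.

Because no CellML runtime is a dependency of this package, the
transcription is validated behaviourally rather than symbolically:

* the quiescent model sits at the published resting potential (−86.2 mV)
  with V and all gates equilibrated;
* the 1 Hz action potential reproduces the published epicardial duration
  (≈301 ms) and upstroke velocity;
* a single beat integrated with an independent stiff solver (scipy BDF,
  rtol 1e−6) on the same right-hand side matches the fast fixed-step
  trajectory to < 2 mV outside the upstroke.

## Numerics

The integrator is the operator-split scheme the model's original authors
published for this system: exponential (Rush–Larsen) updates for the 13
relaxation variables — exact for frozen V — and forward Euler for V_m and
the five concentrations, at a fixed step of **dt = 0.02 ms**.  The scheme
is deterministic (fixed evaluation order, no fastmath), restarts every
beat on a step boundary so stimulus edges never straddle a step, and was
checked for convergence: halving and quartering dt changes steady APD by
< 0.1 ms and leaves every reported metric unchanged to three figures
(Shift_CL at the study's fastest drive moves by 0.05 ms between dt = 0.02
and dt = 0.005).  An implicit adaptive solver was deliberately not used:
at equal accuracy it is orders of magnitude slower for beat-train studies
and introduces step-placement nondeterminism into APD detection.

Cycle lengths are realized as integer numbers of steps (quantization
≤ 0.01 ms); bookkeeping uses the exact requested CLs.

## Stimulation, APD and capture

APs are elicited with 3 ms square current pulses of amplitude 1.5× the
capture threshold.  The threshold is found by bisection (1 % relative
width) from the model's reference diastolic state and re-evaluated for
every parameter set; capture means V_m exceeds 0 mV within 20 ms of pulse
onset.  A beat whose stimulus lands on an unrepolarized membrane
(V_m > −40 mV at onset) is classified as merged/blocked, not captured —
this matters only in the 2:1-block regimes discussed below.

APD is APD₋₆₀ₘᵥ: from the upstroke (argmax dV/dt, refined by quadratic
interpolation around the discrete maximum so the measurement decouples
from step placement) to the linearly interpolated downward −60 mV
crossing.  An AP that has not repolarized when the next stimulus arrives
stays "open" and closes at its true crossing; if it never closes its APD
is NaN (merged-beat sentinel).

### Beat bookkeeping

Beat *n* is stimulated at t(n−1) = Σ_{i<n} CL(i); the first stimulus fires
at t = 0, which is exactly the instant a conditioning snapshot represents
(the state "at the end of the (n−1)-th cycle").  CL_n is the cycle
*initiated* by beat n, DI_n = CL_n − APD_n its closing diastole, and the
interval immediately preceding beat n is therefore CL_{n−1} — which is
what the lag-1 space-of-states pairing (CL_{n−1}, APD_n) uses.  With this
convention the steady DI at CL 350 ms is 350 − APD, and the two
representations of one train satisfy x_DI = x_CL − APD_{n−1} exactly.

## Protocols

* **Conditioning.** 300 beats at constant CL is the standard profile for
  every experiment and for the acceptance script (a `--full`/1000-beat
  profile is available through the experiment registry).  Caveat: TP06's
  Na⁺/K⁺ pools drift slowly, so "steady" APD at CL 350 ms still moves
  ≈ 4.8 ms between 300- and 1000-beat conditioning; the 300-beat profile
  is used consistently so all comparisons are matched.
* **Modified conductances** (G_Kr ×0.10, G_Ks ×0.40, G_CaL ×1.90 and their
  shortening counterparts) are conditioned by *continuing* 300 beats from
  the control snapshot: started from rest at CL 350 ms, the strongly
  AP-prolonged variants fall into 2:1 block (the first AP outlasts the
  cycle), whereas the experiments address the 1:1 branch.
* **Rate dependence (RD).** Steady APD per constant CL (default grid
  300–1400 ms, step 20), mean of the last 20 beats; capture failures flag
  the point rather than dropping it.
* **Classic restitution (ER).** Snapshot at a cycle end, replay the last
  conditioning beat, deliver the test beat after a variable cycle
  (default sweep CL* ± 35 ms for the perturbation studies, ± 20 ms
  otherwise), report APD_test against the test CL and against
  DI = test CL − APD_cond.  Local slopes are central differences on the
  swept grid.
* **Dynamic pacing.** CL(N) = CL* + clv·U(−1,1) (seeded, uniform),
  CL* + clv·sin(ωN) with N from 1, or the alternating law CL* ± clv.
  Spaces of states discard the first 50 beats of a 250-beat train.
* **Missing beat.** One stimulus withheld (clock not reset), intact and
  perturbed twins share schedule and seed, ΔAPD is aligned by stimulus
  index.  Nb is the first post-drop beat whose |ΔAPD| < 2 ms holds for 10
  consecutive beats (the sustainment guard keeps alternans zero-crossings
  from counting as recovery); reported as the mean over 20 drop positions
  (beats 10–29) and, for random pacing, over 5 seeds.
* **Alternans.** A qualifying run is consecutive APD differences of
  alternating sign, each > 2 ms; *present* needs ≥ 40 beats, *sustained*
  means the run reaches the end of the series (500-beat horizon for the
  induction experiments).
* **Switch experiments.** Constant phase (48 beats at 350 ms, drop at
  beat 10) followed by a dynamic phase on the same clock; clamps supplied
  for the dynamic phase only take effect at the switch.
* **Time-dependence removal (clamp).** The current of interest is recorded
  over one steady beat, its I–V trajectory fitted with polynomials of
  order 3–12 (lowest order meeting the RMSE tolerance wins), and the fit
  replaces the gated expression everywhere except the first 9 ms after
  each upstroke.  Outside the fitted voltage range the boundary value is
  used.  The post-blanking I–V trajectory is still a loop (the current
  differs between dome and late repolarization at equal V), so least
  squares averages branches; the achievable RMSE floor is ≈ 3 % of the
  current's range for I_Kr, ≈ 8 % for I_Ks and ≈ 10 % for I_CaL.  The
  default tolerance (2 %) therefore rejects most fits by design — the
  canonical experiments pass an explicit 12–15 % tolerance, and the
  2 ms clamp-self-consistency check holds for I_Kr but not for the
  heavily branch-averaged I_Ks/I_CaL fits.

## Metrics

* **Shift** (hysteresis width): for periodic sources, the vertical gap at
  the reference CL between the x-increasing and x-decreasing branches
  (each linearly interpolated); for random sources, the APD peak-to-peak
  within a ± 2 ms bin.  Branch direction is the sign of x_{n−1} − x_{n−2}.
* **Unimodal vs loop**: mean branch separation over the central 50 % of
  the x-range; a cloud wider than 2 ms refuses an OLS slope and reports
  the principal-axis slope instead.
* **dER slopes**: OLS over the whole cloud, plus a max local slope from
  window-5 finite differences along the x-sorted points.  Windows
  spanning < 2 ms in x are skipped: where many beats share an abscissa, a
  finite difference amplifies sub-ms APD scatter into arbitrarily large
  slopes.
* **Major-axis slope**: first principal axis of the mean-centered cloud,
  both axes in ms (no standardization); degenerate clouds fall back to
  OLS with a flag.
* **Mono-exponential fits**: scipy nonlinear least squares of
  a·exp(−x/τ) + c with R² reported.

## The surrogate map

For metric-layer tests a two-variable iterated map stands in for the ODE:
exponential restitution of the preceding DI minus a memory term that
relaxes toward the running APD level (parameters in
`src/restidyn/surrogate.py`; defaults APD_max 270 ms, a 150 ms, τ_r 60 ms,
τ_m 3 s, noise 0).  It reproduces the qualitative structure of the study
conditions in microseconds.  Computing its properties corrected an
intuition worth recording: a *memoryless* DI→APD map already produces a
CL-hysteresis loop at fast periodic drive — the one-beat history carried
by APD itself, since DI = CL − APD — and that loop collapses when the
drive is adiabatic.  What the accumulating memory term uniquely adds is a
loop in the (DI, APD) plane, which is exactly zero for the memoryless map.
The surrogate emulates beat-series structure only; it has no ionic
content, no capture physics beyond the DI > 0 rule, and is never used for
any model-level result.

## Design choices on genuinely open points

* rand(−1,1) is uniform (the minimal reading of "a random number between
  −1 and 1"); the generator seed is schedule metadata.
* The sinusoid's beat index starts at 1; the phase is configurable.
* The classic-ER sweep half-width is a parameter (35 ms for the
  perturbation-study reproductions, 20 ms otherwise).
* The slope estimator for dER clouds (OLS vs max-local) is surfaced in
  the API because the printed slopes in the source material do not state
  their estimator.
* Nb counts the beats that deviate (the 0-based index of the first beat
  of the sustained-recovery run).

## Known limitations

* Quantitative short-term-memory indices come out systematically smaller
  than the reported values this package set out to reproduce
  (Shift_CL ≈ 57 vs 73 ms at ω = 2.4; constant-pacing Nb ≈ 6 vs 2.6;
  max dER_DI slope ≈ 1.2 vs 1.6), robustly across dt, conditioning depth
  and estimator choice.  The discrepancies are internally coherent — a
  model with stronger accumulated memory damps post-pause oscillations
  faster *and* shows a wider hysteresis loop — and the reference values
  are themselves in tension with the reported ER slope of 0.5 (a linear
  one-beat map with that slope cannot rejoin within 2 ms in 2.6 beats
  from a +50 ms displacement).
* Under G_Ks −60 % or G_CaL +90 % at CL 350 ms, a missing beat drives
  this implementation into *sustained 2:1 block* (the post-pause AP
  outlasts the cycle and every other stimulus falls on a refractory
  membrane) rather than sustained 1:1 APD alternans.  The outcome sits on
  a capture knife-edge: raising the stimulus to ~3× threshold converts
  the block into large 1:1 alternans.  Any beat-to-beat variable pacing
  (periodic at any tested ω, or random) breaks the block within a few
  beats while constant pacing never does — the stabilization-by-
  variability phenomenon is reproduced, but without the ω-selectivity
  reported for alternans quenching.
* Sustained period-doubling under constant pacing appears at CL ≈ 225 ms
  (downward scan, 5 ms steps, 240 beats per CL); alternans seen near
  onset with ~200-beat conditioning decays within 500 beats at the same
  CL, so the onset depends on the observation horizon.
* Single cell only: no electrotonic load, no tissue-level APD smoothing,
  no β-adrenergic modulation; conclusions about anti-arrhythmic pacing
  transfer to tissue only qualitatively.

## Problem sizes

Standard profile: 300-beat conditioning; 250-beat dynamic trains with 50
discarded; 20 drop positions × 5 seeds for random-pacing recovery; 240
beats per CL in the period-doubling scan.  The full suite runs in a few
minutes on one core; `scripts/acceptance.py` recomputes every headline
number in ≈ 2 minutes.
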