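"""Pace the ventricular cell at a constant cycle length and read off APDs.

Conditions the epicardial TP06 myocyte at CL = 350 ms and prints the
steady action-potential duration (APD, upstroke to -60 mV) and diastolic
interval (DI = CL - APD) -- the operating point all the dynamic-pacing
experiments revolve around.
"""

import numpy as np

from restidyn import ModelParams, condition

params = ModelParams()
train = condition(params, cl=350.0, n_cond=300)
apd = float(np.mean(train.apd[-20:]))

print(f"steady APD at CL 350 ms : {apd:6.1f} ms")
print(f"steady DI  (CL - APD)   : {350.0 - apd:6.1f} ms")
print(f"max dV/dt at upstroke   : {train.beats['dvdt_max'].iloc[-1]:6.0f} mV/ms")
print()
print("APD is the depolarized fraction of the cycle (systole); DI is the")
print("recovery time the next beat gets -- the lever behind restitution.")
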