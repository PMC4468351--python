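"""Reverse-correlation baseline: where linear identification fails.

Estimates a linear filter from the M-sequence response of the ODE model,
then compares its ramp predictions against the model's own output on
Poisson-noised synthetic PSTHs.
"""

import numpy as np

from chemotax.fitting import pearson_rho
from chemotax.linear_filter import estimate_filter, predict_linear
from chemotax.stimuli import RampSpec, make_msequence, make_ramp
from chemotax.synthetic import synthetic_psth
from chemotax.transduction import integrate, table_params

params = table_params("light_iff")

mseq = make_msequence([15, 50, 100, 150, 207], step=0.033, seed=0, dt=0.01)
print(f"M-sequence: {5**4} symbols, every ordered 4-tuple of 5 intensity"
      " levels exactly once")
sol = integrate(params, mseq)
filt = estimate_filter(mseq, sol.rate_trace(), window=5.0)
h = filt.h[:300]
print(f"Estimated filter is biphasic: +{h.max():.3f} at"
      f" {filt.lags[np.argmax(h)] * 1000:.0f} ms,"
      f" {h.min():.3f} at {filt.lags[np.argmin(h)]:.2f} s")

print("\nPrediction quality (Pearson rho against noisy synthetic PSTHs):")
for shape in ("exponential", "sigmoid"):
    tr = make_ramp(RampSpec(shape, 8, 8, 15, 207), dt=0.01)
    truth = integrate(params, tr)
    _, psth = synthetic_psth(truth.rate_trace(), 24, seed=3)
    lin = predict_linear(filt, tr, target_mean=float(psth.y.mean()))
    print(f"  {shape:12s} linear filter {pearson_rho(lin.y, psth.y):.3f}"
          f"   ODE model {pearson_rho(truth.y, psth.y):.3f}")
print("The filter handles the broadband sequence but misses the graded"
      " ramps: the transduction nonlinearity matters.")
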