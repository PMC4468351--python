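"""From firing rate to behaviour: the turn-probability GLM.

Simulates open-loop run ensembles driven by the fitted GLM on ODE ramp
responses, estimates the turn probability nonparametrically, refits the
GLM two ways, and compares the test model against a stimulus-only control
by bootstrap.
"""

import numpy as np

from chemotax.stimuli import RampSpec, make_ramp
from chemotax.synthetic import make_turn_ensemble
from chemotax.transduction import integrate, table_params
from chemotax.turn_model import (TurnGlmParams, bootstrap_compare,
                                 estimate_turn_probability, fit_glm,
                                 fit_glm_mle, lambda_of)

params = table_params("light_iff")
glm = TurnGlmParams.test_model()
print(f"Test GLM: logit(lambda) = {glm.gamma0} + {glm.gamma1}*y;"
      f" lambda at y=0 is {float(lambda_of(glm, 0.0)):.4f}")

suite = [("linear", 4, 4), ("linear", 8, 8), ("exponential", 8, 8),
         ("sigmoid", 8, 8)]
profiles, runs_all = [], []
for i, (shape, rise, fall) in enumerate(suite):
    sol = integrate(params, make_ramp(RampSpec(shape, rise, fall, 15, 207),
                                      tail=10.0))
    ens = make_turn_ensemble(glm, [sol.rate_trace()], 600, seed=i)
    runs_all.extend(ens)
    tp = estimate_turn_probability(ens)
    y_sm = np.convolve(sol.y, np.ones(30) / 30.0, mode="same")
    profiles.append((tp, np.interp(tp.t, sol.t, y_sm)))

ols = fit_glm(profiles)
mle = fit_glm_mle(runs_all)
print(f"\nRecovered from 600 runs/ramp:")
print(f"  profile regression  gamma0 {ols.gamma0:+.4f}  gamma1 {ols.gamma1:+.4f}")
print(f"  run-level MLE       gamma0 {mle.gamma0:+.4f}  gamma1 {mle.gamma1:+.4f}")

# bootstrap comparison against a constant-activity control
runs = [r for r in runs_all if r.duration >= 1.0]
mean_lam = float(np.mean([r.lam.mean() for r in runs]))
cmp = bootstrap_compare(runs, None,
                        lambda run: np.full(len(run.lam), mean_lam),
                        n=2000, seed=0)
print(f"\nBootstrap vs constant-activity control ({cmp.n_resamples} resamples):"
      f" p {cmp.p_report}; the rate-driven model explains the run"
      " terminations it generated.")
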