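"""Closed-loop virtual larvae in engineered light landscapes.

Runs the agent simulator on the landscape family (volcano, well, mesa,
linear hat) and prints the median run duration after crossing each rim —
the behavioural signature of offset inhibition — plus the turn-triggered
average of the predicted turn probability in the exponential gradient.
"""

import numpy as np

from chemotax.synthetic import (AgentConfig, make_landscape,
                                post_rim_run_durations, simulate_larva)
from chemotax.transduction import table_params
from chemotax.turn_model import TurnGlmParams, turn_triggered_average

params = table_params("light_iff")
glm = TurnGlmParams.test_model()

print("Median post-rim run duration (40 agents, 90 s each):")
for profile in ("well", "volcano", "mesa", "linear_hat"):
    ls = make_landscape(profile)
    results = [simulate_larva(ls, params, glm,
                              AgentConfig(seed=1000 + s, duration=90.0))
               for s in range(40)]
    d = post_rim_run_durations(results)
    print(f"  {profile:10s} {np.median(d):4.2f} s  ({len(d)} entering runs)")
print("An abrupt fall (well) truncates runs; sustained or rising light"
      " (mesa, linear hat) elongates them.")

ls = make_landscape("exponential", half_size=60.0)
results = [simulate_larva(ls, params, glm,
                          AgentConfig(seed=100 + s, duration=120.0,
                                      start_distance=9.6))
           for s in range(20)]
runs = [r for res in results for r in res.runs
        if r.duration >= 1.0 and r.turn_terminal]
tta = turn_triggered_average(runs, lookback=5.0)
i3 = np.argmin(np.abs(tta.lags + 3.0))
print(f"\nExponential gradient: turn-triggered average of predicted lambda"
      f" rises from {tta.mean[i3]:.3f} (3 s before the turn) to"
      f" {tta.mean[-1]:.3f} at turn onset over {len(runs)} runs —"
      " turns follow drops in predicted OSN activity.")
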