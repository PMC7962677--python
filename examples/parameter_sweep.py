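"""Effect-size robustness to the detector's parameters.

Re-runs detection over a grid of (mindur, vfac) settings and prints the
effect size per cell: if the pre/post difference is real, it should stay
positive across reasonable settings, not just at the defaults.
"""

import numpy as np

from microsaccades import SimulationConfig, parameter_sweep, simulate_study

config = SimulationConfig(n_participants=6, n_trials_per_session=10, seed=5)
dataset, _ = simulate_study(config)

surface = parameter_sweep(dataset.trials, dataset.trial_duration,
                          mindur_values=[4, 6, 8], vfac_values=[4.0, 5.0, 6.0])

print("Cohen's d (pooled) by detection parameters:")
print("            " + "  ".join(f"vfac={v:g}" for v in surface.vfac_values))
for i, md in enumerate(surface.mindur_values):
    cells = "  ".join(f"{surface.d[i, j]:+.3f}" for j in range(surface.d.shape[1]))
    print(f"mindur={md:2d}  {cells}")
print(f"excluded trials anywhere on the grid: {surface.n_excluded_trials.sum()}")
# every cell positive -> the simulated rate reduction is not an artifact of
# one particular detector setting
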