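"""Pre/post session statistics on a simulated study.

Per-trial binocular counts become events/s rates; participant means feed a
paired t-test, three Cohen's d variants and the pre/post correlation that
measures how trait-like the microsaccade rate is.
"""

from microsaccades import (DetectionParams, SimulationConfig, analyze_study,
                           counts_frame, detect_dataset, simulate_study)

config = SimulationConfig(n_participants=10, n_trials_per_session=20, seed=3)
dataset, _ = simulate_study(config)
counts = counts_frame(detect_dataset(dataset.trials, DetectionParams()))
res = analyze_study(counts, dataset.trial_duration)

print(f"pre  mean rate: {res.pre_mean:.3f} events/s (sd {res.pre_sd:.3f})")
print(f"post mean rate: {res.post_mean:.3f} events/s (sd {res.post_sd:.3f})")
print(f"paired t({res.dof}) = {res.t_statistic:.3f}, p = {res.p_value:.2g}")
for variant, d in res.d_all_variants.items():
    print(f"Cohen's d [{variant}]: {d:.3f}")
print(f"pre/post Pearson r = {res.pearson_r:.3f} (p = {res.r_p_value:.2g})")
# a positive t/d reflects the simulated post-session rate reduction
# (multiplier 0.85); the high r is the stable per-participant base rate
# showing through both sessions
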