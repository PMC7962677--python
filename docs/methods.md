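# Methods

## Detection model

Gaze velocity is estimated with a smoothing moving-average differentiator.
For the default 5-sample window the interior estimate is

    v[n] = (p[n+2] + p[n+1] − p[n−1] − p[n−2]) / (6·Δt),

exact on affine signals; samples one step from an edge fall back to the
central difference and the first/last samples get velocity 0. The robust
per-component velocity spread is `σ = sqrt(median(v²) − median(v)²)` —
insensitive to the heavy tails saccades put into the velocity distribution —
and a sample is suprathreshold when `(vx/ηx)² + (vy/ηy)² > 1` with
`η = vfac·σ`. Maximal suprathreshold runs of at least `mindur` samples are
monocular events (optionally merged across gaps of `merge_gap` subthreshold
samples first; default 0, i.e. no overshoot merging — the convention is
explicit so it is testable). Thresholds are estimated per trial and per eye,
keeping trials independent, which the trial-count bootstrap requires.

Binocular pairing is greedy in onset order with each monocular event used at
most once: a left and right event pair when their inclusive index intervals
share at least `min_overlap` (default 1) samples. The binocular event spans
the union interval and takes its kinematics from the eye with the larger
peak velocity. The per-trial count used downstream is the binocular count by
default (`count_mode="mean_LR"` averages the monocular counts instead).
Event amplitude is the component-wise extent
`hypot(max(x)−min(x), max(y)−min(y))` over the interval, ≥ the net
displacement `hypot(dx, dy)` when trajectories overshoot.

Degenerate trials — velocity spread below 1e-10 °/s in any component, i.e. a
frozen or dropped-out signal — are flagged excluded and skipped by every
downstream mean, never silently counted as zero events. Events overlapping
invalid (blink/dropout) samples are discarded; invalid runs are first padded
by 10 samples (20 ms at 500 Hz) on each side to suppress lens-slip velocity
artifacts at blink edges. The padding length is this package's convention;
eye-tracking reports rarely state one.

## Statistics

Analysis units are rates (events/s), not raw counts, so results are
comparable across trial durations. Participant session means feed:

* the paired t-test `t = mean(d)/(sd(d)/√n)`, `d = pre − post`, two-sided p,
* Cohen's d in three paired-design variants — `pooled`
  (`Δmean / sqrt((sd_pre² + sd_post²)/2)`), `pre_sd` (`Δmean / sd_pre`) and
  `dz` (`mean(d)/sd(d)`, with `dz·√n = t` exactly). Published studies often
  do not say which variant a printed d is; all three are therefore computed
  and reported everywhere, with `pooled` as the default.
* the pre/post Pearson correlation (two-sided p via the t transform), the
  stability/trait-ness measure. It requires ≥ 3 participants.

The t and r computations are delegated to scipy.stats; the test suite checks
them against hand-written brute-force formulas.

## Sensitivity analyses

**Parameter sweep.** The effect size is recomputed over the grid
mindur ∈ {2..11} samples × vfac ∈ {3..8}. Both parameters change which
samples form events, so detection is re-run from raw samples in every cell —
no caching of threshold crossings is sound. Cells where the statistic is
undefined (all trials excluded, or no events anywhere so session means have
zero variance) are reported as missing (NaN), not zero.

**Trial-count bootstrap.** For each k in 3..60 and each of `n_boot`
replicates, k trials are drawn *with replacement, independently for every
participant and session*; participant mean rates and then d and r across
participants are recomputed (both statistics from the same draws), and per-k
percentile 2.5/97.5 ranges are reported. Resampling trials within
participant answers "what if we had collected fewer trials"; participants
are deliberately not resampled, which would conflate between-participant
variance with the trial-count question. Percentile intervals (no BCa
correction) keep the construction minimal. The generator stream is pinned
and documented (single `default_rng(seed)`; per k, per replicate, per
participant: one pre draw then one post draw) so replicates can be
enumerated by hand; degenerate replicates are redrawn from the same stream
and counted.

## Simulator

The generator emulates the target study regime: 22 participants × 2 sessions
× 60 trials of 5.5 s at 500 Hz binocular sampling. Its defaults are the
study conditions, not free knobs:

| parameter | default | rationale |
|---|---|---|
| base_rate_mean / sd | 1.4 / 0.45 events/s | center and between-participant spread of typical fixation microsaccade rates |
| post_rate_multiplier | 0.85 | ≈ the 1.18/1.40 pre→post rate ratio a caffeine manipulation produces |
| within_trial_rate_jitter_sd | 0.3 events/s | within-participant trial-to-trial variance beyond Poisson counting noise, needed for a non-trivial bootstrap |
| refractory_interval | 0.15 s | hard dead time giving realistic inter-event gaps at 1–2/s |
| amplitude_log_mean / log_sd | log 0.5 / 0.35 | lognormal amplitudes with median 0.5°, bulk 0.25–1°, the conventional microsaccade range; no published per-participant amplitude distribution was available to fit |
| main_sequence_slope | 120 (°/s)/° | linear main sequence; with the raised-cosine pulse this fixes the pulse duration at 2/slope ≈ 17 ms, inside the canonical 6–25 ms |
| drift_sd / mean_reversion | 0.05° / 5 s⁻¹ | stationary Ornstein–Uhlenbeck drift: bounded wandering that mimics maintained fixation over 5.5 s (a pure random walk would leave the target) |
| noise_sd | 0.01° | per-eye sensor noise typical of a video tracker at 500 Hz |
| blink_probability_per_trial | 0.02 | occasional 50–150 ms invalid runs in both eyes |

Microsaccade onsets are a homogeneous Poisson process with a hard refractory
interval, realised as a renewal process with gaps `τ + Exp(λ)` where
`λ = r/(1 − r·τ)` compensates the dead time so the realised rate equals the
configured rate (verified against an independent Monte-Carlo oracle in the
tests). A configured rate of exactly zero produces no events regardless of
jitter — jitter modulates a rate, it does not create one. Each event is a
raised-cosine velocity pulse (total displacement = amplitude, peak velocity
= slope·amplitude, duration rounded to samples and clamped to ≥ 3);
displacement is identical in the two eyes (disconjugacy is out of scope),
noise is independent per eye.

Randomness: one root seed; participant-level draws use
`SeedSequence(seed, spawn_key=(p,))` and trial-level draws
`SeedSequence(seed, spawn_key=(p, session, trial))`, so any subset of the
study reproduces bit-identically regardless of how many participants are
simulated.

**What the simulator does not emulate.** Real drift is not Gaussian-OU,
real microsaccade durations scale (weakly) with amplitude whereas the
raised-cosine + linear-main-sequence combination makes all pulses ≈ 17 ms
(8–9 samples at 500 Hz), there is no pursuit, no square-wave jerks, no
saccadic overshoot and no pupil signal, and the post-session effect is a
deterministic multiplier rather than a participant-varying response (so
simulated t statistics and correlations tend to exceed what a real
manipulation yields). Passing tests therefore validate the pipeline's
correctness and its sensitivity behaviour, not detector performance on any
particular tracker's noise. The constant pulse duration also means the two
most conservative sweep rows (mindur 10–11) can detect nothing and come out
missing — consistent with effect collapse at the "most conservative"
parameter corner.

## Numerical and design notes

* Coordinates reaching the detector are always degrees; pixel input is
  converted with the exact per-axis arctangent of (offset_mm /
  viewing_distance) about the screen centre (y flipped to point upward).
* Sample indexing is 0-based with inclusive event intervals;
  duration = (offset − onset + 1)/fs.
* Malformed numeric cells in a samples table invalidate that sample for the
  affected eye (positions are forward-filled only to keep velocity finite;
  events touching such samples are discarded).
* Problem sizes in the default test run and the acceptance script — full
  study regime for single runs, 20 replicates for recovery checks,
  n_boot = 200–300 for bootstrap checks — were chosen so each check has
  clear statistical resolution while the whole suite stays quick.
* The examples print real output; the README's worked example is pasted
  from a run of `examples/session_statistics.py`.
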