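"""Sensitivity analyses: detection-parameter surfaces and trial-count bootstrap.

Two questions about robustness:

1. Does the pre/post effect size depend on the detector settings?
   :func:`parameter_sweep` re-runs the *entire* detection from raw samples
   for every (mindur, vfac) grid cell — both parameters change which
   samples form events, so nothing short of full re-detection is sound —
   and records the effect size per cell.

2. How many trials per session would have sufficed?  For each trial count
   ``k``, :func:`bootstrap_trial_curves` resamples ``k`` trials with
   replacement independently per participant and session, recomputes the
   effect size and the pre/post correlation across participants, and
   reports percentile 95% confidence ranges over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import DetectionParams, detect_dataset
from .io import GazeTrial
from .stats import (ZeroVarianceError, cohens_d, counts_frame, pearson_r,
                    session_means, summarize_sessions)

DEFAULT_MINDUR_RANGE = tuple(range(2, 12))       # samples
DEFAULT_VFAC_RANGE = tuple(range(3, 9))          # dimensionless
MAX_REDRAWS_PER_REPLICATE = 100


@dataclass
class EffectSurface:
    """Effect size over the detection-parameter grid."""

    mindur_values: np.ndarray
    vfac_values: np.ndarray
    d: np.ndarray                 # shape (len(mindur), len(vfac)), NaN = missing
    n_excluded_trials: np.ndarray
    d_variant: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, md in enumerate(self.mindur_values):
            for j, vf in enumerate(self.vfac_values):
                rows.append({"mindur": int(md), "vfac": float(vf),
                             "d": self.d[i, j],
                             "n_excluded": int(self.n_excluded_trials[i, j])})
        return pd.DataFrame(rows)


@dataclass
class BootstrapCurve:
    """Per-k bootstrap mean and percentile 95% range of one statistic."""

    statistic: str                # "effect_size" or "correlation"
    k_values: np.ndarray
    mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_boot: int
    seed: int
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "statistic": self.statistic, "k": self.k_values,
            "mean": self.mean, "lo95": self.lo95, "hi95": self.hi95,
        })


def parameter_sweep(
    trials: Sequence[GazeTrial],
    trial_duration: float,
    mindur_values: Sequence[int] = DEFAULT_MINDUR_RANGE,
    vfac_values: Sequence[float] = DEFAULT_VFAC_RANGE,
    d_variant: str = "pooled",
    base_params: DetectionParams | None = None,
) -> EffectSurface:
    """Effect size of the pre/post contrast for every (mindur, vfac) cell.

    Detection is re-run on every trial for every cell.  Cells where the
    statistic cannot be computed (all trials excluded, zero variance) are
    marked NaN rather than zero.
    """
    base = base_params or DetectionParams()
    mindur_values = np.asarray(list(mindur_values), dtype=int)
    vfac_values = np.asarray(list(vfac_values), dtype=float)
    d = np.full((len(mindur_values), len(vfac_values)), np.nan)
    n_excl = np.zeros_like(d, dtype=int)
    for i, md in enumerate(mindur_values):
        for j, vf in enumerate(vfac_values):
            params = replace(base, mindur=int(md), vfac=float(vf))
            detections = detect_dataset(trials, params)
            counts = counts_frame(detections, base.count_mode)
            n_excl[i, j] = int(counts["excluded"].sum())
            try:
                pre, post = session_means(
                    summarize_sessions(counts, trial_duration))
                d[i, j] = cohens_d(pre, post, d_variant)
            except (ValueError, ZeroVarianceError):
                pass   # cell stays NaN (missing, not zero)
    return EffectSurface(mindur_values, vfac_values, d, n_excl, d_variant)


def rates_by_participant(
    counts: pd.DataFrame,
    trial_duration: float,
) -> tuple[list[np.ndarray], list[np.ndarray], list[str]]:
    """Per-trial rate arrays (pre, post) per participant, exclusions dropped."""
    df = counts.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df = df[~df["excluded"]]
    pids = sorted(df["participant_id"].unique())
    pre, post = [], []
    for pid in pids:
        sub = df[df["participant_id"] == pid]
        for session, dest in (("pre", pre), ("post", post)):
            rows = sub[sub["session"] == session].sort_values("trial_index")
            if rows.empty:
                raise ValueError(f"participant {pid} has no usable {session} trials")
            dest.append(rows["n_events"].to_numpy(float) / trial_duration)
    return pre, post, pids


def bootstrap_trial_curves(
    pre_rates: Sequence[np.ndarray],
    post_rates: Sequence[np.ndarray],
    k_range: Sequence[int] = tuple(range(3, 61)),
    n_boot: int = 1000,
    seed: int = 0,
    d_variant: str = "pooled",
) -> tuple[BootstrapCurve, BootstrapCurve]:
    """Bootstrap sensitivity of effect size and correlation to trial count.

    For each ``k`` and each of ``n_boot`` replicates, ``k`` trials are drawn
    with replacement — independently for every participant and session —
    participants' mean rates are recomputed, and the effect size and
    pre/post Pearson correlation are evaluated across participants.  Both
    statistics come from the same replicate draws.

    Generator stream (documented so replicates can be enumerated by hand):
    a single ``numpy.random.default_rng(seed)``; for each k in the order
    given, then each replicate, then each participant in order, one
    ``rng.integers(0, n_pre_trials, size=k)`` draw for the pre session
    followed by one ``rng.integers(0, n_post_trials, size=k)`` draw for the
    post session.  A degenerate replicate (zero-variance statistic) is
    redrawn from the same stream; redraws are counted in ``n_redrawn``.
    """
    if len(pre_rates) != len(post_rates) or len(pre_rates) < 2:
        raise ValueError("need pre and post rates for the same >= 2 participants")
    k_values = np.asarray(list(k_range), dtype=int)
    if (k_values < 3).any():
        raise ValueError("k must be >= 3")
    rng = np.random.default_rng(seed)
    n_p = len(pre_rates)
    d_stats = np.empty((len(k_values), n_boot))
    r_stats = np.empty((len(k_values), n_boot))
    n_redrawn = 0
    for ki, k in enumerate(k_values):
        for b in range(n_boot):
            for attempt in range(MAX_REDRAWS_PER_REPLICATE):
                pre_means = np.empty(n_p)
                post_means = np.empty(n_p)
                for p in range(n_p):
                    idx = rng.integers(0, len(pre_rates[p]), size=k)
                    pre_means[p] = pre_rates[p][idx].mean()
                    idx = rng.integers(0, len(post_rates[p]), size=k)
                    post_means[p] = post_rates[p][idx].mean()
                try:
                    d_stats[ki, b] = cohens_d(pre_means, post_means, d_variant)
                    r_stats[ki, b] = pearson_r(pre_means, post_means)[0]
                    break
                except ZeroVarianceError:
                    n_redrawn += 1
            else:
                raise ZeroVarianceError(
                    f"could not draw a non-degenerate replicate at k={k}")
    def curve(stat_name: str, values: np.ndarray) -> BootstrapCurve:
        return BootstrapCurve(
            statistic=stat_name, k_values=k_values,
            mean=values.mean(axis=1),
            lo95=np.percentile(values, 2.5, axis=1),
            hi95=np.percentile(values, 97.5, axis=1),
            n_boot=n_boot, seed=seed, n_redrawn=n_redrawn,
        )
    return curve("effect_size", d_stats), curve("correlation", r_stats)
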