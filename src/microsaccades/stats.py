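"""Session-level statistics: rates, paired test, effect sizes, stability.

Per-trial microsaccade counts become per-second rates, rates are averaged
within participant and session, and the pre/post contrast is summarised by
a paired t-test, a standardised effect size (three paired-design variants)
and the pre/post Pearson correlation that quantifies how trait-like the
measure is.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SESSIONS

D_VARIANTS = ("pooled", "pre_sd", "dz")


class ZeroVarianceError(ValueError):
    """A statistic's denominator is exactly zero (degenerate input)."""


@dataclass
class SessionSummary:
    participant_id: str
    session: str
    n_trials_used: int
    mean_rate: float                 # events/s
    per_trial_rates: np.ndarray      # events/s, excluded trials omitted


@dataclass
class StudyResult:
    """The headline pre/post comparison across participants."""

    pre_mean: float
    post_mean: float
    pre_sd: float
    post_sd: float
    t_statistic: float
    dof: int
    p_value: float
    cohens_d: float
    d_variant: str
    d_all_variants: dict[str, float]
    pearson_r: float
    r_p_value: float
    n_participants: int


def trial_rate(n_events: float, trial_duration: float) -> float:
    """Events per second for one trial."""
    if trial_duration <= 0:
        raise ValueError("trial_duration must be > 0")
    return n_events / trial_duration


def counts_frame(detections, mode: str = "BIN") -> pd.DataFrame:
    """Per-trial counts table from TrialDetection objects.

    Columns: participant_id, session, trial_index, n_events, excluded.
    """
    rows = []
    for det in detections:
        pid, session, idx = det.trial.key()
        rows.append({
            "participant_id": pid, "session": session, "trial_index": idx,
            "n_events": np.nan if det.excluded else det.count(mode),
            "excluded": det.excluded,
        })
    return pd.DataFrame(rows)


def summarize_sessions(
    counts: pd.DataFrame,
    trial_duration: float,
) -> list[SessionSummary]:
    """Participant x session mean rates from a per-trial counts table.

    ``counts`` needs columns participant_id, session, trial_index, n_events
    and optionally a boolean ``excluded`` column; excluded trials are left
    out of the mean.  Every participant must have both sessions.
    """
    df = counts.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    summaries: list[SessionSummary] = []
    for pid in sorted(df["participant_id"].unique()):
        sub = df[df["participant_id"] == pid]
        present = set(sub["session"])
        if not set(SESSIONS) <= present:
            missing = sorted(set(SESSIONS) - present)
            raise ValueError(f"participant {pid} missing session(s): {missing}")
        for session in SESSIONS:
            rows = sub[(sub["session"] == session) & (~sub["excluded"])]
            rows = rows.sort_values("trial_index")
            rates = np.array([trial_rate(c, trial_duration)
                              for c in rows["n_events"]])
            summaries.append(SessionSummary(
                participant_id=pid, session=session,
                n_trials_used=len(rates),
                mean_rate=float(rates.mean()) if len(rates) else float("nan"),
                per_trial_rates=rates,
            ))
    return summaries


def session_means(summaries: Sequence[SessionSummary]) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (pre, post) per-participant mean-rate vectors."""
    pre = {s.participant_id: s.mean_rate for s in summaries if s.session == "pre"}
    post = {s.participant_id: s.mean_rate for s in summaries if s.session == "post"}
    pids = sorted(pre)
    if sorted(post) != pids:
        raise ValueError("pre/post participant sets differ")
    return (np.array([pre[p] for p in pids]),
            np.array([post[p] for p in pids]))


def paired_t(pre: np.ndarray, post: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test on per-participant means.

    Returns ``(t, dof, p)`` with ``t = mean(d) / (sd(d)/sqrt(n))`` for
    ``d = pre - post`` (sample sd, n-1 denominator).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diff = pre - post
    if np.std(diff, ddof=1) == 0:
        raise ZeroVarianceError("zero variance of paired differences")
    res = sps.ttest_rel(pre, post)
    return float(res.statistic), pre.size - 1, float(res.pvalue)


def cohens_d(pre: np.ndarray, post: np.ndarray, variant: str = "pooled") -> float:
    """Standardised pre-post mean difference.

    Variants (all sds use the n-1 denominator):

    * ``pooled`` — (mean(pre) - mean(post)) / sqrt((sd(pre)^2 + sd(post)^2)/2)
    * ``pre_sd`` — divide by sd(pre) only
    * ``dz`` — mean(pre - post) / sd(pre - post); note dz * sqrt(n) equals
      the paired t statistic exactly
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    num = pre.mean() - post.mean()
    if variant == "pooled":
        denom = np.sqrt((np.var(pre, ddof=1) + np.var(post, ddof=1)) / 2.0)
    elif variant == "pre_sd":
        denom = np.std(pre, ddof=1)
    elif variant == "dz":
        num = (pre - post).mean()
        denom = np.std(pre - post, ddof=1)
    else:
        raise ValueError(f"unknown Cohen's d variant {variant!r}")
    if denom == 0:
        raise ZeroVarianceError(f"zero denominator for Cohen's d ({variant})")
    return float(num / denom)


def pearson_r(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(a, ddof=1) == 0 or np.std(b, ddof=1) == 0:
        raise ZeroVarianceError("zero variance input to correlation")
    res = sps.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def analyze_study(
    counts: pd.DataFrame,
    trial_duration: float,
    d_variant: str = "pooled",
) -> StudyResult:
    """Full pre/post study summary from a per-trial counts table."""
    summaries = summarize_sessions(counts, trial_duration)
    pre, post = session_means(summaries)
    t, dof, p = paired_t(pre, post)
    d_all = {v: cohens_d(pre, post, v) for v in D_VARIANTS}
    r, rp = pearson_r(pre, post)
    return StudyResult(
        pre_mean=float(pre.mean()), post_mean=float(post.mean()),
        pre_sd=float(np.std(pre, ddof=1)), post_sd=float(np.std(post, ddof=1)),
        t_statistic=t, dof=dof, p_value=p,
        cohens_d=d_all[d_variant], d_variant=d_variant, d_all_variants=d_all,
        pearson_r=r, r_p_value=rp, n_participants=int(pre.size),
    )


def trial_timecourse(counts: pd.DataFrame, trial_duration: float) -> pd.DataFrame:
    """Mean rate per trial index and session, averaged over participants.

    Excluded trials are skipped.  Returns a table with columns
    trial_index, session, mean_rate, n_participants.
    """
    df = counts.copy()
    if "excluded" not in df.columns:
        df["excluded"] = False
    df = df[~df["excluded"]].copy()
    df["rate"] = df["n_events"] / float(trial_duration)
    out = (df.groupby(["trial_index", "session"], sort=True)["rate"]
             .agg(mean_rate="mean", n_participants="count")
             .reset_index())
    return out
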