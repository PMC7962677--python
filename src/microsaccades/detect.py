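"""Binocular microsaccade detection by median-based velocity thresholding.

The detector follows the standard fixational-eye-movement algorithm of
Engbert & Kliegl: gaze velocity is computed with a smoothing moving-average
differentiator, a robust per-trial velocity spread is estimated from medians
(``sigma = sqrt(median(v^2) - median(v)^2)``), and samples whose velocity
vector leaves the ellipse with semi-axes ``vfac * sigma`` are candidate
microsaccade samples.  Maximal runs of at least ``mindur`` consecutive
candidate samples become monocular events; left- and right-eye events that
overlap in time are paired into binocular events, which are the count unit
used by the downstream statistics.

All parameters the sensitivity analysis sweeps (``vfac``, ``mindur``) are
explicit fields of :class:`DetectionParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import GazeTrial

#: below this velocity spread (deg/s) a trial is considered degenerate
#: (tracker dropout / frozen signal), excluded rather than counted as zero
SIGMA_FLOOR = 1e-10


class DegenerateTrialError(ValueError):
    """Velocity spread is numerically zero; the trial cannot be thresholded."""


@dataclass(frozen=True)
class DetectionParams:
    """Parameters of the velocity-threshold microsaccade detector.

    Attributes
    ----------
    vfac
        Velocity threshold scaling factor: the detection ellipse has
        semi-axes ``vfac * sigma`` per velocity component.
    mindur
        Minimum event duration in samples (6 samples = 12 ms at 500 Hz).
    velocity_window
        Width in samples of the moving-average velocity kernel (odd, >= 3).
    min_overlap
        Minimum number of shared samples for a left/right event pair to
        count as one binocular event.
    merge_gap
        Runs separated by at most this many subthreshold samples are merged
        before the duration test (0 = no merging).
    count_mode
        Per-trial count used downstream: "BIN" (binocular events, default)
        or "mean_LR" (average of the two monocular counts).
    """

    vfac: float = 5.0
    mindur: int = 6
    velocity_window: int = 5
    min_overlap: int = 1
    merge_gap: int = 0
    count_mode: str = "BIN"

    def __post_init__(self) -> None:
        if not self.vfac > 0:
            raise ValueError("vfac must be > 0")
        if self.mindur < 1:
            raise ValueError("mindur must be >= 1")
        if self.velocity_window < 3 or self.velocity_window % 2 == 0:
            raise ValueError("velocity_window must be an odd integer >= 3")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if self.count_mode not in ("BIN", "mean_LR"):
            raise ValueError("count_mode must be 'BIN' or 'mean_LR'")


@dataclass(frozen=True)
class MicrosaccadeEvent:
    """One detected microsaccade.

    ``onset_index``/``offset_index`` are 0-based inclusive sample indices.
    ``amplitude`` is the component-wise extent
    ``hypot(max(x)-min(x), max(y)-min(y))`` over the event interval, which
    is always >= the net displacement ``hypot(dx, dy)``.
    """

    eye: str                  # "L", "R" or "BIN"
    onset_index: int
    offset_index: int
    duration_ms: float
    peak_velocity: float      # deg/s
    dx: float                 # onset -> offset displacement, degrees
    dy: float
    amplitude: float          # degrees


@dataclass
class TrialDetection:
    """Detection output for one trial."""

    trial: GazeTrial
    events: list[MicrosaccadeEvent]
    excluded: bool = False
    exclusion_reason: str | None = None

    @property
    def left_events(self) -> list[MicrosaccadeEvent]:
        return [e for e in self.events if e.eye == "L"]

    @property
    def right_events(self) -> list[MicrosaccadeEvent]:
        return [e for e in self.events if e.eye == "R"]

    @property
    def binocular_events(self) -> list[MicrosaccadeEvent]:
        return [e for e in self.events if e.eye == "BIN"]

    def count(self, mode: str = "BIN") -> float:
        if mode == "BIN":
            return float(len(self.binocular_events))
        if mode == "mean_LR":
            return (len(self.left_events) + len(self.right_events)) / 2.0
        raise ValueError(f"unknown count mode {mode!r}")


def compute_velocity(
    x: np.ndarray,
    y: np.ndarray,
    sampling_rate: float,
    velocity_window: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed gaze velocity in deg/s.

    For a window of ``2m + 1`` samples the interior estimate is

        v[n] = sum_{k=1..m} (p[n+k] - p[n-k]) / (m * (m+1) * dt)

    which for the default 5-sample window is the familiar
    ``(p[n+2] + p[n+1] - p[n-1] - p[n-2]) / (6 dt)`` kernel, exact on
    affine signals.  Samples closer than ``m`` to an edge fall back to the
    widest symmetric window that fits; the first and last samples get
    velocity 0.
    """
    if velocity_window < 3 or velocity_window % 2 == 0:
        raise ValueError("velocity_window must be an odd integer >= 3")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < velocity_window:
        raise ValueError(
            f"series of length {n} shorter than velocity_window={velocity_window}"
        )
    m = velocity_window // 2
    dt = 1.0 / sampling_rate
    out = []
    for p in (x, y):
        v = np.zeros(n)
        # interior: full symmetric window
        acc = np.zeros(n - 2 * m)
        for k in range(1, m + 1):
            acc += p[m + k: n - m + k] - p[m - k: n - m - k]
        v[m: n - m] = acc / (m * (m + 1) * dt)
        # edges: widest symmetric window that fits (0 at the extremes)
        for i in range(1, m):
            for j in (i, n - 1 - i):
                mm = min(j, n - 1 - j)
                s = sum(p[j + k] - p[j - k] for k in range(1, mm + 1))
                v[j] = s / (mm * (mm + 1) * dt)
        out.append(v)
    return out[0], out[1]


def estimate_thresholds(
    vx: np.ndarray,
    vy: np.ndarray,
    vfac: float,
    invalid_mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Median-based elliptic velocity thresholds ``(eta_x, eta_y)`` in deg/s.

    Per component: ``sigma = sqrt(median(v^2) - median(v)^2)`` and
    ``eta = vfac * sigma``.  The median estimator is robust to the heavy
    tails that saccades induce in the velocity distribution, so the
    threshold tracks the drift/noise background.

    Raises
    ------
    DegenerateTrialError
        If either component's spread falls below the numeric floor
        (frozen or dropped-out signal).
    """
    etas = []
    for v in (vx, vy):
        v = np.asarray(v, dtype=float)
        if invalid_mask is not None:
            v = v[~np.asarray(invalid_mask, dtype=bool)]
        if v.size == 0:
            raise DegenerateTrialError("no valid samples to estimate threshold")
        var = np.median(v ** 2) - np.median(v) ** 2
        sigma = np.sqrt(max(var, 0.0))
        if sigma < SIGMA_FLOOR:
            raise DegenerateTrialError(
                f"velocity spread {sigma:g} deg/s below floor {SIGMA_FLOOR:g}"
            )
        etas.append(vfac * sigma)
    return etas[0], etas[1]


def detect_monocular(
    vx: np.ndarray,
    vy: np.ndarray,
    eta_x: float,
    eta_y: float,
    mindur: int,
    merge_gap: int = 0,
    invalid_mask: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Find suprathreshold runs -> monocular event intervals.

    A sample is suprathreshold iff ``(vx/eta_x)^2 + (vy/eta_y)^2 > 1``.
    Maximal runs of consecutive suprathreshold samples, after merging runs
    separated by at most ``merge_gap`` subthreshold samples, that last at
    least ``mindur`` samples become events.  Events overlapping any invalid
    sample are discarded.

    Returns 0-based inclusive ``(onset, offset)`` index pairs.
    """
    if not (eta_x > 0 and eta_y > 0):
        raise ValueError("thresholds must be positive")
    test = (np.asarray(vx) / eta_x) ** 2 + (np.asarray(vy) / eta_y) ** 2 > 1.0
    runs = _find_runs(test)
    if merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        for on, off in runs[1:]:
            if on - merged[-1][1] - 1 <= merge_gap:
                merged[-1] = (merged[-1][0], off)
            else:
                merged.append((on, off))
        runs = merged
    runs = [(on, off) for on, off in runs if off - on + 1 >= mindur]
    if invalid_mask is not None:
        inv = np.asarray(invalid_mask, dtype=bool)
        runs = [(on, off) for on, off in runs if not inv[on:off + 1].any()]
    return runs


def _find_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive (start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1))
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(len(mask) - 1)
    return list(zip(starts, stops))


def pair_binocular(
    left_events: Sequence[MicrosaccadeEvent],
    right_events: Sequence[MicrosaccadeEvent],
    min_overlap: int = 1,
) -> list[MicrosaccadeEvent]:
    """Pair temporally overlapping monocular events into binocular events.

    Pairing is greedy in onset order with each event used at most once: a
    left and a right event pair iff their inclusive index intervals share
    at least ``min_overlap`` samples.  The binocular event spans the union
    interval; its kinematic properties come from the eye with the larger
    peak velocity.
    """
    for evs, name in ((left_events, "left"), (right_events, "right")):
        onsets = [e.onset_index for e in evs]
        if onsets != sorted(onsets):
            raise ValueError(f"{name} events must be sorted by onset")
        if any(evs[i].offset_index >= evs[i + 1].onset_index
               for i in range(len(evs) - 1)):
            raise ValueError(f"{name} events must be non-overlapping")
    pairs: list[MicrosaccadeEvent] = []
    i = j = 0
    while i < len(left_events) and j < len(right_events):
        le, re = left_events[i], right_events[j]
        overlap = (min(le.offset_index, re.offset_index)
                   - max(le.onset_index, re.onset_index) + 1)
        if overlap >= min_overlap:
            winner = le if le.peak_velocity >= re.peak_velocity else re
            onset = min(le.onset_index, re.onset_index)
            offset = max(le.offset_index, re.offset_index)
            fs = 1000.0 * (le.offset_index - le.onset_index + 1) / le.duration_ms
            pairs.append(MicrosaccadeEvent(
                eye="BIN",
                onset_index=onset,
                offset_index=offset,
                duration_ms=(offset - onset + 1) * 1000.0 / fs,
                peak_velocity=winner.peak_velocity,
                dx=winner.dx,
                dy=winner.dy,
                amplitude=winner.amplitude,
            ))
            i += 1
            j += 1
        elif le.offset_index < re.offset_index:
            i += 1
        else:
            j += 1
    return pairs


def event_properties(
    x: np.ndarray,
    y: np.ndarray,
    vx: np.ndarray,
    vy: np.ndarray,
    onset: int,
    offset: int,
    sampling_rate: float,
    eye: str = "L",
) -> MicrosaccadeEvent:
    """Kinematic properties of the event interval [onset, offset]."""
    if not (0 <= onset <= offset < len(x)):
        raise ValueError("invalid event interval")
    sl = slice(onset, offset + 1)
    peak = float(np.max(np.hypot(vx[sl], vy[sl])))
    dx = float(x[offset] - x[onset])
    dy = float(y[offset] - y[onset])
    amplitude = float(np.hypot(np.ptp(x[sl]), np.ptp(y[sl])))
    return MicrosaccadeEvent(
        eye=eye,
        onset_index=int(onset),
        offset_index=int(offset),
        duration_ms=(offset - onset + 1) * 1000.0 / sampling_rate,
        peak_velocity=peak,
        dx=dx,
        dy=dy,
        amplitude=amplitude,
    )


def detect_trial(trial: GazeTrial, params: DetectionParams | None = None) -> TrialDetection:
    """Run the full monocular + binocular detection pipeline on one trial.

    Thresholds are estimated per trial and per eye.  Degenerate trials
    (velocity spread at the numeric floor in either eye) are flagged
    excluded rather than silently reported as zero events.
    """
    params = params or DetectionParams()
    fs = trial.sampling_rate
    per_eye: dict[str, list[MicrosaccadeEvent]] = {}
    for eye, xx, yy, valid in (
        ("L", trial.left_x, trial.left_y, trial.valid_left),
        ("R", trial.right_x, trial.right_y, trial.valid_right),
    ):
        invalid = ~np.asarray(valid, dtype=bool)
        vx, vy = compute_velocity(xx, yy, fs, params.velocity_window)
        try:
            eta_x, eta_y = estimate_thresholds(vx, vy, params.vfac, invalid)
        except DegenerateTrialError as exc:
            return TrialDetection(trial, [], excluded=True,
                                  exclusion_reason=f"{eye}: {exc}")
        runs = detect_monocular(vx, vy, eta_x, eta_y,
                                params.mindur, params.merge_gap, invalid)
        per_eye[eye] = [
            event_properties(xx, yy, vx, vy, on, off, fs, eye=eye)
            for on, off in runs
        ]
    bin_events = pair_binocular(per_eye["L"], per_eye["R"], params.min_overlap)
    return TrialDetection(trial, per_eye["L"] + per_eye["R"] + bin_events)


def detect_dataset(
    trials: Sequence[GazeTrial],
    params: DetectionParams | None = None,
) -> list[TrialDetection]:
    """Detect microsaccades in every trial (per-trial thresholds)."""
    params = params or DetectionParams()
    return [detect_trial(tr, params) for tr in trials]


def events_to_records(detections: Sequence[TrialDetection]) -> list[dict]:
    """Flatten detections into events-table rows (gaze_io schema)."""
    rows = []
    for det in detections:
        pid, session, idx = det.trial.key()
        for e in det.events:
            rows.append({
                "participant_id": pid, "session": session, "trial_index": idx,
                "eye": e.eye, "onset_idx": e.onset_index,
                "offset_idx": e.offset_index, "duration_ms": e.duration_ms,
                "peak_velocity_dps": e.peak_velocity,
                "amplitude_deg": e.amplitude, "dx_deg": e.dx, "dy_deg": e.dy,
            })
    return rows
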