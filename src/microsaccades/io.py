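"""Gaze sample / event table I/O and coordinate conversion.

The canonical interchange format is a plain tab-separated samples table with
columns ``participant_id, session, trial_index, t, xl, yl, xr, yr, valid_l,
valid_r`` (time in seconds, positions in degrees of visual angle).  Event
tables carry one detected microsaccade per row.  Positions handed to the
detector are always in degrees; pixel data must be converted first with
:func:`pixels_to_degrees` and a :class:`DisplayGeometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SESSIONS = ("pre", "post")

SAMPLES_COLUMNS = [
    "participant_id", "session", "trial_index",
    "t", "xl", "yl", "xr", "yr", "valid_l", "valid_r",
]

EVENTS_COLUMNS = [
    "participant_id", "session", "trial_index", "eye",
    "onset_idx", "offset_idx", "duration_ms", "peak_velocity_dps",
    "amplitude_deg", "dx_deg", "dy_deg",
]

#: tolerance on timestamp spacing uniformity, seconds
TIME_UNIFORMITY_TOL = 1e-6

#: default padding (samples) added around invalid runs; 20 ms at 500 Hz,
#: enough to suppress lens-slip velocity artifacts at blink edges
DEFAULT_BLINK_PAD = 10


class SchemaError(ValueError):
    """A table is missing a mandatory column or has an unusable header."""


class FormatError(ValueError):
    """Table contents violate the format contract (e.g. ragged timestamps)."""


@dataclass(frozen=True)
class DisplayGeometry:
    """Screen geometry for pixel -> degree conversion.

    Parameters
    ----------
    resolution
        Screen resolution in pixels, (width, height).
    physical_size
        Physical screen size in millimetres, (width, height).
    viewing_distance
        Eye-to-screen distance in millimetres.
    """

    resolution: tuple[int, int]
    physical_size: tuple[float, float]
    viewing_distance: float

    def __post_init__(self) -> None:
        vals = (*self.resolution, *self.physical_size, self.viewing_distance)
        if any(v <= 0 for v in vals):
            raise ValueError("all DisplayGeometry dimensions must be positive")


@dataclass
class GazeTrial:
    """One fixation trial of binocular gaze samples, positions in degrees."""

    participant_id: str
    session: str
    trial_index: int
    sampling_rate: float
    time: np.ndarray
    left_x: np.ndarray
    left_y: np.ndarray
    right_x: np.ndarray
    right_y: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def __post_init__(self) -> None:
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        arrays = [self.time, self.left_x, self.left_y, self.right_x,
                  self.right_y, self.valid_left, self.valid_right]
        n = len(self.time)
        if n < 5:
            raise ValueError("a GazeTrial needs at least 5 samples")
        if any(len(a) != n for a in arrays):
            raise ValueError("all sample arrays must have equal length")
        dt = np.diff(self.time)
        if dt.size and (np.any(dt <= 0) or np.ptp(dt) > TIME_UNIFORMITY_TOL):
            raise FormatError(
                f"non-uniform timestamps in trial "
                f"({self.participant_id}, {self.session}, {self.trial_index})"
            )
        if dt.size and abs(dt.mean() - 1.0 / self.sampling_rate) > TIME_UNIFORMITY_TOL:
            raise FormatError(
                f"timestamp spacing inconsistent with sampling_rate="
                f"{self.sampling_rate} in trial "
                f"({self.participant_id}, {self.session}, {self.trial_index})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    def key(self) -> tuple[str, str, int]:
        return (self.participant_id, self.session, self.trial_index)


def pixels_to_degrees(
    x_px: np.ndarray | float,
    y_px: np.ndarray | float,
    geometry: DisplayGeometry,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert screen pixel coordinates to degrees of visual angle.

    Positions are recentred on the screen centre; each axis is converted
    independently with the exact per-axis arctangent (no small-angle
    approximation).  x is positive rightward and y positive upward (pixel
    rows grow downward, so the y axis is flipped).
    """
    w_px, h_px = geometry.resolution
    w_mm, h_mm = geometry.physical_size
    d = geometry.viewing_distance
    x_mm = (np.asarray(x_px, dtype=float) - w_px / 2.0) * (w_mm / w_px)
    y_mm = (np.asarray(y_px, dtype=float) - h_px / 2.0) * (h_mm / h_px)
    x_deg = np.degrees(np.arctan2(x_mm, d))
    y_deg = -np.degrees(np.arctan2(y_mm, d))
    return x_deg, y_deg


def mark_invalid_runs(trial: GazeTrial, pad: int = DEFAULT_BLINK_PAD) -> GazeTrial:
    """Extend every contiguous invalid run by ``pad`` samples on both sides.

    Returns a new trial; detection later discards events overlapping any
    invalid sample, so padding suppresses velocity artifacts at the edges
    of blinks and tracker dropouts.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if pad == 0:
        return trial
    return replace(
        trial,
        valid_left=_pad_invalid(trial.valid_left, pad),
        valid_right=_pad_invalid(trial.valid_right, pad),
    )


def _pad_invalid(valid: np.ndarray, pad: int) -> np.ndarray:
    invalid = ~np.asarray(valid, dtype=bool)
    if not invalid.any():
        return np.asarray(valid, dtype=bool).copy()
    # dilate the invalid mask by `pad` samples using a sliding window
    kernel = np.ones(2 * pad + 1, dtype=bool)
    dilated = np.convolve(invalid, kernel, mode="same") > 0
    return ~dilated


def _trial_from_group(group: pd.DataFrame, sampling_rate: float) -> GazeTrial:
    group = group.sort_values("t")
    pos = {c: pd.to_numeric(group[c], errors="coerce").to_numpy(float)
           for c in ("xl", "yl", "xr", "yr")}
    valid_l = _parse_bool(group["valid_l"]) & np.isfinite(pos["xl"]) & np.isfinite(pos["yl"])
    valid_r = _parse_bool(group["valid_r"]) & np.isfinite(pos["xr"]) & np.isfinite(pos["yr"])
    # hold positions through invalid stretches so velocity math stays finite;
    # detection discards any event overlapping the invalid samples anyway
    for c in ("xl", "yl"):
        pos[c] = _fill_nonfinite(pos[c])
    for c in ("xr", "yr"):
        pos[c] = _fill_nonfinite(pos[c])
    return GazeTrial(
        participant_id=str(group["participant_id"].iloc[0]),
        session=str(group["session"].iloc[0]),
        trial_index=int(group["trial_index"].iloc[0]),
        sampling_rate=float(sampling_rate),
        time=pd.to_numeric(group["t"]).to_numpy(float),
        left_x=pos["xl"], left_y=pos["yl"],
        right_x=pos["xr"], right_y=pos["yr"],
        valid_left=valid_l, valid_right=valid_r,
    )


def _parse_bool(col: pd.Series) -> np.ndarray:
    mapped = col.map(
        {True: True, False: False, 1: True, 0: False,
         "1": True, "0": False, "True": True, "False": False,
         "true": True, "false": False}
    )
    return mapped.fillna(False).to_numpy(bool)


def _fill_nonfinite(x: np.ndarray) -> np.ndarray:
    """Forward-fill non-finite samples (backfill a leading invalid stretch)."""
    finite = np.isfinite(x)
    if finite.all():
        return x
    if not finite.any():
        return np.zeros_like(x)
    idx = np.where(finite, np.arange(len(x)), 0)
    np.maximum.accumulate(idx, out=idx)
    out = x[idx]
    first = np.flatnonzero(finite)[0]
    out[:first] = x[first]
    return out


def read_samples_table(path: str | Path, sampling_rate: float) -> list[GazeTrial]:
    """Read a tab-separated gaze samples table into a list of GazeTrials.

    Rows are grouped by (participant, session, trial) and sorted by time
    within trial.  Malformed numeric position cells mark that sample invalid
    for the affected eye; the trial is still loaded.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"samples table missing mandatory column(s): {missing}")
    trials: list[GazeTrial] = []
    if df.empty:
        return trials
    df["trial_index"] = pd.to_numeric(df["trial_index"]).astype(int)
    for _, group in df.groupby(
        ["participant_id", "session", "trial_index"], sort=True
    ):
        trials.append(_trial_from_group(group, sampling_rate))
    return trials


def write_samples_table(trials: Iterable[GazeTrial], path: str | Path) -> None:
    """Write trials to the tab-separated samples schema (degrees)."""
    frames = []
    for tr in trials:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "session": tr.session,
            "trial_index": tr.trial_index,
            "t": tr.time,
            "xl": tr.left_x, "yl": tr.left_y,
            "xr": tr.right_x, "yr": tr.right_y,
            "valid_l": tr.valid_left.astype(int),
            "valid_r": tr.valid_right.astype(int),
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=SAMPLES_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_events_table(events: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write detected events as a tab-separated table (one event per row)."""
    df = pd.DataFrame(events, columns=EVENTS_COLUMNS) if not isinstance(
        events, pd.DataFrame) else events
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"events table missing column(s): {missing}")
    df[EVENTS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_events_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"events table missing mandatory column(s): {missing}")
    return df


def write_summary(results: dict, path: str | Path) -> None:
    """Write a flat key-value summary document (YAML)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(results), fh, sort_keys=True)


def read_summary(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML stays readable."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
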