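"""Reach-deviation measures from raw 2-D hand trajectories.

The central measure is the angular deviation at the point of maximum hand
velocity: the signed angle (CCW positive) between the start-to-target line and
the start-to-hand line at the sample of peak tangential speed. Deviations are
baseline-corrected with per-target biases estimated from the aligned session
and normalized by rotation size so that 1.0 means full compensation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .config import REACH_TARGETS
from .schedule import FIRST_ALIGNED_REACHES, FIRST_ROTATED_REACHES

__all__ = [
    "ReachDeviation",
    "wrap_angle",
    "tangential_speed",
    "peak_velocity_index",
    "angular_deviation",
    "compute_reach_deviations",
    "screen_deviations",
    "baseline_biases",
    "correct_and_normalize",
    "learning_trial_sets",
    "MIN_MOVEMENT_CM",
    "MAX_ABS_DEVIATION_DEG",
]

# Automated screening thresholds (replace manual inspection).
MIN_MOVEMENT_CM = 6.0
MAX_ABS_DEVIATION_DEG = 90.0


class DegenerateTrialError(ValueError):
    """The trajectory carries no usable movement (e.g. all samples coincide)."""


class ReachDeviation(NamedTuple):
    """Angular deviation of one reach at peak velocity (deg, CCW positive)."""

    deviation_deg: float
    peak_index: int
    hand_angle_deg: float


def wrap_angle(deg):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    w = np.mod(np.asarray(deg, dtype=float), 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    return float(w) if np.isscalar(deg) or np.ndim(deg) == 0 else w


def tangential_speed(
    t_s: np.ndarray, x_cm: np.ndarray, y_cm: np.ndarray, smooth_window: int = 0
) -> np.ndarray:
    """Tangential speed at interior samples by central finite differences.

    Returns an array of length ``n - 2`` aligned to samples ``1 .. n-2``. An
    optional centred moving average (odd ``smooth_window`` > 1) is available
    for noisy recorded data; synthetic trajectories need none.
    """
    t = np.asarray(t_s, dtype=float)
    x = np.asarray(x_cm, dtype=float)
    y = np.asarray(y_cm, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("sample times must be strictly increasing")
    dt = t[2:] - t[:-2]
    vx = (x[2:] - x[:-2]) / dt
    vy = (y[2:] - y[:-2]) / dt
    speed = np.hypot(vx, vy)
    if smooth_window and smooth_window > 1:
        k = int(smooth_window) | 1  # force odd
        kernel = np.ones(k) / k
        speed = np.convolve(speed, kernel, mode="same")
    return speed


def peak_velocity_index(
    t_s: np.ndarray, x_cm: np.ndarray, y_cm: np.ndarray, smooth_window: int = 0
) -> int:
    """Sample index of maximum tangential speed; ties break to the earliest.

    Raises :class:`DegenerateTrialError` when the path carries no movement.
    """
    speed = tangential_speed(t_s, x_cm, y_cm, smooth_window)
    if not np.any(speed > 0):
        raise DegenerateTrialError("no movement detected in trajectory")
    # earliest-index tie-break, robust to float rounding of equal speeds
    peak = float(speed.max())
    first = int(np.flatnonzero(speed >= peak * (1.0 - 1e-9))[0])
    return first + 1  # speeds are defined at interior samples


def angular_deviation(
    t_s: np.ndarray,
    x_cm: np.ndarray,
    y_cm: np.ndarray,
    target_deg: float,
    smooth_window: int = 0,
) -> ReachDeviation:
    """Angular deviation at peak velocity, wrapped to (-180, 180].

    Raises :class:`DegenerateTrialError` for no-movement trials and
    ``ValueError`` when the peak-velocity sample sits at the origin.
    """
    idx = peak_velocity_index(t_s, x_cm, y_cm, smooth_window)
    x, y = float(np.asarray(x_cm)[idx]), float(np.asarray(y_cm)[idx])
    if x == 0.0 and y == 0.0:
        raise ValueError("hand at origin at peak velocity; deviation undefined")
    hand_angle = np.rad2deg(np.arctan2(y, x))
    return ReachDeviation(wrap_angle(hand_angle - target_deg), idx, hand_angle)


# ---------------------------------------------------------------------------
# Bulk trial tables
# ---------------------------------------------------------------------------

_TRIAL_KEYS = ["participant", "session", "block", "task", "strategy_cue", "trial"]
_CARRY = ["group", "instructed", "rotation_deg", "target_deg"]


def compute_reach_deviations(samples: pd.DataFrame, smooth_window: int = 0) -> pd.DataFrame:
    """Per-trial angular deviations from a long-format trajectory table.

    Expects the tidy sample schema (one row per sample; see the cohort
    module). Returns one row per trial with ``deviation_deg``, ``peak_index``,
    ``hand_angle_deg``, ``valid`` and ``exclude_reason`` (automated screening:
    degenerate trajectory, movement shorter than 6 cm, |deviation| > 90 deg).
    """
    keys = [k for k in _TRIAL_KEYS if k in samples.columns]
    carry = [c for c in _CARRY if c in samples.columns]
    rows = []
    for key, sub in samples.groupby(keys, sort=False, dropna=False):
        t = sub["t_s"].to_numpy()
        x = sub["x_cm"].to_numpy()
        y = sub["y_cm"].to_numpy()
        target = float(sub["target_deg"].iloc[0])
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        for c in carry:
            rec[c] = sub[c].iloc[0]
        rec.update(
            deviation_deg=np.nan, peak_index=-1, hand_angle_deg=np.nan,
            valid=True, exclude_reason="",
        )
        try:
            dev = angular_deviation(t, x, y, target, smooth_window)
        except (DegenerateTrialError, ValueError):
            rec["valid"] = False
            rec["exclude_reason"] = "degenerate_trajectory"
            rows.append(rec)
            continue
        rec["deviation_deg"] = dev.deviation_deg
        rec["peak_index"] = dev.peak_index
        rec["hand_angle_deg"] = dev.hand_angle_deg
        max_extent = float(np.max(np.hypot(x, y)))
        if max_extent < MIN_MOVEMENT_CM:
            rec["valid"] = False
            rec["exclude_reason"] = "short_movement"
        elif abs(dev.deviation_deg) > MAX_ABS_DEVIATION_DEG:
            rec["valid"] = False
            rec["exclude_reason"] = "large_deviation"
        rows.append(rec)
    return pd.DataFrame(rows)


def screen_deviations(devs: pd.DataFrame) -> pd.DataFrame:
    """Apply screening flags to a trial-level deviation table.

    Used when deviations arrive precomputed (no trajectories). Adds/updates
    ``valid`` and ``exclude_reason`` columns; rules mirror
    :func:`compute_reach_deviations`.
    """
    out = devs.copy()
    if "valid" not in out.columns:
        out["valid"] = True
        out["exclude_reason"] = ""
    dev = out["deviation_deg"]
    bad_nan = dev.isna() & out["valid"]
    out.loc[bad_nan, ["valid", "exclude_reason"]] = [False, "degenerate_trajectory"]
    bad_large = (dev.abs() > MAX_ABS_DEVIATION_DEG) & out["valid"]
    out.loc[bad_large, ["valid", "exclude_reason"]] = [False, "large_deviation"]
    return out


def baseline_biases(
    aligned_devs: pd.DataFrame, last_n: int = FIRST_ALIGNED_REACHES
) -> pd.DataFrame:
    """Per-participant, per-target mean deviation over the baseline window.

    ``aligned_devs`` must already be restricted to the first aligned
    reach-to-target task; the last ``last_n`` trials per participant are used
    (the first aligned set has exactly 45 trials, so by default all of them).
    Raises when a trained target is missing for a participant.
    """
    rows = []
    for pid, sub in aligned_devs.groupby("participant", sort=False):
        window = sub.sort_values("trial").tail(last_n)
        if "valid" in window.columns:
            window = window[window["valid"] != False]  # noqa: E712
        means = window.groupby("target_deg")["deviation_deg"].mean()
        for target in REACH_TARGETS:
            if target not in means.index:
                raise ValueError(
                    f"participant {pid}: no baseline trials for target {target} deg"
                )
            rows.append((pid, float(target), float(means.loc[target])))
    return pd.DataFrame(rows, columns=["participant", "target_deg", "bias_deg"])


def correct_and_normalize(
    devs: pd.DataFrame, biases: pd.DataFrame, rotation_deg: Optional[float] = None
) -> pd.DataFrame:
    """Baseline-correct deviations and normalize by rotation size.

    ``corrected_deg = deviation - bias(participant, target)`` and
    ``normalized = corrected / rotation``. Rotation is taken per row from a
    ``rotation_deg`` column unless given explicitly; zero rotation is an
    error.
    """
    merged = devs.merge(
        biases, on=["participant", "target_deg"], how="left", validate="m:1",
        suffixes=("", "_bias"),
    )
    if merged["bias_deg"].isna().any():
        missing = merged.loc[merged["bias_deg"].isna(), ["participant", "target_deg"]]
        raise ValueError(f"missing baseline bias for:\n{missing.drop_duplicates()}")
    merged["corrected_deg"] = merged["deviation_deg"] - merged["bias_deg"]
    if rotation_deg is not None:
        rot = float(rotation_deg)
        if rot == 0:
            raise ValueError("rotation_deg must be nonzero")
        merged["normalized"] = merged["corrected_deg"] / rot
    else:
        rot_col = merged["rotation_deg"].astype(float)
        if (rot_col == 0).any():
            raise ValueError("rotation_deg must be nonzero for all trials")
        merged["normalized"] = merged["corrected_deg"] / rot_col
    return merged


def learning_trial_sets(training: pd.DataFrame) -> pd.DataFrame:
    """Trial-set summaries of the first rotated training set.

    ``training`` is the corrected/normalized deviation table of the 90-trial
    first rotated reach-to-target set, ordered by ``trial``. Set 1 is trials
    1-3, set 2 trials 4-6, and the final set the last 9 trials; each summary
    is the mean corrected and normalized deviation over its window.
    """
    rows = []
    for pid, sub in training.groupby("participant", sort=False):
        sub = sub.sort_values("trial")
        if len(sub) < FIRST_ROTATED_REACHES:
            raise ValueError(
                f"participant {pid}: expected >= {FIRST_ROTATED_REACHES} "
                f"training trials, got {len(sub)}"
            )
        windows = {
            "set1": sub.iloc[0:3],
            "set2": sub.iloc[3:6],
            "final": sub.iloc[-9:],
        }
        for label, w in windows.items():
            if "valid" in w.columns:
                w = w[w["valid"] != False]  # noqa: E712
            rows.append(
                (
                    pid, sub["group"].iloc[0] if "group" in sub else "",
                    label,
                    float(w["corrected_deg"].mean()),
                    float(w["normalized"].mean()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["participant", "group", "set", "corrected_deg", "normalized"],
    )
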