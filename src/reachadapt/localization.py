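"""Hand-localization error profiles, shifts, and afferent/efferent split.

Participants choose their own hand-movement directions, so localization error
(tap angle minus true hand angle) is estimated at fixed probe angles —
50, 90 and 130 deg — by Nadaraya-Watson kernel regression with a normal
kernel (default sd 10 deg). The rotated-minus-aligned difference of these
interpolated errors, averaged over the three probe angles, is the
training-induced localization shift. Passive-movement shifts isolate the
afferent (proprioceptive) component; active minus passive isolates the
efferent (predicted-consequence) component.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import LOCALIZATION_CENTERS

__all__ = [
    "kernel_smooth",
    "localization_profiles",
    "localization_shifts",
    "decompose_shifts",
    "WEIGHT_FLOOR",
]

#: Total kernel weight below which a probe angle yields a missing estimate
#: rather than an extrapolated one.
WEIGHT_FLOOR = 1e-6


def kernel_smooth(
    hand_deg,
    error_deg,
    centers: Sequence[float] = LOCALIZATION_CENTERS,
    kernel_sd_deg: float = 10.0,
) -> np.ndarray:
    """Nadaraya-Watson estimates of localization error at given angles.

    ``estimate(c) = sum_i w_i err_i / sum_i w_i`` with normal weights
    ``w_i = exp(-(hand_i - c)^2 / (2 sd^2))``. Centers whose total weight
    falls below :data:`WEIGHT_FLOOR` return NaN. Every finite estimate is a
    convex combination of the observed errors.
    """
    hand = np.asarray(hand_deg, dtype=float)
    err = np.asarray(error_deg, dtype=float)
    if hand.size == 0:
        raise ValueError("kernel_smooth needs at least one trial")
    if hand.shape != err.shape:
        raise ValueError("hand_deg and error_deg must have the same shape")
    if kernel_sd_deg <= 0:
        raise ValueError("kernel_sd_deg must be positive")
    c = np.asarray(centers, dtype=float)
    w = np.exp(-((hand[None, :] - c[:, None]) ** 2) / (2.0 * kernel_sd_deg**2))
    total = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        est = (w @ err) / total
    est = np.where(total < WEIGHT_FLOOR, np.nan, est)
    return est


def localization_profiles(
    loc: pd.DataFrame,
    centers: Sequence[float] = LOCALIZATION_CENTERS,
    kernel_sd_deg: float = 10.0,
) -> pd.DataFrame:
    """Per participant/session/movement error estimates at the probe angles.

    ``loc`` is the tidy localization table (``hand_deg``, ``tap_deg``,
    ``movement_type`` columns). Passive trials are pooled regardless of how
    the robot chose its displacement targets. Returns one row per
    (participant, session, movement) with ``est_<angle>`` columns and their
    mean ``mean_error_deg``.
    """
    centers = tuple(float(c) for c in centers)
    rows = []
    carry = [c for c in ("group", "instructed", "rotation_deg") if c in loc.columns]
    for (pid, session, movement), sub in loc.groupby(
        ["participant", "session", "movement_type"], sort=False
    ):
        err = sub["tap_deg"].to_numpy() - sub["hand_deg"].to_numpy()
        est = kernel_smooth(sub["hand_deg"].to_numpy(), err, centers, kernel_sd_deg)
        rec = {"participant": pid, "session": session, "movement_type": movement}
        for c in carry:
            rec[c] = sub[c].iloc[0]
        for center, e in zip(centers, est):
            rec[f"est_{center:g}"] = e
        rec["mean_error_deg"] = float(np.mean(est)) if np.all(np.isfinite(est)) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def localization_shifts(profiles: pd.DataFrame) -> pd.DataFrame:
    """Rotated-minus-aligned shift per participant and movement type.

    The shift is the mean over probe angles of the center-wise differences of
    the interpolated errors. Raises when the two sessions carry mismatched
    probe-angle columns; a missing (NaN) estimate propagates to a NaN shift,
    which downstream decomposition excludes with a log entry.
    """
    est_cols = sorted(c for c in profiles.columns if c.startswith("est_"))
    if not est_cols:
        raise ValueError("profiles table has no est_* columns")
    rows = []
    carry = [c for c in ("group", "instructed", "rotation_deg") if c in profiles.columns]
    for (pid, movement), sub in profiles.groupby(
        ["participant", "movement_type"], sort=False
    ):
        by_session = {s: g for s, g in sub.groupby("session")}
        if set(by_session) != {"aligned", "rotated"}:
            raise ValueError(
                f"participant {pid} ({movement}): need exactly one aligned and "
                f"one rotated profile, got sessions {sorted(by_session)}"
            )
        aligned = by_session["aligned"][est_cols].to_numpy(dtype=float).ravel()
        rotated = by_session["rotated"][est_cols].to_numpy(dtype=float).ravel()
        rec = {
            "participant": pid,
            "movement_type": movement,
            "shift_deg": float(np.mean(rotated - aligned)),
        }
        for c in carry:
            rec[c] = sub[c].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)


def decompose_shifts(shifts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split per-participant shifts into afferent and efferent components.

    ``afferent = passive shift``; ``efferent = active - passive``; the
    identity ``afferent + efferent = active`` holds exactly by construction.
    Returns ``(decomposition, exclusions)``; participants missing either
    component (or with NaN shifts) land in ``exclusions`` with a reason.
    """
    wide = shifts.pivot_table(
        index="participant", columns="movement_type", values="shift_deg",
        aggfunc="first", dropna=False,
    )
    carry_cols = [c for c in ("group", "instructed", "rotation_deg") if c in shifts.columns]
    meta = (
        shifts.drop_duplicates("participant").set_index("participant")[carry_cols]
        if carry_cols
        else None
    )
    rows, excluded = [], []
    for pid in wide.index:
        active = wide.at[pid, "active"] if "active" in wide.columns else np.nan
        passive = wide.at[pid, "passive"] if "passive" in wide.columns else np.nan
        if not (np.isfinite(active) and np.isfinite(passive)):
            missing = []
            if not np.isfinite(active):
                missing.append("active")
            if not np.isfinite(passive):
                missing.append("passive")
            excluded.append((pid, "missing_" + "_".join(missing)))
            continue
        rec = {
            "participant": pid,
            "active_shift_deg": float(active),
            "afferent_shift_deg": float(passive),
            "efferent_shift_deg": float(active) - float(passive),
        }
        if meta is not None:
            for c in carry_cols:
                rec[c] = meta.at[pid, c]
        rows.append(rec)
    return (
        pd.DataFrame(rows),
        pd.DataFrame(excluded, columns=["participant", "reason"]),
    )
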