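"""Synthetic cohorts for visuomotor rotation adaptation.

Generates complete participants — reach trajectories, no-cursor reaches,
active/passive hand-localization taps and awareness-questionnaire scores —
with the statistical structure the downstream analysis assumes, so that every
stage of the pipeline can be validated by parameter recovery.

Model
-----
Learning is a single implicit state ``u`` (deg, CCW positive) updated after
every cursor-feedback trial of the rotated session::

    u' = A * u + B * (-visual_error),   visual_error = hand_deviation - r

where ``r`` is the CW rotation magnitude and ``A``/``B`` are retention and
learning rate. Aware participants additionally adopt a constant explicit
strategy ``e = strategy_frac * r`` at rotation onset, applied during cursor
training and during no-cursor reaches cued "with strategy". Proprioceptive
recalibration (afferent) and predicted-consequence (efferent) shifts are
injected into rotated-session localization taps in the CW (negative)
direction; active taps receive afferent + efferent, passive taps afferent
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import (
    LOCALIZATION_CENTERS,
    REACH_TARGETS,
    TARGET_DISTANCE_CM,
    SimulationConfig,
)
from .schedule import ScheduleEntry, build_schedule

__all__ = [
    "AdaptationState",
    "TrajectoryTrial",
    "LocalizationTrial",
    "ParticipantRecord",
    "Cohort",
    "update_state",
    "implicit_closed_form",
    "min_jerk_profile",
    "simulate_reach",
    "simulate_localization",
    "simulate_participant",
    "simulate_cohort",
    "AWARENESS_PMF",
]


# ---------------------------------------------------------------------------
# Learning state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdaptationState:
    """Hidden learning state: implicit adaptation plus explicit strategy."""

    implicit_deg: float = 0.0
    explicit_deg: float = 0.0
    trial_index: int = 0


def update_state(
    state: AdaptationState, visual_error_deg: float, cfg: SimulationConfig
) -> AdaptationState:
    """One error-driven update of the implicit state.

    ``visual_error_deg`` is the cursor error (hand deviation minus rotation,
    CCW positive); the explicit strategy is untouched — it is set once per
    group at rotation onset.
    """
    new_implicit = (
        cfg.retention_A * state.implicit_deg
        + cfg.learn_rate_B * (-visual_error_deg)
    )
    return AdaptationState(new_implicit, state.explicit_deg, state.trial_index + 1)


def implicit_closed_form(
    n_trials: int, cfg: SimulationConfig, explicit_deg: float = 0.0
) -> float:
    """Noise-free implicit state after ``n_trials`` cursor trials.

    With constant explicit strategy ``e`` the recursion
    ``u' = (A - B) u + B (r - e)`` gives
    ``u_n = B (r - e) * sum_{k<n} (A - B)^k``.
    """
    a, b = cfg.retention_A, cfg.learn_rate_B
    drive = b * (cfg.rotation_deg - explicit_deg)
    rho = a - b
    if abs(1.0 - rho) < 1e-15:
        return drive * n_trials
    return drive * (1.0 - rho**n_trials) / (1.0 - rho)


def implicit_asymptote(cfg: SimulationConfig, explicit_deg: float = 0.0) -> float:
    """Fixed point of the noise-free implicit recursion."""
    a, b = cfg.retention_A, cfg.learn_rate_B
    denom = 1.0 - a + b
    if denom <= 0:
        return float("inf")
    return b * (cfg.rotation_deg - explicit_deg) / denom


# ---------------------------------------------------------------------------
# Single-trial primitives
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryTrial:
    """One reach: time-stamped 2-D hand path plus task metadata."""

    session: str
    task: str
    target_deg: float
    t_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    strategy_cue: Optional[str] = None
    rotation_deg: float = 0.0
    participant: Optional[str] = None


@dataclass
class LocalizationTrial:
    """One localization probe: hand endpoint angle and touchscreen tap angle."""

    session: str
    movement: str  # "active" | "passive"
    hand_deg: float
    tap_deg: float
    participant: Optional[str] = None


def min_jerk_profile(duration_s: float, sample_rate_hz: float):
    """Times and radial path fraction of a minimum-jerk point-to-point reach.

    The speed profile is bell-shaped with its unique maximum at mid-movement.
    """
    if duration_s <= 0 or sample_rate_hz <= 0:
        raise ValueError("duration and sample rate must be positive")
    n = int(round(duration_s * sample_rate_hz)) + 1
    if n < 3:
        raise ValueError("sampling too coarse: fewer than 3 samples per reach")
    t = np.arange(n) / sample_rate_hz
    tau = np.clip(t / duration_s, 0.0, 1.0)
    frac = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return t, frac


def simulate_reach(
    aim_deg: float,
    target_deg: float,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    session: str = "aligned",
    task: str = "reach_target",
) -> TrajectoryTrial:
    """Sample a minimum-jerk reach of 12 cm along ``aim_deg`` plus motor noise.

    ``aim_deg`` is the intended movement direction (already including any
    internal state); a motor-noise draw is added when an rng is supplied.
    """
    if not np.isfinite(aim_deg):
        raise ValueError("aim_deg must be finite")
    actual = float(aim_deg)
    if rng is not None and cfg.motor_noise_sd_deg > 0:
        actual += rng.normal(0.0, cfg.motor_noise_sd_deg)
    t, frac = min_jerk_profile(cfg.reach_duration_s, cfg.sample_rate_hz)
    r = TARGET_DISTANCE_CM * frac
    theta = np.deg2rad(actual)
    return TrajectoryTrial(
        session=session,
        task=task,
        target_deg=float(target_deg),
        t_s=t,
        x_cm=r * np.cos(theta),
        y_cm=r * np.sin(theta),
        rotation_deg=cfg.rotation_deg if session == "rotated" else 0.0,
    )


def localization_shift_deg(movement: str, session: str, cfg: SimulationConfig) -> float:
    """Injected tap shift for a localization trial (CW shifts are negative)."""
    if session == "aligned":
        return 0.0
    if movement == "passive":
        return -cfg.afferent_shift_deg
    if movement == "active":
        return -(cfg.afferent_shift_deg + cfg.efferent_shift_deg)
    raise ValueError(f"unknown movement type {movement!r}")


def simulate_localization(
    true_hand_deg: float,
    movement: str,
    session: str,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    bias_deg: float = 0.0,
) -> LocalizationTrial:
    """One localization tap: true hand angle + bias + injected shift + noise."""
    if not 0.0 <= true_hand_deg <= 180.0:
        raise ValueError(
            f"hand angle {true_hand_deg!r} outside the [0, 180] deg workspace"
        )
    tap = true_hand_deg + bias_deg + localization_shift_deg(movement, session, cfg)
    if rng is not None and cfg.tap_noise_sd_deg > 0:
        tap += rng.normal(0.0, cfg.tap_noise_sd_deg)
    return LocalizationTrial(
        session=session, movement=movement, hand_deg=float(true_hand_deg), tap_deg=float(tap)
    )


# ---------------------------------------------------------------------------
# Whole participants and cohorts
# ---------------------------------------------------------------------------

#: Group-conditional pmf of questionnaire awareness scores over {0, 1, 3}.
AWARENESS_PMF = {
    "instr30": (0.05, 0.15, 0.80),
    "instr60": (0.05, 0.15, 0.80),
    "noninstr60": (0.20, 0.40, 0.40),
    "noninstr30": (0.70, 0.25, 0.05),
}
_SCORES = np.array([0, 1, 3])

REACH_COLUMNS = [
    "participant", "group", "instructed", "rotation_deg", "arm", "session",
    "block", "task", "strategy_cue", "trial", "target_deg", "deviation_deg",
    "implicit_deg", "explicit_deg",
]

LOC_COLUMNS = [
    "participant", "group", "instructed", "rotation_deg", "arm", "session",
    "block", "task", "movement_type", "trial", "hand_deg", "tap_deg",
]

SAMPLE_COLUMNS = [
    "participant", "group", "instructed", "rotation_deg", "session", "block",
    "task", "strategy_cue", "trial", "target_deg", "t_s", "x_cm", "y_cm",
]


@dataclass
class ParticipantRecord:
    """One participant's group assignment and full trial tables."""

    participant: str
    group: str
    arm: str
    reaches: pd.DataFrame
    localization: pd.DataFrame
    awareness_score: int
    samples: Optional[pd.DataFrame] = None


@dataclass
class Cohort:
    """Tidy trial tables for a simulated multi-group cohort.

    ``reaches`` holds one row per reach-type trial with its angular deviation
    and the generator's hidden-state ground truth (``implicit_deg``,
    ``explicit_deg`` — never read by the analysis); ``localization`` one row
    per localization probe; ``samples`` (optional) one row per trajectory
    sample.
    """

    reaches: pd.DataFrame
    localization: pd.DataFrame
    questionnaire: pd.DataFrame
    samples: Optional[pd.DataFrame] = None
    configs: list = field(default_factory=list)

    def to_csv(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("reaches", self.reaches),
            ("localization", self.localization),
            ("questionnaire", self.questionnaire),
            ("samples", self.samples),
        ]:
            if df is None:
                continue
            p = out_dir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    def participant_records(self) -> list[ParticipantRecord]:
        records = []
        q = self.questionnaire.set_index("participant")
        for pid, sub in self.reaches.groupby("participant", sort=False):
            loc = self.localization[self.localization["participant"] == pid]
            samples = None
            if self.samples is not None:
                samples = self.samples[self.samples["participant"] == pid]
            records.append(
                ParticipantRecord(
                    participant=pid,
                    group=sub["group"].iloc[0],
                    arm=sub["arm"].iloc[0],
                    reaches=sub,
                    localization=loc,
                    awareness_score=int(q.loc[pid, "awareness_score"]),
                    samples=samples,
                )
            )
        return records


def _target_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Targets in permuted triplets: each consecutive set of 3 visits all three."""
    n_sets, rem = divmod(n_trials, 3)
    if rem:
        raise ValueError("reach sets must be multiples of 3 trials")
    base = np.asarray(REACH_TARGETS, dtype=float)
    return np.concatenate([rng.permutation(base) for _ in range(n_sets)])


def simulate_participant(
    cfg: SimulationConfig,
    participant: str,
    arm: str,
    rng: np.random.Generator,
    trajectories: bool = True,
) -> ParticipantRecord:
    """Simulate one participant through the full two-session schedule."""
    schedule = build_schedule(arm)
    biases = {t: rng.normal(0.0, cfg.reach_bias_sd_deg) for t in REACH_TARGETS}
    loc_bias = rng.normal(0.0, cfg.loc_bias_sd_deg)
    implicit = 0.0

    reach_rows: list[tuple] = []
    loc_rows: list[tuple] = []
    sample_chunks: list[pd.DataFrame] = []
    meta = (participant, cfg.group, cfg.instructed, cfg.rotation_deg, arm)

    for entry in schedule:
        rotated = entry.session == "rotated"
        if entry.task in ("reach_target", "nocursor"):
            targets = _target_sequence(entry.n_trials, rng)
            noise = rng.normal(0.0, cfg.motor_noise_sd_deg, entry.n_trials)
            cue = entry.strategy_cue or ""
            if entry.task == "reach_target":
                use_explicit = rotated
            else:
                use_explicit = rotated and cue == "with"
            devs = np.empty(entry.n_trials)
            states = np.empty(entry.n_trials)
            for i, tgt in enumerate(targets):
                e_used = cfg.explicit_deg if use_explicit else 0.0
                dev = biases[tgt] + implicit + e_used + noise[i]
                devs[i] = dev
                states[i] = implicit
                if rotated and entry.task == "reach_target":
                    visual_error = dev - cfg.rotation_deg
                    implicit = (
                        cfg.retention_A * implicit
                        + cfg.learn_rate_B * (-visual_error)
                    )
                reach_rows.append(
                    meta
                    + (
                        entry.session, entry.block, entry.task, cue, i + 1,
                        tgt, dev, states[i],
                        cfg.explicit_deg if use_explicit else 0.0,
                    )
                )
            if trajectories:
                sample_chunks.append(
                    _materialize_trajectories(cfg, meta, entry, targets, devs)
                )
        else:  # localization sets
            movement = "active" if entry.task == "loc_active" else "passive"
            n_per_center = entry.n_trials // len(LOCALIZATION_CENTERS)
            hands = np.repeat(
                np.asarray(LOCALIZATION_CENTERS, dtype=float), n_per_center
            )
            rng.shuffle(hands)
            hands = hands + rng.uniform(
                -cfg.loc_spread_deg, cfg.loc_spread_deg, entry.n_trials
            )
            hands = np.clip(hands, 0.0, 180.0)
            shift = localization_shift_deg(movement, entry.session, cfg)
            taps = (
                hands
                + loc_bias
                + shift
                + rng.normal(0.0, cfg.tap_noise_sd_deg, entry.n_trials)
            )
            for i in range(entry.n_trials):
                loc_rows.append(
                    meta
                    + (
                        entry.session, entry.block, entry.task, movement,
                        i + 1, hands[i], taps[i],
                    )
                )

    score = int(rng.choice(_SCORES, p=AWARENESS_PMF[cfg.group]))
    reaches = pd.DataFrame(reach_rows, columns=REACH_COLUMNS)
    localization = pd.DataFrame(loc_rows, columns=LOC_COLUMNS)
    samples = (
        pd.concat(sample_chunks, ignore_index=True) if sample_chunks else None
    )
    return ParticipantRecord(
        participant=participant,
        group=cfg.group,
        arm=arm,
        reaches=reaches,
        localization=localization,
        awareness_score=score,
        samples=samples,
    )


def _materialize_trajectories(cfg, meta, entry: ScheduleEntry, targets, devs):
    """Long-format minimum-jerk samples for one set of reach-type trials."""
    t, frac = min_jerk_profile(cfg.reach_duration_s, cfg.sample_rate_hz)
    n_samp = t.size
    directions = np.deg2rad(targets + devs)
    r = TARGET_DISTANCE_CM * frac
    x = np.cos(directions)[:, None] * r[None, :]
    y = np.sin(directions)[:, None] * r[None, :]
    n = entry.n_trials
    participant, group, instructed, rotation_deg, _arm = meta
    return pd.DataFrame(
        {
            "participant": participant,
            "group": group,
            "instructed": instructed,
            "rotation_deg": rotation_deg,
            "session": entry.session,
            "block": entry.block,
            "task": entry.task,
            "strategy_cue": entry.strategy_cue or "",
            "trial": np.repeat(np.arange(1, n + 1), n_samp),
            "target_deg": np.repeat(targets, n_samp),
            "t_s": np.tile(t, n),
            "x_cm": x.ravel(),
            "y_cm": y.ravel(),
        },
        columns=SAMPLE_COLUMNS,
    )


def simulate_cohort(
    cfgs: Sequence[SimulationConfig],
    trajectories: bool = True,
    seed: Optional[int] = None,
) -> Cohort:
    """Simulate a full multi-group cohort.

    One config per group; participant streams are spawned deterministically
    from ``(seed, group_index, participant_index)`` so that identical configs
    and seeds give bit-identical tables. ``seed`` overrides each config's own
    seed when given. Counterbalance arms alternate A/B within each group.
    """
    groups = [c.group for c in cfgs]
    if len(set(groups)) != len(groups):
        raise ValueError(f"duplicate group configs: {groups}")
    reach_frames, loc_frames, sample_frames, q_rows = [], [], [], []
    records_seen: set[str] = set()
    for gi, cfg in enumerate(cfgs):
        base_seed = int(cfg.seed if seed is None else seed)
        for i in range(cfg.n_participants):
            pid = f"{cfg.group}_p{i:02d}"
            if pid in records_seen:
                raise ValueError(f"duplicate participant id {pid}")
            records_seen.add(pid)
            rng = np.random.default_rng([base_seed, gi, i])
            rec = simulate_participant(
                cfg, pid, "A" if i % 2 == 0 else "B", rng, trajectories
            )
            reach_frames.append(rec.reaches)
            loc_frames.append(rec.localization)
            if rec.samples is not None:
                sample_frames.append(rec.samples)
            q_rows.append(
                (pid, cfg.group, cfg.instructed, cfg.rotation_deg, rec.awareness_score)
            )
    return Cohort(
        reaches=pd.concat(reach_frames, ignore_index=True),
        localization=pd.concat(loc_frames, ignore_index=True),
        questionnaire=pd.DataFrame(
            q_rows,
            columns=["participant", "group", "instructed", "rotation_deg", "awareness_score"],
        ),
        samples=pd.concat(sample_frames, ignore_index=True) if sample_frames else None,
        configs=list(cfgs),
    )
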