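"""Task schedule for the two-session adaptation experiment.

The experiment runs an aligned-cursor session (baseline) and, after a break, a
rotated-cursor session. Each session consists of four blocks. A block starts
with reach-to-target trials (45 in the first aligned set, 90 in the first
rotated set; 9- and 30-trial top-ups thereafter), followed by an active and a
passive hand-localization set of 18 probes each, and closes with a 9-reach
no-cursor task (3 reaches per target). In the rotated session the no-cursor
tasks carry a strategy cue ("with"/"without"), counterbalanced over blocks
between the two arms A and B.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

SESSIONS = ("aligned", "rotated")
TASKS = ("reach_target", "loc_active", "loc_passive", "nocursor")

N_BLOCKS = 4
FIRST_ALIGNED_REACHES = 45
ALIGNED_TOPUP = 9
FIRST_ROTATED_REACHES = 90
ROTATED_TOPUP = 30
LOCALIZATION_SET = 18
NOCURSOR_SET = 9

_CUE_ORDER = {
    "A": ("with", "without", "with", "without"),
    "B": ("without", "with", "without", "with"),
}


@dataclass(frozen=True)
class ScheduleEntry:
    """One task instance: a contiguous set of trials of a single kind."""

    session: str
    block: int
    task: str
    n_trials: int
    strategy_cue: Optional[str] = None


def build_schedule(counterbalance_arm: str = "A") -> list[ScheduleEntry]:
    """Full ordered task list for one participant.

    Parameters
    ----------
    counterbalance_arm : {"A", "B"}
        Determines the order of with/without-strategy no-cursor tasks across
        the rotated blocks; the two arms contain the same multiset of tasks.
    """
    if counterbalance_arm not in _CUE_ORDER:
        raise ValueError(
            f"counterbalance arm must be 'A' or 'B', got {counterbalance_arm!r}"
        )
    cues = _CUE_ORDER[counterbalance_arm]
    entries: list[ScheduleEntry] = []
    for block in range(1, N_BLOCKS + 1):
        n_reach = FIRST_ALIGNED_REACHES if block == 1 else ALIGNED_TOPUP
        entries += [
            ScheduleEntry("aligned", block, "reach_target", n_reach),
            ScheduleEntry("aligned", block, "loc_active", LOCALIZATION_SET),
            ScheduleEntry("aligned", block, "loc_passive", LOCALIZATION_SET),
            ScheduleEntry("aligned", block, "nocursor", NOCURSOR_SET),
        ]
    for block in range(1, N_BLOCKS + 1):
        n_reach = FIRST_ROTATED_REACHES if block == 1 else ROTATED_TOPUP
        entries += [
            ScheduleEntry("rotated", block, "reach_target", n_reach),
            ScheduleEntry("rotated", block, "loc_active", LOCALIZATION_SET),
            ScheduleEntry("rotated", block, "loc_passive", LOCALIZATION_SET),
            ScheduleEntry("rotated", block, "nocursor", NOCURSOR_SET, cues[block - 1]),
        ]
    return entries


def session_trial_counts(schedule: list[ScheduleEntry]) -> dict[tuple[str, str], int]:
    """Total trials per (session, task) — used for conservation checks."""
    counts: dict[tuple[str, str], int] = {}
    for e in schedule:
        key = (e.session, e.task)
        counts[key] = counts.get(key, 0) + e.n_trials
    return counts
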