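"""Process dissociation, awareness scoring, and cross-measure correlations.

After adaptation, participants reach without a cursor while cued either to
use or to suppress any strategy learned during training. Per-participant
medians of these baseline-corrected no-cursor deviations give the
process-dissociation (PDP) measures: the without-strategy median is the
implicit reach aftereffect, and the with-minus-without contrast indexes
awareness of the perturbation. Questionnaire awareness scores {0, 1, 3} map
to levels None/Low/High.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AWARENESS_LEVELS",
    "awareness_from_score",
    "nocursor_baseline_biases",
    "nocursor_summaries",
    "pdp_contrasts",
    "correlate",
    "CorrelationResult",
]

AWARENESS_LEVELS = {0: "None", 1: "Low", 3: "High"}


def awareness_from_score(score: int) -> tuple[int, str]:
    """Map a questionnaire awareness score to its level.

    Only the scores 0, 1 and 3 exist; anything else is rejected.
    """
    s = int(score)
    if s not in AWARENESS_LEVELS:
        raise ValueError(
            f"awareness score must be one of {sorted(AWARENESS_LEVELS)}, got {score!r}"
        )
    return s, AWARENESS_LEVELS[s]


def nocursor_baseline_biases(aligned_nocursor: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-target mean no-cursor deviation in the aligned session."""
    out = (
        aligned_nocursor.groupby(["participant", "target_deg"], sort=False)[
            "deviation_deg"
        ]
        .mean()
        .reset_index()
        .rename(columns={"deviation_deg": "bias_deg"})
    )
    return out


def nocursor_summaries(
    rotated_nocursor: pd.DataFrame,
    biases: pd.DataFrame,
    pool_blocks: bool = True,
) -> pd.DataFrame:
    """Baseline-corrected median no-cursor deviation per participant and cue.

    Rotated-session deviations are corrected trial-by-trial with the aligned
    per-target biases, then summarized by the median. With ``pool_blocks``
    (default) the two 9-reach task instances per cue are pooled before the
    median; otherwise per-block medians are averaged.
    """
    merged = rotated_nocursor.merge(
        biases, on=["participant", "target_deg"], how="left", validate="m:1"
    )
    if merged["bias_deg"].isna().any():
        bad = merged.loc[merged["bias_deg"].isna(), ["participant", "target_deg"]]
        raise ValueError(f"missing aligned no-cursor bias for:\n{bad.drop_duplicates()}")
    merged["corrected_deg"] = merged["deviation_deg"] - merged["bias_deg"]
    carry = [c for c in ("group", "instructed", "rotation_deg") if c in merged.columns]
    if pool_blocks:
        grouped = merged.groupby(["participant", "strategy_cue"], sort=False)
        rows = []
        for (pid, cue), sub in grouped:
            rec = {
                "participant": pid,
                "strategy_cue": cue,
                "median_deg": float(sub["corrected_deg"].median()),
                "n_trials": int(len(sub)),
            }
            for c in carry:
                rec[c] = sub[c].iloc[0]
            rows.append(rec)
        return pd.DataFrame(rows)
    per_block = (
        merged.groupby(["participant", "strategy_cue", "block"], sort=False)[
            "corrected_deg"
        ]
        .median()
        .reset_index()
    )
    rows = []
    for (pid, cue), sub in per_block.groupby(["participant", "strategy_cue"], sort=False):
        rec = {
            "participant": pid,
            "strategy_cue": cue,
            "median_deg": float(sub["corrected_deg"].mean()),
            "n_trials": int(len(sub)),
        }
        meta = merged[merged["participant"] == pid].iloc[0]
        for c in carry:
            rec[c] = meta[c]
        rows.append(rec)
    return pd.DataFrame(rows)


def pdp_contrasts(summaries: pd.DataFrame) -> pd.DataFrame:
    """With-minus-without strategy contrast per participant.

    A contrast near zero is the expected signature of an unaware participant;
    aware participants re-express their explicit strategy on cue.
    """
    carry = [c for c in ("group", "instructed", "rotation_deg") if c in summaries.columns]
    wide = summaries.pivot_table(
        index="participant", columns="strategy_cue", values="median_deg",
        aggfunc="first", dropna=False,
    )
    for cue in ("with", "without"):
        if cue not in wide.columns:
            raise ValueError(f"missing '{cue}' strategy condition")
    meta = summaries.drop_duplicates("participant").set_index("participant")
    rows = []
    for pid in wide.index:
        with_deg = wide.at[pid, "with"]
        without_deg = wide.at[pid, "without"]
        if not (np.isfinite(with_deg) and np.isfinite(without_deg)):
            raise ValueError(f"participant {pid}: missing cue condition")
        rec = {
            "participant": pid,
            "with_strategy_deg": float(with_deg),
            "without_strategy_deg": float(without_deg),
            "pdp_contrast_deg": float(with_deg) - float(without_deg),
        }
        for c in carry:
            rec[c] = meta.at[pid, c]
        rows.append(rec)
    return pd.DataFrame(rows)


class CorrelationResult(NamedTuple):
    method: str
    n: int
    coefficient: float
    p_value: float
    n_dropped: int


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation over complete pairs.

    Pairs with a missing entry are dropped (and counted in ``n_dropped``);
    Spearman uses average ranks for ties. Requires at least 3 complete pairs
    and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired (same length)")
    keep = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    import warnings

    with warnings.catch_warnings():
        # near-constant inputs are legitimate here (e.g. noise-free cohorts)
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        if method == "pearson":
            res = stats.pearsonr(x, y)
        elif method == "spearman":
            res = stats.spearmanr(x, y)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        method, int(x.size), float(res.statistic), float(res.pvalue), n_dropped
    )
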