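"""Model/Results facade for the adaptation analysis.

:class:`AdaptationStudy` bundles the trial tables of a cohort (simulated or
converted from recordings) with analysis settings; :meth:`AdaptationStudy.fit`
runs the full measurement pipeline — reach deviations, learning trial sets,
kernel-smoothed localization shifts with afferent/efferent decomposition,
process-dissociation contrasts, awareness levels and cross-measure
correlations — and returns an :class:`AdaptationResults` carrying every
product plus a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import kinematics, localization as loc_mod, pdp as pdp_mod
from .config import LOCALIZATION_CENTERS, SimulationConfig, default_study_configs
from .cohort import Cohort, simulate_cohort

__all__ = ["AdaptationStudy", "AdaptationResults"]


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return (np.nan, np.nan)
    m = v.mean()
    half = stats.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return (m - half, m + half)


class AdaptationStudy:
    """The four-group visuomotor-rotation study, ready to analyze.

    Parameters
    ----------
    reaches : DataFrame or None
        Trial-level reach table with ``deviation_deg`` (tidy schema of the
        cohort module). May be omitted when ``samples`` is given.
    localization : DataFrame
        Localization probes (``hand_deg``, ``tap_deg``, ``movement_type``).
    questionnaire : DataFrame, optional
        Awareness scores per participant.
    samples : DataFrame, optional
        Long-format trajectory samples; deviations are computed from them
        when ``reaches`` is missing or lacks deviations.
    kernel_sd_deg, centers, pool_blocks, smooth_window
        Analysis settings: kernel sd of the localization regression, probe
        angles, whether PDP medians pool the two task instances per cue, and
        an optional velocity-smoothing window for recorded data.
    """

    def __init__(
        self,
        reaches: Optional[pd.DataFrame] = None,
        localization: Optional[pd.DataFrame] = None,
        questionnaire: Optional[pd.DataFrame] = None,
        samples: Optional[pd.DataFrame] = None,
        kernel_sd_deg: float = 10.0,
        centers: Sequence[float] = LOCALIZATION_CENTERS,
        pool_blocks: bool = True,
        smooth_window: int = 0,
    ):
        if reaches is None and samples is None:
            raise ValueError("need reaches (with deviations) or trajectory samples")
        if localization is None:
            raise ValueError("localization table is required")
        self.reaches = reaches
        self.localization = localization
        self.questionnaire = questionnaire
        self.samples = samples
        self.kernel_sd_deg = float(kernel_sd_deg)
        self.centers = tuple(float(c) for c in centers)
        self.pool_blocks = bool(pool_blocks)
        self.smooth_window = int(smooth_window)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "AdaptationStudy":
        return cls(
            reaches=cohort.reaches,
            localization=cohort.localization,
            questionnaire=cohort.questionnaire,
            samples=cohort.samples,
            **kwargs,
        )

    @classmethod
    def from_csv(
        cls,
        reaches_path=None,
        localization_path=None,
        questionnaire_path=None,
        samples_path=None,
        **kwargs,
    ) -> "AdaptationStudy":
        read = lambda p: pd.read_csv(p) if p is not None else None  # noqa: E731
        return cls(
            reaches=read(reaches_path),
            localization=read(localization_path),
            questionnaire=read(questionnaire_path),
            samples=read(samples_path),
            **kwargs,
        )

    @classmethod
    def simulate(
        cls,
        configs: Optional[Sequence[SimulationConfig]] = None,
        seed: int = 0,
        n_per_group: int = 20,
        trajectories: bool = False,
        analysis: Optional[dict] = None,
        **overrides,
    ) -> "AdaptationStudy":
        """Simulate the default four-group design and wrap it for analysis."""
        if configs is None:
            configs = default_study_configs(seed=seed, n_per_group=n_per_group, **overrides)
        cohort = simulate_cohort(configs, trajectories=trajectories, seed=seed)
        study = cls.from_cohort(cohort, **(analysis or {}))
        study.cohort = cohort
        return study

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "AdaptationResults":
        """Run the full measurement pipeline and collect the results."""
        devs = self._deviations()
        devs = kinematics.screen_deviations(devs)
        exclusions = devs.loc[
            devs["valid"] == False,  # noqa: E712
            [c for c in devs.columns if c in (
                "participant", "session", "block", "task", "strategy_cue",
                "trial", "exclude_reason",
            )],
        ].rename(columns={"exclude_reason": "reason"})
        valid = devs[devs["valid"] != False].copy()  # noqa: E712

        # Training: baseline biases from the first aligned reach set, then
        # corrected/normalized deviations over the 90-trial rotated set.
        aligned_first = valid[
            (valid["session"] == "aligned")
            & (valid["task"] == "reach_target")
            & (valid["block"] == 1)
        ]
        biases = kinematics.baseline_biases(aligned_first)
        training = valid[
            (valid["session"] == "rotated")
            & (valid["task"] == "reach_target")
            & (valid["block"] == 1)
        ]
        training = kinematics.correct_and_normalize(training, biases)
        trial_sets = kinematics.learning_trial_sets(training)

        # Localization: kernel profiles -> shifts -> decomposition.
        profiles = loc_mod.localization_profiles(
            self.localization, self.centers, self.kernel_sd_deg
        )
        shifts = loc_mod.localization_shifts(profiles)
        decomposition, shift_excl = loc_mod.decompose_shifts(shifts)

        # Process dissociation from no-cursor reaches.
        nc = valid[valid["task"] == "nocursor"]
        nc_biases = pdp_mod.nocursor_baseline_biases(nc[nc["session"] == "aligned"])
        summaries = pdp_mod.nocursor_summaries(
            nc[nc["session"] == "rotated"], nc_biases, self.pool_blocks
        )
        contrasts = pdp_mod.pdp_contrasts(summaries)

        awareness = self._awareness()
        correlations = self._correlations(decomposition, contrasts, awareness)

        return AdaptationResults(
            model=self,
            deviations=devs,
            exclusions=exclusions,
            baseline_biases=biases,
            training=training,
            trial_sets=trial_sets,
            localization_profiles=profiles,
            localization_shifts=decomposition,
            shift_exclusions=shift_excl,
            nocursor_summaries=summaries,
            pdp=contrasts,
            awareness=awareness,
            correlations=correlations,
        )

    # -- internals --------------------------------------------------------

    def _deviations(self) -> pd.DataFrame:
        if self.reaches is not None and "deviation_deg" in self.reaches.columns:
            return self.reaches.copy()
        return kinematics.compute_reach_deviations(self.samples, self.smooth_window)

    def _awareness(self) -> Optional[pd.DataFrame]:
        if self.questionnaire is None:
            return None
        out = self.questionnaire.copy()
        levels = [pdp_mod.awareness_from_score(s)[1] for s in out["awareness_score"]]
        out["awareness_level"] = levels
        return out

    def _correlations(self, decomposition, contrasts, awareness) -> pd.DataFrame:
        merged = decomposition.merge(
            contrasts[
                ["participant", "with_strategy_deg", "without_strategy_deg",
                 "pdp_contrast_deg"]
            ],
            on="participant",
            how="inner",
        )
        if awareness is not None:
            merged = merged.merge(
                awareness[["participant", "awareness_score"]],
                on="participant", how="left",
            )
        pairs = [
            ("pearson", "afferent_shift_deg", "without_strategy_deg"),
            ("pearson", "efferent_shift_deg", "without_strategy_deg"),
            ("pearson", "afferent_shift_deg", "with_strategy_deg"),
            ("pearson", "efferent_shift_deg", "with_strategy_deg"),
        ]
        if awareness is not None:
            pairs += [
                ("spearman", "afferent_shift_deg", "awareness_score"),
                ("spearman", "efferent_shift_deg", "awareness_score"),
            ]
        rows = []
        for method, xcol, ycol in pairs:
            rec = {"method": method, "x": xcol, "y": ycol,
                   "n": 0, "coefficient": np.nan, "p_value": np.nan, "note": ""}
            try:
                res = pdp_mod.correlate(merged[xcol], merged[ycol], method)
                rec.update(n=res.n, coefficient=res.coefficient, p_value=res.p_value)
                if res.n_dropped:
                    rec["note"] = f"dropped {res.n_dropped} incomplete pairs"
            except ValueError as err:
                rec["note"] = str(err)
            rows.append(rec)
        return pd.DataFrame(rows)


@dataclass
class AdaptationResults:
    """Every product of the fitted pipeline, with summaries and plots."""

    model: AdaptationStudy
    deviations: pd.DataFrame
    exclusions: pd.DataFrame
    baseline_biases: pd.DataFrame
    training: pd.DataFrame
    trial_sets: pd.DataFrame
    localization_profiles: pd.DataFrame
    localization_shifts: pd.DataFrame
    shift_exclusions: pd.DataFrame
    nocursor_summaries: pd.DataFrame
    pdp: pd.DataFrame
    awareness: Optional[pd.DataFrame]
    correlations: pd.DataFrame

    def participant_measures(self) -> pd.DataFrame:
        """One row per participant with the headline per-participant measures."""
        final = (
            self.trial_sets[self.trial_sets["set"] == "final"]
            .rename(columns={"normalized": "final_compensation"})
            [["participant", "final_compensation"]]
        )
        out = self.localization_shifts.merge(
            self.pdp[
                ["participant", "with_strategy_deg", "without_strategy_deg",
                 "pdp_contrast_deg"]
            ],
            on="participant", how="outer",
        ).merge(final, on="participant", how="outer")
        if self.awareness is not None:
            out = out.merge(
                self.awareness[["participant", "awareness_score", "awareness_level"]],
                on="participant", how="left",
            )
        return out

    def group_summary(self, level: float = 0.95) -> pd.DataFrame:
        """Group means with t-based confidence intervals for each measure."""
        pm = self.participant_measures()
        measures = [
            "final_compensation", "without_strategy_deg", "with_strategy_deg",
            "pdp_contrast_deg", "afferent_shift_deg", "efferent_shift_deg",
            "active_shift_deg",
        ]
        rows = []
        for group, sub in pm.groupby("group", sort=True):
            rec = {"group": group, "n": int(len(sub))}
            for m in measures:
                v = sub[m].to_numpy(dtype=float)
                v = v[np.isfinite(v)]
                rec[f"{m}_mean"] = float(v.mean()) if v.size else np.nan
                lo, hi = _t_ci(v, level)
                rec[f"{m}_ci_lo"] = lo
                rec[f"{m}_ci_hi"] = hi
            rows.append(rec)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Readable per-group summary of the fitted measures."""
        gs = self.group_summary()
        lines = ["Visuomotor adaptation analysis", "=" * 70]
        for _, r in gs.iterrows():
            lines.append(f"\nGroup {r['group']} (n={int(r['n'])}):")
            lines.append(
                f"  final compensation     {r['final_compensation_mean']:7.3f}"
                f"  [{r['final_compensation_ci_lo']:.3f}, {r['final_compensation_ci_hi']:.3f}]"
            )
            lines.append(
                f"  aftereffect (deg)      {r['without_strategy_deg_mean']:7.2f}"
                f"  [{r['without_strategy_deg_ci_lo']:.2f}, {r['without_strategy_deg_ci_hi']:.2f}]"
            )
            lines.append(
                f"  PDP contrast (deg)     {r['pdp_contrast_deg_mean']:7.2f}"
                f"  [{r['pdp_contrast_deg_ci_lo']:.2f}, {r['pdp_contrast_deg_ci_hi']:.2f}]"
            )
            lines.append(
                f"  afferent shift (deg)   {r['afferent_shift_deg_mean']:7.2f}"
                f"  [{r['afferent_shift_deg_ci_lo']:.2f}, {r['afferent_shift_deg_ci_hi']:.2f}]"
            )
            lines.append(
                f"  efferent shift (deg)   {r['efferent_shift_deg_mean']:7.2f}"
                f"  [{r['efferent_shift_deg_ci_lo']:.2f}, {r['efferent_shift_deg_ci_hi']:.2f}]"
            )
        lines.append("\nCorrelations:")
        for _, r in self.correlations.iterrows():
            if r["note"] and not np.isfinite(r["coefficient"]):
                lines.append(f"  {r['method']:8s} {r['x']} vs {r['y']}: {r['note']}")
            else:
                lines.append(
                    f"  {r['method']:8s} {r['x']} vs {r['y']}: "
                    f"r={r['coefficient']:+.3f}, p={r['p_value']:.3g}, n={int(r['n'])}"
                )
        if len(self.exclusions):
            lines.append(f"\nExcluded trials: {len(self.exclusions)}")
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_learning_curves(self, ax=None):
        """Group-mean normalized reach deviation across the 90 training trials."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for group, sub in self.training.groupby("group"):
            curve = sub.groupby("trial")["normalized"].mean()
            ax.plot(curve.index, curve.values, label=group)
        ax.axhline(1.0, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("training trial")
        ax.set_ylabel("normalized reach deviation")
        ax.legend()
        return ax

    def plot_localization_shifts(self, ax=None):
        """Group-mean afferent and efferent localization shifts."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        gs = self.group_summary()
        xs = np.arange(len(gs))
        ax.bar(xs - 0.2, gs["afferent_shift_deg_mean"], 0.4, label="afferent")
        ax.bar(xs + 0.2, gs["efferent_shift_deg_mean"], 0.4, label="efferent")
        ax.set_xticks(xs, gs["group"])
        ax.set_ylabel("localization shift (deg)")
        ax.legend()
        return ax
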