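# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `reachadapt`, and what the package's validation does and
does not establish.

## Conventions

Angles are in degrees throughout, counter-clockwise (CCW) positive; positions
in cm. The cursor rotation is clockwise, so compensation is a positive reach
deviation and training-induced localization shifts are negative. Angle
differences are wrapped to (−180, 180]. The workspace spans 0–180°, far from
the wrap-around point, so plain (non-circular) statistics are used on
localization angles.

## Task structure

Each simulated participant completes an aligned session and a rotated
session of four blocks each. A block is: reach-to-target trials (45 in the
first aligned set, 90 in the first rotated set; 9/30-trial top-ups
afterwards), an 18-probe active localization set, an 18-probe passive set,
and a 9-reach no-cursor task (3 reaches per target at 45/90/135°, 12 cm from
the start). Rotated-session no-cursor tasks carry a with/without-strategy
cue; the two counterbalance arms (A: with/without/with/without across
blocks; B reversed) contain the same multiset of tasks. Active localization
precedes passive within a block because passive displacement targets are
matched to the preceding active reaches; the analysis pools passive trials
regardless of placement.

## Generator

### Learning model

The analysis itself is model-free; a generative model is needed only so that
synthetic cohorts have realistic structure and known ground truth. We use the
minimal model that reproduces the qualitative phenomenology (fast instructed
start, proportional compensation, cue-switchable strategy, stable
aftereffects): a single implicit state updated after every cursor-feedback
trial,

    u' = A·u + B·(−e_vis),    e_vis = hand_deviation − r,

with retention `A` and learning rate `B`, plus a constant explicit strategy
`e = strategy_frac · r` adopted at rotation onset by *aware* groups (both
instructed groups and the non-instructed 60° group; a 30° rotation without
instruction goes unnoticed). The implicit state changes only on
cursor-feedback trials — no decay during no-cursor or localization tasks.
Noise-free, the state follows `u_n = B(r−e)·Σ_{k<n}(A−B)^k` with asymptote
`B(r−e)/(1−A+B)`.

Defaults `A = 0.98`, `B = 0.13` put the unaware asymptote at 0.867·r,
matching end-of-training compensation of roughly 85–90% of the rotation; a
retention factor of exactly 1 was rejected because it forces full asymptotic
compensation for every group. `strategy_frac = 0.4` gives explicit
magnitudes of 12°/24° — large enough that aware and unaware groups separate
cleanly in the process-dissociation contrast. With these defaults total
compensation converges ~1.5 trials into training per unit of `1/(A−B)`;
the 90-trial first rotated set is effectively at asymptote (residual
(A−B)⁹⁰·r ≈ 10⁻⁵ °).

A known limitation of this model class: because the implicit state is driven
by visual error, aftereffects scale with rotation size. Human aftereffects
are far more rigid across rotation sizes; the generator makes no attempt to
reproduce that, and no validation target depends on it. Passing tests
therefore show that the *pipeline* measures what was injected — not that the
generator reproduces every empirical regularity of human adaptation.

### Trials and noise

Reaches are minimum-jerk straight paths (12 cm, default 0.6 s at 100 Hz);
human paths are curved, but the analysis only needs a speed profile with a
unique interior maximum, which minimum jerk provides (peak at mid-movement).
The executed direction is `target + bias(target) + u + e_used + ε`,
ε ~ N(0, motor 3.5°); per-target reach biases are drawn once per participant
(N(0, 2°)). Localization hand angles are uniform within ±20° of the
50/90/130° centres (the true within-arc distribution is unknowable; uniform
around centre is the least-informative choice). Taps are
`hand + bias₀ + shift + ε`, bias₀ ~ N(0, 3°) once per participant,
ε ~ N(0, tap 6°), with injected shifts −5.6° (afferent, both movement types,
rotated session only) and an additional −2.2° (efferent, active only).
Questionnaire awareness scores are drawn from group-conditional pmfs over
{0, 1, 3} (instructed: 0.05/0.15/0.80; non-instructed 60°: 0.20/0.40/0.40;
non-instructed 30°: 0.70/0.25/0.05).

Noise magnitudes, group size (20/group) and probe counts (18/task) are the
study conditions the recovery harness assumes; `SimulationConfig` exposes
them all. Identical config + seed is guaranteed bit-identical output
(participant streams spawned from (seed, group index, participant index)).

## Estimators

- **Peak velocity**: central finite differences on raw samples, no smoothing
  by default (synthetic paths are clean); a moving-average window is
  available for recorded data. Ties in peak speed break to the earliest
  sample, with a 10⁻⁹ relative tolerance so that float rounding of a
  constant-speed segment cannot push the peak later.
- **Screening** replaces manual inspection with declared rules: degenerate
  trajectory (no movement / peak at origin), movement extent < 6 cm, or
  |deviation| > 90° → excluded and logged. Input rows always equal analyzed
  plus excluded rows.
- **Kernel regression**: "10° normal kernel" is read as sd = 10°
  (configurable). The kernel is not truncated or renormalized at workspace
  edges; a centre whose total weight falls below 10⁻⁶ yields a missing
  estimate rather than an extrapolation, and participants with missing
  components are excluded from the decomposition with a log entry. Every
  finite estimate is a convex combination of observed errors.
- **PDP medians** pool the two 9-reach task instances per cue before the
  median (18 values); a `pool_blocks=False` switch averages per-block
  medians instead. Baseline correction subtracts aligned per-target
  no-cursor means trial-by-trial before aggregation.
- **Correlations** delegate to `scipy.stats` (Pearson; Spearman with
  average ranks), dropping and counting incomplete pairs; fewer than three
  pairs or zero variance is an error, not a NaN.
- Group summaries use t-based confidence intervals.

## Validation design and problem sizes

Every stage is checked three ways, at sizes chosen to keep the default test
run fast:

1. **Oracle equivalence** — deviations, kernel estimates, medians and
   correlations agree with independent brute-force recomputation to 1e−12
   relative on 1,000 random synthetic trials.
2. **Zero-noise closure** — with all noise SDs at 0 (2 participants/group,
   full trajectory fidelity), recovered afferent/efferent shifts equal the
   injected −5.6°/−2.2° to float precision and every no-cursor deviation
   equals the hidden implicit+explicit state exactly. The block-pooled
   explicit contrast matches the injected strategy to ≤ 10⁻⁴ ° — the
   state-convergence residual, since the first rotated no-cursor block sits
   a hair short of the asymptote. The decomposition identity
   afferent + efferent = active holds to the last bit of float addition
   (≤ 10⁻¹² ° residual).
3. **Stochastic recovery** — 200 seeded replicates at the study conditions
   (trial-level fidelity, trajectory sampling off for speed; the trajectory
   path is covered by 1 and 2): group-mean afferent and efferent shifts fall
   within 1.0° of injection in ≥ 95% of replicates, unaware-group PDP
   contrasts reject a zero-mean t-test at the nominal 5% (±3 points), and
   aware groups' contrast CIs cover the injected explicit magnitude at
   ≈ nominal coverage.

`scripts/acceptance.py` reports the same quantities from a fresh run: the
shift magnitudes averaged over a 100-replicate recovery experiment (a
lower-variance estimate of the same recovered measures than a single
cohort), plus the final-compensation percentage of one full trajectory-level
cohort.

## Known limitations

- The generator's aftereffect scales with rotation size (see above); its
  absolute aftereffect magnitudes are not calibrated to human values.
- The explicit strategy is constant from rotation onset; no trial-by-trial
  explicit dynamics.
- No online feedback corrections, path curvature, or generalization across
  directions; localization shifts are injected as constants rather than
  developing over training (the analysis only uses session-level contrasts).
- The converter for externally recorded datasets is a documented stub until
  a concrete column layout is available.
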