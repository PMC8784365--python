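# Methods

## The surgical process model

A suturing task is modeled at movement level.  At every instant each hand's
tool is performing exactly one of 18 activities: one of the 16
`<action;target>` tuples (actions: *move*, *transport*, *hold_still*,
*grasp*; targets of interest: *needle*, *incision*, *thread*, *tool*), or
*idle* (movement with no definable target, e.g. waiting while the other hand
works), or *not_visible* (tool outside the camera's field of view).  The
target is a target *of interest*, not a direction of motion: extracting the
thread away from the incision is still `<transport;incision>`.  On top of
the bottom-up activity labels sits a top-down segmentation of each suture
into five ordered phases — needle transport, piercing, and three knots —
taken as given from the annotation file; the pipeline never infers
segmentation.

Annotations are continuous-time intervals in seconds (no frame rate is
assumed).  Within one (suture, segment, hand) the intervals must tile the
segment span contiguously: gaps are a validation error, not silently imputed
idle time, which keeps the nonproductive-time bookkeeping exact.  Stretches
the annotator excluded entirely (e.g. movement off camera between segments)
are simply absent, and the total duration `T` of any analysis unit is the
sum of its annotated segment durations.

**Short-activity merging.**  Activities shorter than 0.5 s (configurable)
are merged into the previous activity, e.g. a brief pause during a transport
does not interrupt the transport.  Two boundary decisions are ours: a short
*leading* interval, having no predecessor, merges into its successor; and
adjacent intervals left with equal labels are coalesced so interval counts
are canonical.  Total annotated time is conserved exactly (asserted to
1e-9 s).

## Activity vectors and the similarity score

Each suture (or segment) and hand yields a vector whose component `β_l` is
the seconds spent in activity `l`, normalised to unit Euclidean length.
Vectors therefore encode the proportional time allocation, not speed:
uniformly rescaling all durations leaves them unchanged.  Suture-level
vectors pool the suture's segment durations before normalising (pooling, not
averaging of segment vectors, because the components are durations).

Three vocabularies are supported: `full18`; `actions_special6` (targets
collapsed, keeping idle and not-visible); and `actions_only4`, which drops
idle/not-visible time *before* normalising — the minimal reading of
"actions only".  Under `actions_only4` an all-nonproductive unit has no
vector; such items are skipped and counted, and a reduced-vocabulary
analysis aborts if more than half of the items are skipped.

Similarity between two unit vectors of the same hand, level and vocabulary
is their dot product (cosine similarity, in [0, 1] for nonnegative vectors).
Each unit is scored against the cohort: its mean similarity to all expert
vectors and to all novice vectors, always excluding the scored participant's
own vectors, and the *difference* (expert minus novice) is the skill score.
Segment-level pools contain only same-type segments (knot1 vs knot1, and so
on); comparing across types would conflate phase structure with skill.
Means are unweighted over eligible vectors rather than per-participant means
of means.  Scoring is in-sample — the scored unit's cohort supplies the
pools — with self-participant exclusion as the only leakage control; this
mirrors how such scores are used for descriptive group comparison, not
classifier evaluation.

## Efficiency metrics

A label is *productive* exactly when it carries a target; `hold_still` with
a target counts as productive (supporting a structure is work).  For a unit
of duration `T` and one hand's nonproductive time `t_w` (idle +
not-visible), the suturing efficiency is `S_eff = (T − t_w)/T`.  Bimanual
efficiency is `B_eff = t_B/T` where `t_B` is the measure of time both hands
are simultaneously productive, computed by an exact event-boundary sweep
over the two hands' productive interval sets — never by sampling (a 1 ms
sampling oracle exists only in the test suite).  Not-visible time stays in
the denominator `T`, consistent with subtracting it via `t_w`.  These
definitions force `0 ≤ B_eff ≤ min(S_eff,left, S_eff,right) ≤ 1` and make
suture-level records the duration-weighted aggregates of their segment
records; both are asserted in the tests.

## Group comparison models

Participants contribute repeated sutures, so all contrasts use a
per-participant random intercept, fitted by REML.

*Suture level.*  `outcome ~ skill + (1 | participant)`; the reported
estimate is the novice-minus-expert contrast with a t test and 95% CI.
Degrees of freedom use Satterthwaite's method, computed numerically from the
REML fit: for `g(θ) = l'(X'V⁻¹X)⁻¹l`, `df = 2g²/(∇g' A ∇g)` with `A` the
inverse observed REML information (finite differences over the log-variance
parameters).  For the balanced two-group design this lands at
n_participants − 2 (≈ 8 for a 5 + 5 cohort), which is also the documented
fallback when a fit is singular.

*Segment level.*  The question is whether skill and segment phase interact,
so `outcome ~ skill * segment + (1 | participant)` is tested with type III
Wald F statistics under sum-to-zero coding.  Because the residual spread of
both similarity and efficiency outcomes differs strongly across phases and
groups, the residual variance is free to vary by segment-by-skill cell
(ten variances in a full design); the fitter inverts each participant block
in closed form via the rank-one structure, so fits are fast enough for
simulation studies.  Denominator df are n_participants − 2 for the
between-participant skill term and the within-participant residual df
(n_obs − rank(X) − (n_participants − 1)) for segment and interaction; the
multi-df eigenvalue generalisation of Satterthwaite is not implemented.
Simulations in the acceptance suite check the consequences directly: the
interaction test's type-I error is ≈ 5% under the null, and the suture-level
CI covers a known contrast at ≈ 95%.

Outcomes are bounded ([0, 1] or [−1, 1]) but analysed untransformed; when
observed values come within 0.01 of a bound the result carries a warning,
and a Levene-type diagnostic (absolute deviations from group medians, via
`scipy.stats.levene(center='median')`) is available for residual-spread
checks.  Singular fits (participant variance on the boundary) are flagged,
never silently dropped.

## Label-noise validation

Target annotation leaves room for interpretation; action labels are
considered objectively visible.  The corruption model therefore switches
*targets only*: each productive interval independently, with probability p,
has its target resampled uniformly from the three other targets — so a
triggered switch always changes the label and p = 1 means every target
changed.  Idle/not-visible intervals and all actions are untouched.  The
sweep runs p ∈ {0, 0.1, …, 1.0} with replication (default 20 corrupted
datasets per p) and summarises, per contrast, the largest p at which at
least half the replicates stay significant at α = 0.05.

A consequence worth stating plainly: because `S_eff` and `B_eff` depend only
on the idle/not-visible labels, they are *exactly invariant* under target
switching (asserted bit-for-bit in the tests).  Any observed degradation of
efficiency conclusions under "target noise" therefore implies a corruption
process that also moves labels into or out of the no-target class.  An
optional mode (`mode="to_idle"`, off by default) relabels a productive
interval as idle with probability p to emulate that reading.

## The synthetic-data generator

The generator produces cohorts with the statistical structure the analysis
assumes: by default 5 experts and 5 novices, 5 sutures each, 5 segments per
suture, both hands tiling identical segment spans.  Per participant, a
random effect b ~ N(0, 0.3) shifts the idle fraction on the logit scale
(keeping efficiencies inside (0, 1) and correlating a participant's
sutures); 0.3 on the logit scale is ≈ 0.06 on the efficiency scale, a
moderate between-surgeon variability for a homogeneous training cohort.
Segment lengths are log-normal around type medians (18/16/30/24/20 s),
activity intervals log-normal with a 2 s median — positive, right-skewed
durations matching movement-time phenomenology.  Labels are drawn i.i.d.
per interval: idle with the participant-adjusted probability, not-visible
with a small fixed probability, otherwise an `<action;target>` pair from
the group's hand- and segment-specific mixture (action marginal × target
marginal).

Default calibration targets: novice left-hand (microforceps) nonproductive
fraction 0.32 vs 0.12 for experts, and right-hand (needleholder) 0.13 vs
0.02.  These imply relative efficiency gaps of ≈ 29% (left) and ≈ 13%
(right); with the hands' idle placement independent (the default), the
bimanual gap emerges as ≈ 46% from the product of per-hand efficiencies.  A
`bimanual_overlap` propensity lets left-hand intervals copy the right
hand's concurrent productivity state when explicit co-ordination structure
is wanted.  Expert and novice mixtures differ in *both* action and target
marginals (experts transport- and hold-still-heavy on canonical targets;
novices move-heavy with mass on the tool target), so group separation
survives target corruption, as in the validation experiments.  Two
auxiliary profile pairs isolate one signal each: `target_signal_profiles`
(identical actions and idle; only targets differ — full corruption erases
all group signal) and `action_signal_profiles` (identical targets and idle;
only actions differ — separation survives p = 1).

**What the synthetic cohorts do not emulate.**  Labels are exchangeable
within a segment (no within-segment sequential grammar of activities), both
hands' activity processes are conditionally independent given the profiles,
annotation boundaries are exact (no annotator jitter), and incomplete
sutures occur only as a configurable missing-third-knot probability.
Passing tests on these data therefore demonstrate that the pipeline
recovers group structure *of the kind assumed*, with correctly calibrated
inference — not that real novice/expert cohorts will show these effect
sizes, nor that the scores are robust to structured (non-random) annotation
disagreement.

## Numerical choices and problem sizes

* Interval contiguity/span tolerance 1e-6 s; unit-norm tolerance 1e-9.
* REML variances optimised on the log scale (L-BFGS-B, bounds e⁻²⁵…e¹⁰);
  participant variance below 1e-6 of the mean residual variance flags the
  fit singular.
* Cosine similarity is a plain dot product of unit vectors; no clipping.
* Zero-duration units, empty group pools after self-exclusion, all-zero
  duration vectors and mismatched hand spans are explicit errors, not NaNs.
* The simulation-based checks use 50 replicates for parameter recovery at
  the default cohort size, 1000 for CI coverage, 500 for the interaction
  type-I error, and 5 replicates per noise level in the sweep examples;
  these sizes keep each Monte-Carlo standard error well inside the band
  being checked.

## Known limitations

* The segment-level F tests use containment-style denominator df rather
  than multi-df Satterthwaite; with ≥ 2 observations per cell and the
  default design this is accurate (type-I error ≈ 5% in simulation), but
  very small unbalanced designs may be liberal.
* The similarity score is descriptive, not a validated classifier; no ROC
  or cross-validation machinery is provided by design.
* Kinematic measures (velocities, path lengths, sub-movements) are out of
  scope: they are not computable from activity labels.
* The annotation format carries one activity per hand per instant; models
  with overlapping or hierarchical activities need a different container.
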