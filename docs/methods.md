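# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limitations of `replayplan`. Everything stated
here is computed by the package's tests or by `scripts/acceptance.py`;
nothing is asserted from outside the code.

## Task model

The environment is a three-state, two-stage Markov decision process. The
root state `S1` offers `left`/`right`, deterministically leading to `S2` or
`S3`; each second-stage state offers `top`/`bottom`, paying a reward drawn
from a state-action mean and then clipping to [1, 50] (the instructed
bounds). Default means are 45 (best action of the rich state), 20 (best
action of the poor state) and 5 (both low actions); in the noisy condition
rewards carry Gaussian noise with sd 2 (configurable), chosen so that
persistent prediction errors survive learning while the revaluation margin
(45 vs 20) remains unambiguous. Revaluation blocks swap the 45/20
best-action means between `S2` and `S3` from the Relearning phase onward,
flipping the optimal root action; control blocks change nothing.

A block runs 70 learning trials, 18 relearning episodes (alternating
`S2`, `S3`; the minimal schedule consistent with "rest after every six
episodes, three rests"), and 4 test choices with no feedback and no value
update. Rest periods of 30 s (15 TRs at TR = 2.08 s; 14.4 rounded up so the
5-TR spillover skip and the 10-TR analysis window exactly tile the period)
follow every sixth relearning episode.

**Forced-choice balancing.** Any state-action pair not experienced in the
last 10 trials is presented as a forced choice (stalest pair first); to
reach a stale second-stage pair the root choice is directed too, and both
steps are logged as forced. Forced choices are excluded from the
replanning-score counts — they reflect the sampling schedule, not
preference, and including them biases every score downward by roughly the
forcing rate.

## Agent

Tabular TD learning: δ = r + γ·Q(s′,a′) − Q(s,a), Q(s,a) ← Q(s,a) + αδ,
with γ = 1 (one-step horizon) and the successor term zero at terminal
states. Defaults: α = 0.7 (the pooled estimate this class of task yields),
softmax inverse temperature β = 3, and a 5 % uniform lapse. The lapse is
load-bearing: with β = 3 over value gaps of ~25 currency units, softmax
choice is effectively deterministic, and without a lapse every
control-block replanning score is exactly zero, degenerating the rank
statistics downstream. A small lapse produces the human-like score spread
the group statistics operate on.

**Root-state updates bootstrap from the greedy second-stage action**
(evaluated on pre-update values) rather than the action actually pressed
next. The root learns what the successor state is *worth*; bootstrapping
from pressed keys lets forced or lapsed second-stage presses crush the
root value at α = 0.7, and offline replay then "repairs" it before test —
an artifactual replay-behavior coupling that appears *in control blocks*
and contradicts the design's control logic. The terminal (second-stage)
updates, whose prediction errors drive all PE analyses, are the plain TD
rule.

### Prioritized replay

Every experienced transition is stored in a buffer (one slot per
state-action pair; re-experiencing replaces the slot) tagged with priority
`pe_sensitivity · |δ|`. Tagging also performs the prioritized-sweeping
backup: buffered *predecessors* of the tagged state (transitions whose
successor it is) have their priority raised to at least the new value.
This is what lets root transitions — never experienced during relearning —
acquire priority when the changed second-stage rewards produce surprise.

At each rest period the agent makes `replay_budget_k` draws. Under the
prioritized mode each draw selects a stored transition with probability
proportional to its current priority, in competition with a constant
`background_replay_mass` (default 25, priority units) representing
off-task memories; draws landing in the background replay nothing
task-related. Replayed terminal transitions re-update from their stored
reward; replayed root transitions update from r = 0 plus the greedy
successor value — the integration step. Priorities refresh to the new |δ|
after each replay (with predecessor propagation), so replay self-quenches
once values are integrated: most root replay happens at Rest 1, matching
the decreasing evidence dynamics. If every priority is zero, all draws are
background draws and nothing is replayed: no surprise, no task replay.
The uniform mode (a lesion comparator) draws uniformly over stored
transitions without background competition; `none` disables replay.

### Learning-rate estimation

`fit_learning_rate` reconstructs each block's value trajectory from its
logged transitions at every candidate α on a 0.01-step grid and pools the
log-likelihood of all free choices under softmax(β·Q) with the known lapse
mixed in (β and lapse are fixed inputs; only α is estimated, as a single
population-level parameter). Reconstruction covers online updates only, so
recovery studies simulate with `replay_mode='none'`.

Near-deterministic choice makes the likelihood *asymmetrically*
informative: candidates slower than the truth mispredict early and
post-revaluation choices and are punished sharply, while candidates faster
than the truth produce virtually the same saturated choice probabilities —
the likelihood is flat from the truth up to α = 1 (measured: the per-block
log-likelihood difference between α = 1.0 and a true α = 0.7 is
−0.04 ± 0.02). A raw argmax therefore drifts to the boundary on a large
fraction of finite samples. The estimator reads "tie-break toward smaller
α" through that geometry: it returns the smallest grid value whose
log-likelihood is within `tie_tol` (default 1 nat) of the maximum — the
lower edge of the near-maximal plateau, which is the quantity the data
identify. The raw argmax is also reported. A likelihood that is flat over
the whole grid (β = 0) is flagged non-identifiable and returns the grid
minimum.

## Synthetic neural data

Voxels form three category-selective populations (face, scene, object)
plus a nonselective background, 50 voxels each by default, with i.i.d.
unit-variance Gaussian noise. The localizer presents each category in four
12-s blocks (6 TRs) separated by 12-s rests, order shuffled per cycle;
category blocks add a constant selectivity amplitude (default 1.0) to
their population. Rest periods receive (a) spillover of the pre-rest
(second-stage) category, amplitude 2.0 decaying as exp(−t/2 TRs) from
TR 0, and (b) one reactivation event of the root-state category per
`coupling_gain × (replayed root transitions)` (default gain 2), each
adding the selectivity amplitude at a uniformly random TR ≥ 5. Restricting
events to TR ≥ 5 keeps ground truth inside the analysis window; a stress
mode (`allow_early_events`) lifts the restriction to quantify what the
window omission loses. There is no hemodynamic convolution: the analysis
operates on TR-resolution patterns, and a response kernel would add no
testable content at this abstraction level.

### Cohort coupling

Each of the 24 simulated participants receives a latent replay propensity
u, evenly spaced on [0, 1] and shuffled. One latent variable drives all
three arms of the hypothesis: the replay budget k = round(40·u), the
tagging gain `pe_sensitivity = 0.1·u`, and the gain of the simulated
PE-sensitive region signal (u itself). The 0.1 scale on the tagging gain
is a design-time calibration: against the fixed background replay mass it
spreads the policy flip across the propensity range (instead of saturating
at the smallest budgets), so that replanning, replay counts, and replay
evidence all vary monotonically across the cohort — the planted effect the
analysis stack is supposed to recover. Every participant completes the
2 × 2 design (revaluation/control × noisy/noiseless, order randomized,
root categories balanced 2 face / 2 scene).

The simulated PE-region signal is two samples per learning-phase reward
(onset + baseline); onsets carry a unit mean response plus the
participant's gain times |δ|, with unit noise. The parametric-modulation
GLM (OLS on intercept + onset indicator + mean-centered |δ|) recovers the
gain as the modulation beta; correlating per-participant betas with replay
evidence and replanning is the statistical skeleton of the
PE → replay → replanning chain, without volumetric maps.

## MVPA

ROI selection is a per-voxel two-sample t test of face-block vs
scene-block TRs, one-sided p < 0.005, uncorrected, per direction — the
liberal threshold is intentional (missing informative voxels costs more
than admitting a few null ones, ~0.5 % per direction by construction). On
these synthetic block designs without an HRF, the t contrast is the GLM
contrast. Classifiers are L2-regularized logistic regressions (strength
C = 1) trained one-vs-other on block TRs only, restricted to the target
category's own ROI, with per-voxel mean-centering by localizer block
statistics. Keeping the face and scene readouts on disjoint voxel sets
avoids the anti-correlation artifact of shared-voxel classifiers; the
package computes the face-scene evidence cross-correlation as a
diagnostic, and a test demonstrates that a shared-ROI variant scores
strictly lower. Because the generator has no shared global signal (no
arousal or scanner drift), the disjoint-ROI cross-correlation sits near
zero or mildly negative rather than positive as in real data.

Replay evidence is the mean posterior for the block's root-state category
over TRs 5–14 of each rest; the block score averages all 3 × 10
contributing TRs.

## Inference

Spearman correlations use average ranks (tie-corrected) with the
t-approximation p; a permutation option exists for robustness checks. The
bootstrap resamples participants with replacement 1000 times, applying the
same resample to both conditions (participants are the exchangeable unit,
and a participant's two conditions travel together), and recomputes
ρ_reval − ρ_control per resample; the reported p is one-sided
(revaluation > control, the directional hypothesis), with a two-sided
flag. Exact zero differences count half (mid-p), so the symmetric null
yields p ≈ 0.5. Resamples with degenerate (constant) inputs contribute a
zero coefficient and are counted. Rest-period dynamics mean-center each
block's three rest evidences before the Rest 1 vs Rest 3 paired t test;
the Rest 1 revaluation-vs-control comparison uses uncentered values.
Fisher-z comparisons use atanh with the 1/(n−3) variance; the pipeline
applies it to the Rest 1 vs Rest 3 replay-behavior correlations and,
separately labeled, to the condition comparison.

## Determinism

Every stochastic stage derives its generator from the master seed plus a
stage tag (CRC-32); cohorts, bootstraps, and the pipeline reproduce byte
for byte under a fixed seed, which the test suite asserts end to end.

## Problem sizes

Defaults are sized for desk-scale reproduction: 24 participants × 4
blocks, 200-voxel patterns, 1000 bootstrap resamples; the mechanism-lesion
checks use 200–500 simulated blocks and the end-to-end recovery check 50
cohort replicates. All sizes are parameters.

## What passing tests do and do not show

The generator realizes the analysis stack's assumptions exactly:
independent Gaussian voxel noise, discrete TR-resolution events confined
to the analysis window, no hemodynamics, no motion, no session effects, a
single latent propensity coupling replay to behavior, and agents that
always respond. Passing tests therefore certify the *pipeline* — that the
statistics recover a planted replay-replanning coupling and stay null when
it is absent — not that real fMRI data would behave this way. In real
data, autocorrelated noise, shared global signal, HRF smearing of events
across the window boundary, and missed responses all degrade the mapping;
the stress mode, the spillover robustness test, and the noise-only cohort
test probe the nearest of these failure modes, and the valid-response
denominators in the replanning score exist for data where responses can be
missing. Sequential (ordered) replay, successor-representation agents, and
volumetric inference are out of scope.
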