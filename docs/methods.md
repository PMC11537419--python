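# Methods

`gazeshelf` re-implements, end to end, the analysis of action-locked gaze
behavior in a VR shelf-sorting experiment: subjects sort 16 objects (4
colors x 4 shapes, each pair once) on a 5x5 shelf under 12 instructions —
8 EASY (one feature, rows or columns) and 4 HARD (two features, or one
feature over rows and columns jointly). Because no raw recordings are
publicly deposited, every stage is driven by a synthetic-session
generator with complete ground truth; this note records the models,
parameter choices, and the places where the published description was
ambiguous or internally inconsistent and a decision had to be made.

## Event detection

Gaze is a 120 Hz stream of unit direction vectors (x right, y up, z
forward). Gaze angles are `theta_h = (180/pi) arctan(x/z)`,
`theta_v = (180/pi) arctan(y/z)`; angular velocity is the first
difference over time, assigned to the later timestamp of each pair, with
magnitude `omega = sqrt(omega_h^2 + omega_v^2)`. Samples with `z = 0` are
flagged invalid; gaps longer than two nominal sample intervals split
events (no interpolation).

The saccade threshold is adapted iteratively from an initial 200 deg/s:
each iteration re-estimates the threshold from the sub-threshold samples
and stops when it changes by at most 1 deg/s. The update is
`median + 3 x MAD` (raw MAD, no 1.4826 scaling) of the sub-threshold
velocities. A dispersion-only update (`3 x MAD` alone) is **not** a fixed
point of this iteration: for any velocity distribution whose density
vanishes at zero (every rectified-noise distribution), the truncated MAD
shrinks faster than the threshold, and the iteration contracts to zero —
on synthetic streams it bottomed out at 0.1–4 deg/s and classified every
sample as saccadic. Including the robust center, as the adaptive-threshold
saccade-detection literature does, gives a stable fixed point (~65–70
deg/s on default synthetic streams). Samples at or below the converged
threshold are fixation samples; runs of equal labels become events.

Two merge rules clean up one- and two-sample misclassifications, applied
in this order, one pass each: (a) saccades shorter than 30 ms bracketed
by fixations are absorbed into a single fixation; (b) fixations shorter
than 50 ms bracketed by saccades become part of a single saccade. The
merge pass is idempotent. Fixations shorter than 100 ms are then removed,
and fixations longer than the robust upper fence `median + 3.5 x MAD` of
the fixation-duration population are rejected as outliers. A literal
absolute cutoff of `3.5 x MAD` would sit *below* the median for any
plausible duration distribution (lognormal-like shapes have MAD well
under median/3.5) and reject most of the data, which is irreconcilable
with a ~2% rejection share; the upper-fence reading is the standard
robust-outlier rule and removes ~2–5% on default synthetic sessions.
When the duration MAD is zero (identical durations) the outlier step is
skipped with a warning.

## Grasps, epochs, quality control

Grasps are trigger press–release pairs; pickup and drop-off cells are the
nearest cell centers to the controller position at those instants
(positions farther than 0.5 m from every cell flag the trial). Grasps
with identical pickup and drop-off cells are discarded; unpaired presses
at stream end are dropped with a warning. Trials with fewer than three
grasps are removed, as are trials whose grasp count exceeds the upper
Tukey fence `Q3 + 1.5 x IQR` of the per-trial-type count distribution.
Each grasp k induces a preparation epoch `[end(k-1), onset(k))` (from
trial start for k = 0) and an execution epoch `[onset(k), end(k)]`; the
half-open preparation convention attributes a fixation straddling grasp
onset by its own onset time.

## Action-relative ROI labels

A fixation resolves to the shelf cell nearest its mean gaze direction,
accepted within half a cell pitch (~7.4 deg at the default geometry: 2 m
x 2 m shelf viewed from 1.5 m); fixations outside the shelf are excluded
from ROI analyses. Relative to a reference grasp, cells are labeled:
current pickup -> `cur_target_object`, current drop-off ->
`cur_target_shelf`, next grasp's cells -> `next_target_object/shelf`,
previous drop-off -> `prev_target_object` while the displaced object
still occupies it, `prev_target_shelf` otherwise. The previous target
object and previous target shelf are spatially the same location (the
object sits where it was placed), so occupancy is the only way to
distinguish them; the shelf label is correspondingly rare. Precedence on
coinciding cells is current > next > previous. All remaining cells are
`other_objects` (occupied) or `other_shelves` (empty). The first grasp
has no previous targets and the last no next targets; those cells fall
through to the `other_*` categories.

## The greedy task model

The model scores a shelf configuration per line (row/column, per the
instruction's axis): same-mode lines score the count of the modal feature
value ("identical object features"); unique-mode lines score the number
of feature values occurring exactly once ("unique object features"),
summed over the required features. Goals are line-wise: same-mode lines
must be feature-homogeneous or empty; unique-mode lines must be free of
repeated required-feature values. Empty lines always satisfy — with 16
objects on 5 rows every goal arrangement leaves lines empty. The strict
alternative reading ("all four values exactly once per line") was
rejected because no strictly score-improving move sequence reaches it
from random starts under any scoring tried (exhaustive search over the
improvement DAG solves 0–5% of HARD instances), while the lenient goal is
exactly the score-maximal set.

Two search procedures are provided. `steepest` hill climbing applies the
best strictly improving displacement (occupied -> empty cell; visited
states blocked; scan-order tie-breaks, optionally randomized) until goal
or local maximum; its trajectory is what the synthetic agent replays.
`stack` is the literal transcription of the published pseudocode: while
scanning a state's successors in fixed order, every successor beating
the best score seen so far in that scan is pushed; the search continues
from the stack top, backtracks on dead ends, and stops when a popped
state satisfies the goal, reporting the number of states ever pushed
("length of S" with the stack read as an append-only history, initial
configuration included). The constrained variant excludes destinations in
the bottom row or rightmost column as a hard rule — only a hard exclusion
can make HARD instances genuinely unsolvable, as the reported failure
rate requires. An exact breadth-first-search oracle validates the greedy
counts on reduced (3x3, 4-object) instances, where the whole state space
is enumerable.

Reproducibility caveat, stated plainly: the printed pseudocode is
internally inconsistent when read literally (its loop empties the stack
whose length it then returns, and contains no goal test), and across a
systematic grid of readings — steepest/first-improvement ascent with and
without plateau moves, stop-at-goal and exhaustive stack search,
best-so-far vs push-all, distinct-count vs exactly-once scoring, strict
vs lenient goals — no variant jointly reproduces all five published
model statistics. The adopted reading reproduces the constrained-model
mean and the constrained unsolvable rate within sampling error but gives
unconstrained means of ~6.9 (EASY) and ~9.6 (HARD) moves at 48 simulated
subjects, below the published 9.34/11.06; uniform random initial
configurations simply sit closer to the lenient goals than those figures
imply. `scripts/acceptance.py` recomputes and reports these quantities
as measured.

## Synthetic sessions

Each simulated subject performs 24 trials (each instruction twice,
shuffled) with uniformly random initial placements. An agent policy
produces the move sequence: `greedy_optimal` replays the steepest-ascent
model; `spatial_heuristic` chooses among improving moves preferring
pickups near the top-left and avoiding drop-offs into the bottom
row/rightmost column (reproducing the human spatial-progression
signature: strongly positive Spearman correlation between mean pickup
row/column and grasp index, and depleted drop-off propensity along the
bottom/right edge); `random_valid` picks uniformly among improving
moves. All policies emit only legal moves and terminate at the goal, at
a local maximum, or at a move cap.

Epoch durations are lognormal (shape 0.25, floor 0.8 s) with means 2.10 s
(EASY) / 4.05 s (HARD) for preparation and 1.76 s / 2.15 s for execution
— the observed means of the emulated experiment. The gaze schedule per
grasp: during early preparation, fixations sample the previous drop-off
and other objects/shelves (with small shares on next-action targets);
after a fraction 0.42 (EASY) / 0.46 (HARD) of the preparation epoch has
elapsed, fixations lock onto the current target object until grasp onset
— the just-in-time signature; execution fixations stay on the pickup
location for the first half, move to the drop-off shelf, and sample
next-action targets and other regions late. Fixation durations are
lognormal, median 350 ms, shape 0.17, truncated at 100 ms; the shape was
solved analytically so that ~2.4% of durations exceed the
`median + 3.5 x MAD` fence, making the outlier-rejection share of the
pipeline realistic by construction. Fixation points jitter within a cell
(<= 30% of the cell pitch, consecutive points >= 0.20 m apart) so that
refixations of one cell produce detectable >= 32 ms saccades at 120 Hz
rather than merging; saccades are constant-velocity great-circle sweeps
(400 deg/s nominal, 32–60 ms). Angular noise is stationary AR(1)
(marginal SD 0.5 deg, the tracker's calibration-error scale; AR
coefficient 0.9, because white noise at 120 Hz would imply ~100 deg/s
fixational velocities that no filtered tracker produces). The controller
moves linearly between cell centers, arriving at the pickup exactly at
grasp onset, with the trigger held during execution.

What the generator does not emulate: human fixation proportions are a
deterministic schedule here (the current-target proportion reaches ~100%
at grasp onset rather than the ~68% of real data); there are no blinks,
tracking dropouts, smooth pursuit of the carried object, or
between-subject strategy differences beyond sampling noise. Passing
round-trip tests therefore demonstrates the correctness of the pipeline's
event algebra, not its robustness to every artifact of real recordings.

## Gaze dynamics statistics

Time-locked profiles count fixations on the eight ROIs in 0.25 s bins
over [-3 s, +2 s] around every grasp onset; labels are re-derived
relative to each reference grasp; a fixation contributes to every bin it
overlaps (onset-only assignment available); bins are anchored to grasp
onset regardless of epoch boundaries. Proportions are normalized per
(subject, bin) and averaged across subjects.

EASY-HARD differences are tested per ROI by cluster-based permutation:
per bin, `t = sqrt(N) mean(d) / sd(d)` over per-subject proportion
differences d; contiguous, sign-consistent bins with |t| > 2.14 (the
printed constant, taken as-is; a df-derived threshold is an option) form
clusters with mass = sum of t. The null shuffles time-bin labels
independently within every trial's binned series (condition-label
exchange available behind a flag) and records the maximal absolute
cluster mass; cluster p is the fraction of null masses at least as
large. With eight ROIs, significance is Bonferroni-corrected to
0.05/8 = 0.006. Family-wise type-I error under a simulated null is
verified at <= 0.05 in the acceptance suite.

Transition matrices M (8x8, zero diagonal) count consecutive
differing-ROI fixation pairs per epoch. Since the entries of `M - M^T`
sum to zero identically, relative net transitions are computed over
unordered pairs: `R = sum_{i<j} |M_ij - M_ji| / sum_{i<j} (M_ij + M_ji)`,
which is 1 for one-directional flow and 0 for symmetric switching, and
is averaged over a trial's epochs of each kind.

First-fixation latency is the time from epoch start to the first
fixation on an ROI, divided by epoch duration (in [0, 1]; never-fixated
ROIs are missing, not zero), aggregated to the per-trial median.

## Mixed models

Five model families are registered (epoch durations, displacements,
transitions, preparation/execution latencies), fitted by REML through
statsmodels MixedLM with random intercepts and slopes by subject. Binary
factors are effect-coded at +/-1 with the level of interest (HARD,
preparation, HUMAN) mapped to +1, so a coefficient is half the marginal
difference; the duration response is log-transformed and estimates/CIs
are exponentiated in the report (multiplicative effects). The ROI factor
of the latency models is treatment-coded against the
current-target-object reference, matching the published comparison of
every ROI against the just-in-time target; ROI levels with fewer than 10
observations are dropped before fitting to keep the design nonsingular.
Non-convergence triggers a documented fallback ladder of simplified
random structures ending at a random intercept. Fixed-effect inference
uses a between-within df approximation (Satterthwaite is not available
in the host solver; a normal approximation is selectable); 95% CI
coverage of known coefficients is verified by simulation for every
family in the acceptance suite.

## Problem sizes

Defaults used by the test suite and scripts: 4–6 simulated subjects for
pipeline-level statistics, 48 subjects for the model benchmark, 500
simulations x 200 permutations for the type-I-error check, 100
replicates per model family for CI coverage, and the full 3,024-state
enumeration of the reduced 3x3 task for solver validation.
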