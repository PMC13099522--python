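# Methods

`dyadvr` analyzes dyadic fighting-like interaction between two adult
zebrafish moving in a shared circular virtual-reality arena. Each fish is
logged once per frame (100 ms) as position, heading, forward speed and
turning speed; the package turns a pair of frame-aligned logs into the
behavioral statistics of the paradigm and ships a synthetic generator so
every statistic can be validated against known ground truth.

## Coordinate and angle conventions

The arena center is the origin; lengths are VR units (the arena radius is
100 units, the avatar 25 units ≈ one body length). Angles are degrees,
counterclockwise from +x, normalized to (−180, +180]. The *relative
bearing* of a target is the signed angle from the observer's heading to
the observer→target vector with **negative = left**. This sign choice is
forced by the visual-field definition: the left monocular field is
[−135°, −30°), the binocular field [−30°, +30°], the right monocular
field (+30°, +135°]; bearings beyond ±135° are the blind spot. The three
fields tile 270° of the horizontal view. Interval endpoints are assigned
uniquely (left: half-open right, binocular: closed, right: half-open
left), a measure-zero convention that makes classification a total
partition.

## Per-frame classifiers

**Attack posture.** A fish is in attack posture when the forward ray from
its mouth — modeled as a point half an avatar length ahead of the logged
position, which is taken to be the body center — intersects the disk of
radius 25 units centered on the opponent. The attack-posture rate is the
percentage of such frames in a trial.

**Bite events.** The VR rig resolves collisions in a 3D physics engine;
the package approximates the collider in 2D: a candidate collision exists
when the biter's mouth point is within 2 units of the opponent's mid-body
segment (the central third of the body axis) *and* the biter's heading is
within ±75° of the line perpendicular to the opponent's body axis (an
attack parallel to the opponent's flank is not a bite). The mid-body
geometry (central fraction 1/3, lateral half-width 2 units) is this
package's approximation and is exposed in the configuration. A bite is
counted on the rising edge only: a candidate at frame t with no candidate
at t−1 for the same (biter, bitten) pair, so a collision lasting many
frames counts once.

**Occupancy.** The near rate is the percentage of frames with inter-fish
distance ≤ 50 units (boundary inclusive). The center-occupancy rate is
the percentage of frames a fish spends strictly inside the inner circle
of radius 70 units (half the arena's area).

## Approach episodes

Approaches are mined from the mutual-distance series. Peaks and valleys
are detected with a plateau-aware scan (first frame of a plateau is the
extremum; a monotone run reaching the series boundary makes the endpoint
an extremum; an optional prominence threshold merges small wiggles —
default 0, since the logs are not smoothed). Each peak→next-valley window
is a candidate. Within a window, an episode of fish A is a maximal span
where (1) the distance is non-increasing with a strict net decrease, (2)
A's episode-mean speed exceeds B's, and (3) B stays within ±90° of A's
heading at every frame. "Kept reducing" is implemented as non-increasing
rather than strictly decreasing per frame, which is too brittle at 100 ms
sampling. Episodes shorter than 3 frames are discarded (configurable; a
single-frame "approach" is an artifact at this frame rate).

The three conditions make the assignment exclusive by construction in the
typical case; when both fish qualify on overlapping frames the fish with
the higher mean speed over the contested frames keeps them, and an exact
tie assigns them to neither. The distance at the final frame of an
episode is its *remaining distance*; an episode is flagged `terminal_bite`
when the approacher scores a bite within one frame of the episode end.

## Attraction

Attraction is the fractional reduction of the observed mean inter-fish
distance relative to a shuffled null:

    attraction = (mean(dist_shuffled) − dist_real) / mean(dist_shuffled)

where `dist_shuffled` is the mean distance after a uniform random
permutation of one fish's position frames, averaged over 10 permutations
(whole-frame permutation, not block or cyclic shuffling). Which fish is
shuffled is a free choice; the default is fish B, with an option to
average both choices. The statistic is 0 in expectation for temporally
unrelated trajectories, positive when the fish are closer than chance,
and at most 1. The numerator is computed as the mean of per-permutation
differences so that a shuffle-invariant input (a time-constant opponent)
yields exactly zero in floating point.

## Eye-use indices

Over any frame set, with N_l, N_r, N_b the counts of frames in which the
opponent lies in the left, right and binocular fields (blind frames
excluded from the denominator):

    LEP  = 100 · N_l / (N_l + N_r + N_b)
    FBVP = 100 · N_b / (N_l + N_r + N_b)
    REP  = 100 · N_r / (N_l + N_r + N_b)
    LEI  = (N_l − N_r) / (N_l + N_r)        (binocular frames excluded)

LEP + FBVP + REP = 100 whenever the denominator is non-zero; empty
denominators propagate as missing values, never as zero. The indices
measure field-of-view occupancy only — whether the fish actually fuses a
binocular percept is not knowable from the logs. Distance-resolved
profiles bin frames by mutual distance into 20 bins of 10 units over
[0, 200) and compute the percentages per bin. Approach episodes are also
split by remaining distance into high proximity (≤ 20 units, just under a
body length) and low proximity (> 100 units, the arena radius).

## Transfer entropy

Directed interaction is quantified with discrete transfer entropy

    T(P→Q) = H(Q_t | Q_{t−1:t−L}) − H(Q_t | Q_{t−1:t−L}, P_{t−1:t−L})

estimated by plugging empirical joint frequencies into Shannon entropies
(base 2, so bits; the choice of base cancels in every within-package
comparison). The default history length is L = 1, one frame = 100 ms.
ΔTE = T(A→B) − T(B→A) is the net flow. The plug-in estimate is clamped at
zero; no bias correction is applied — at the trial length of 18 000
frames and alphabets of 4–5 symbols the bias is far below the effects of
interest, and the null simulations in the test suite bound it directly.

Three symbolizations are used per trial:

* **merged ethogram** (K = 4): per frame, the pair of signs of the
  frame-to-frame change in speed and in heading direction, giving
  (++), (+−), (−+), (−−). Heading changes are wrapped (170° → −170° is a
  +20° turn). A zero change maps to '+'; only increase/decrease are
  meaningful states and ties at float resolution are rare in real logs.
* **speed** and **turn** (K = 5): the raw per-frame values split at the
  series' own 5/35/65/95th percentiles (linear-interpolation quantiles;
  values equal to an edge fall into the lower bin).

The estimator is verified three ways: exhaustive agreement with a
brute-force enumeration oracle on small alphabets, recovery of the
closed-form TE of a lag-1 copy channel (a follower that copies the
leader's previous symbol with probability c; TE = log2 K − H(channel
row)), and near-zero values on independent pairs at n = 10^5.

## Shock-protocol simulator

The stimulation schedule is simulated as a discrete-event system over a
bite-event stream: both fish receive the 0.5 V mild pulse for 300 ms at
the start of every 1 s cycle, phase-locked to trial start; a bite delivers
one 100 ms 4 V transient to the bitten fish (overriding a concurrent mild
pulse — higher voltage wins) and suppresses the biter's mild pulses for
2 min, after which the phase-locked schedule resumes (pulses are
suppressed, not phase-shifted). Conventions the protocol description does
not pin down, chosen here: a repeat bite inside an open relief window
restarts the window rather than stacking; mutual same-frame bites give
both fish the transient and both the relief; a pulse in progress at bite
time is clipped at the bite.

## Group statistics

Condition contrasts within the same animals (no-shock vs shock) use the
two-sided Wilcoxon signed-rank test on one averaged value per unit (fish
or pair — the caller declares the unit); group contrasts (WT vs TG) use
the two-sided Wilcoxon rank-sum test, with exact small-sample p-values
where the data permit. Identical paired samples are reported with p = 1.
The effect size is the standardized mean difference (μ1 − μ2)/σ with σ
the population (ddof = 0) standard deviation of the concatenation of both
groups; the classical pooled-within-group σ is available as an option,
since the verbal definition "based on both populations" admits both
readings. No multiple-testing correction is applied. α = 0.05.

## Synthetic data generator

`generate_dyad` integrates two kinematic point-agents at 10 Hz from the
standard start positions (50, 0) and (−50, 0), headings parallel. Per
frame, each agent's heading relaxes toward the opponent's bearing offset
by `lateral_bias` at rate `attraction_gain`, plus Gaussian heading noise;
agent A's speed is base speed plus noise, agent B's speed is a
`coupling_gain`-weighted copy of A's previous speed. Walls either steer
the agent back toward the center (default) or reflect its velocity;
positions are clamped inside the arena. Defaults: 18 000 frames (one
30-min trial), base speed 30 units/s (≈ 1.2 body lengths/s), speed noise
10 units/s, heading noise 15°/frame — an unremarkable wandering gait
for an adult zebrafish avatar in a 100-unit arena; all gains default to
zero, i.e. two independent agents.

The generator emulates the statistical structure the analyses assume —
mutual attraction, lagged directional coupling, lateral viewing bias,
monotone scripted approaches — not fish biomechanics: there is no tail
kinematics, no burst-and-glide speed profile, no collision between
bodies, and heading noise is white rather than autocorrelated. Passing
recovery tests therefore certifies the *estimators* (that each statistic
detects the structure it claims to, and reports null when it is absent),
not that real fish behave like the model. `generate_scripted_approach`
builds single-approach trials with an exact, known view-label sequence;
`generate_coupled_symbols` provides the analytic TE channel.

## Numerical choices and degenerate inputs

* Headings are wrapped to (−180, 180] everywhere; the wrap maps −180 to
  +180.
* Classification boundaries (±30°, ±135°, the 50-unit near threshold, the
  70-unit inner circle) are measure-zero decisions and are fixed as
  documented above.
* Trial logs are written with 6-decimal fixed precision and round-trip
  exactly at that precision.
* A constant distance series has no extrema and hence no approach
  windows; a constant value series occupies a single percentile bin;
  all-blind frame sets, zero-approach fish and zero-spread effect sizes
  are reported as missing, never coerced.
* Validation (`validate_trial`) is total: any input produces a report.

## Problem sizes in the verification suite

The test suite and the acceptance script validate Monte-Carlo properties
at sizes chosen to make the checks sharp but cheap: the attraction null
uses 200 independent 18 000-frame trials; gain-monotonicity uses 3 gain
levels × 30 replicates of 3 000 frames; lateral-bias recovery uses 100
replicates of 1 500 frames; episode exclusivity uses 100 random 600-frame
trials; TE oracle equivalence is exhaustive over all binary sequence
pairs up to length 5 (and ternary to length 3) plus seeded random pairs
up to length 12; the rank-test size is estimated from 10 000 null
replicates at n = 12 per group.

## Known limitations

* The 2D mid-body collider is a proxy for the rig's 3D physics engine;
  absolute bite counts on real logs depend on its two parameters.
* The deposited experimental data are not bundled; the CSV reader is the
  adapter point for mapping the archive's column layout.
* The plug-in TE estimator is biased upward at short series lengths;
  comparisons between conditions of equal length are unaffected.
* The scripted-approach generator produces piecewise-linear closing
  trajectories, adequate for boundary/label ground truth but not for
  speed-profile realism.
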