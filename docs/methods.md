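# Methods

This note documents the models, defaults and numerical choices behind
`icmspsych`, and what the synthetic-data tests do and do not establish
about real experiments.

## Data model

Stimuli are charge-balanced, cathodal-first biphasic pulse trains
(200 µs cathodal phase, 100 µs interphase gap, 400 µs anodal phase at half
amplitude), with amplitude limited to 2–100 µA and pulse frequency to
20–300 Hz. Electrodes sit on two physically separate 6 × 10 lattices with
32 wired sites each; grid coordinates are `(array, row, col)`, 0-based and
row-major — any fixed convention works as long as it is used consistently,
and this one is asserted by the round-trip tests. Unwired sites,
wired-but-untested sites and tested sites are three distinct states; only
tested sites enter the spatial statistics.

## Magnitude-estimation pipeline

**First-block exclusion.** Participants settle on a self-selected rating
scale during each session's first block, so the pipeline removes every
trial whose block index equals the *minimum* block index of its
(electrode, day) set — robust to files whose blocks are numbered from 0, 1
or anything else. The synthetic generator gives this rule something to do:
it adds a configurable additive bias (default 0.5 rating units) to every
first-block trial, and a test verifies that exclusion removes the bias
from the profiles exactly.

**Screening.** Each electrode's retained blocks (pooled across days; day
is deliberately excluded as a cofactor) form the replicates of a Friedman
test with pulse frequencies as treatments; incomplete blocks are dropped,
not imputed. The Friedman statistic is computed in-package — scipy's
implementation refuses two-treatment designs, which the shape-invariance
test needs — with the chi-square approximation (df = k−1) by default and
an exact (k!)^n permutation enumeration for small designs; scipy
cross-checks the statistic and p in the test suite. Multiple comparisons
use Benjamini–Hochberg with the critical-p convention: the critical p is
the largest sorted p(i) ≤ (i/m)·α, everything at or below it is
significant, and the critical p is 0 when nothing passes.

**Fits.** Amplitude series (fixed 100 Hz, 1 s) are fit by least squares;
when data span several sessions, responses are first divided by their
session median so differently-scaled rating sets are commensurate.
Duration series are fit with a 3-parameter logistic
`L / (1 + exp(−k(t − t₀)))` initialised at L = max response, t₀ = median
duration, k = 1, with a deterministic ladder of rate perturbations
(×1, ×0.5, ×2, ×0.25, ×4) as restarts; the best converged SSE wins and a
diagnostic error is raised if nothing converges.

**Shape invariance across amplitudes.** Whether the frequency–intensity
*shape* changes with current amplitude is tested after dividing each
amplitude condition by its median (removing a pure gain change). A plain
rank test of the amplitude main effect cannot detect the interesting
alternative — a peak that moves from 20 Hz to 300 Hz is a symmetric
interaction whose rank sums cancel — so the package tests the
amplitude × frequency interaction directly: within-replicate differences
between the two normalized conditions enter a Friedman test with
replicates as blocks and frequencies as treatments. Exactly two amplitude
conditions are compared per call (multi-amplitude designs are compared
pairwise). A pure gain change leaves the differences exchangeable across
frequencies; a moving peak makes them frequency-dependent.

**Parametric gate.** Where a parametric/non-parametric choice arises, an
Anderson–Darling normality check at the 5% critical value decides, and the
outcome is logged.

## Categorization

Intensity features are the raw mean ratings at 20, 100 and 300 Hz —
deliberately not per-electrode normalized, because the categories differ
in overall rating level and normalization would erase that separation.
k-means uses squared Euclidean distance, k-means++ initialisation, 50
restarts and a logged seed; clusters are named by their centroid's peak
frequency (20 → LFP, 100 → IFP, 300 → HFP; for k = 2 the lower-peaking
cluster is LFP), and a shared peak is a hard naming error rather than a
silent guess. k is selected as the silhouette argmax over 2–6, with the
inertia curve emitted for elbow inspection.

Quality features fold the four participant-coined descriptors onto the ten
standard ones (tapping → pressure, buzzing → vibration, prick → sharp,
sparkle → tickle; the coined percepts were described as combinations of
standard ones, and the alias table is configuration, not a claim), then
divide each quality column by its maximum report count over electrodes so
each reported quality spans (0, 1]. No dimensionality reduction. Partition
agreement is the adjusted Rand index; category–quality association uses
two-sided Fisher exact tests on 2×2 tables of (reports, non-report
stimulations) per category pair, BH-corrected across all pairs × qualities
at a frequency. Sample sizes here are tens of stimulations, which is why
the exact hypergeometric tail is used instead of a chi-squared
approximation.

## Spatial statistics

The adjacency fraction counts tested electrodes with at least one
same-category tested neighbour and divides by the number of tested
electrodes that have any tested neighbour; degree-0 sites are excluded
from both numerator and denominator, which makes the statistic a
well-defined proportion in [0, 1]. The alternative denominator (all tested
electrodes) is available behind a flag; the default is a documented
reading, not an assertion about intent. Rook (4-neighbour) adjacency is
the default as the minimal, conservative reading of "adjacent"; queen
(8-neighbour) is a flag. Arrays are physically separate, so no edges cross
arrays — but permutations redistribute labels across both arrays jointly.

The pseudo p-value is the plain proportion of permutations whose fraction
is ≥ the observed one (ties count toward the tail, no +1 correction), so
it can be 0 when no permutation reaches the observed value. The
Monte-Carlo path is vectorised (permutation matrices in chunks, edge-wise
same-label accumulation); the exact path enumerates all multiset
permutations of the labels (bounded at 10⁶ arrangements) and is the oracle
the Monte-Carlo estimator is tested against, at desk scale (≤ 9 sites),
to within 3 binomial standard errors at 100 000 simulations.

## Detection

The staircase lowers amplitude by 2 dB after three consecutive correct
responses and raises it by 2 dB after any error, so every tested amplitude
lies on the exact ladder `start × 10^(k/10)` until clamping at the 2/100 µA
stimulator limits. Direction bookkeeping: a direction exists only after
the first actual movement; the first step sets the direction without
counting a change; steps pinned at the floor/ceiling neither set nor flip
it. The run stops when the fifth direction change registers, and the
threshold is the mean of the 10 amplitudes on the trials immediately
*preceding* (and excluding) that trial; the inclusive reading differs by
one step and is exposed as `include_reversal_trial=True`. A `max_trials`
guard (200) converts pathological runs — e.g. an observer that is always
correct marching to the floor — into an error carrying the history, since
a simulation has no human in the loop to stop it.

The simulated observer has a logistic psychometric function in dB
amplitude with a 0.5 guess rate (2AFC) and a small lapse rate (default
0.02), anchored so that P(correct) at `threshold_uA` is exactly
0.5^(1/3) ≈ 79.4% — the convergence point of the 1-up-3-down rule — which
makes "estimator bias" well defined. Default slope is 1 per dB. Over 1000
seeded runs the mean estimate sits within ±1 dB of the true threshold
(measured bias ≈ +0.3 dB, consistent with the estimator's known slight
upward bias from the error-triggered up-steps).

The fixed-amplitude task presents each frequency 30 times, randomly
interleaved (90 trials per electrode for the standard three frequencies)
at 1.2× the 100 Hz threshold. Default per-frequency thresholds
(60 / 15 / 11 µA at 20 / 100 / 300 Hz) encode the finding that higher
pulse frequencies are detectable at lower amplitudes; at the standard test
amplitude of 18 µA this places 20 Hz far below its own threshold (near
chance accuracy) and 300 Hz well above. Note a stationary observer
anchored at 79.4% cannot score *below* 79.4% at 1.2× its own threshold, so
mid-frequency accuracies in the simulation run higher than a human's
would; the ordering and the chance-level 20 Hz behaviour are the modelled
features.

## Synthetic participant

Archetype frequency–intensity curves are piecewise-linear over the nine
standard frequencies (20–300 Hz), on a 0–4 rating scale: LFP peaks at
20 Hz and declines; IFP peaks at 80 Hz with the highest overall median;
HFP rises monotonically to 300 Hz with the lowest overall median. These
knot values are configuration with validated qualitative constraints, not
constants. Amplitude scales responses linearly (1%/µA around the 60 µA
reference); duration scales them through a saturating logistic normalised
to 1 at 1 s.

Rating noise is multiplicative log-normal (σ = 0.2 by default): free
magnitude estimation is a ratio scale, so noise should scale with the
rating and never produce negative values. Verbal magnitude-estimation
data do not pin down a rating variance a priori, so σ is a free parameter
recorded in generated metadata; σ = 0.2 gives single-trial ratings within roughly ±40% of the
mean, a realistic spread for verbal magnitude estimates.

Category maps are generated at fixed category counts: a uniform random
permutation at clustering strength θ = 0, annealed for θ > 0 by Metropolis
label-swap sweeps with acceptance `min(1, exp(θ·Δ same-label edges))` — a
fixed-composition Potts model, so counts are preserved exactly at any θ.
The default wired mask is a contiguous 4 × 8 block per array (real array
wiring is hardware-determined and irregular; a connected block keeps the
adjacency graph non-trivial and is stated, fixed layout rather than a
claim about any device). Quality counts are binomial per (category,
frequency, quality) with default probabilities encoding the qualitative
survey patterns: pressure/tapping/sparkle never occur on HFP electrodes,
buzzing/vibration/sharp are IFP-specific at 100–300 Hz, pressure fades at
300 Hz.

**What passing tests show — and don't.** Synthetic data are stationary,
balanced, and noise is homoscedastic on the log scale; real participants
drift within sessions, miss trials, and produce heavier-tailed ratings.
Recovery results (k selection, ≥ 90% label agreement, screening
sensitivity) therefore demonstrate correctness of the pipeline under its
own assumptions, not expected performance on human data.

## Problem sizes and tolerances

The test suite runs the spatial oracle comparison at 100 000 simulations
on ≤ 9-site graphs, null calibration on 500 random 64-site maps at 1999
simulations each (rejection rate required within 5% ± 2%, the slack
reflecting the discreteness of the permutation null), staircase
convergence over 1000 runs (±1 dB), category recovery over 100 seeds, BH
brute-force equivalence over 10 000 random p-vectors, and Fisher
exactness over 400 random tables with margins ≤ 30. The acceptance script
uses 30 recovery seeds, 200 calibration maps and 300 staircase runs, which
reproduce the same quantities at slightly wider Monte-Carlo error.
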