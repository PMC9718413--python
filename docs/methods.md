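# Methods

This note documents the models, numerical choices and known limitations of
`mmnfb`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal chain

The recording model is a single frontal EEG channel plus one EOG channel at
500 Hz with stimulus markers. The chain is fixed as
**filter → epoch → baseline → reject → average → peak**, all stages causal
and deterministic.

- **Filter.** Causal Butterworth band-pass, 0.1–35 Hz, 4th order per band
  edge (8 poles), applied with zero initial state (`scipy.signal.sosfilt`)
  so output at time *t* depends only on samples ≤ *t* — the same code path
  is valid online and offline. The passband gain at 10 Hz is 0.99998 and
  the stopband gain at 100 Hz is 0.0089 (asserted against the design's own
  transfer function in the tests). Family, order and band are configurable;
  a zero-phase variant was deliberately not used because the real-time
  system cannot be acausal.
- **Epochs.** Half-open window [−100, +500) ms around stimulus onset — 300
  samples at 500 Hz; the half-open convention avoids double-counting and
  gives round counts. Event times map to the nearest sample at or after
  onset. Windows that leave the recording raise a boundary error and the
  trial is skipped.
- **Baseline.** The mean over [−100, 0) ms is subtracted per channel;
  the operation is idempotent and the removed mean is recorded.
- **Artifact gate.** An epoch is rejected iff any baseline-corrected EEG
  *or* EOG sample strictly exceeds 40 µV in absolute value. "Strictly"
  follows the rejection rule's wording ("exceeded"); applying the gate
  after baseline correction is a fixed design choice (the order is not
  otherwise determined).
- **MMN score.** amplitude = |most negative sample of (deviant − standard
  average)| within 100–250 ms; latency = that sample's time; ties break to
  the earliest latency. The peak is a single-sample minimum, not a local
  minimum — the simplest deterministic reading.

## Online estimator

Warm-up requires exactly 16 accepted standards *and* 4 accepted deviants
(the 1:4 ratio over the first 20 trials); mere trial count is not enough,
because replacement is type-matched and the typed capacities are the only
self-consistent reading. After warm-up each accepted epoch replaces the
oldest of its own type and triggers a recomputation, so estimates update
once per 800 ms trial. Artifact epochs trigger nothing; the previous
estimate stays in force. The streaming estimate is provably identical to a
from-scratch batch average of the buffer contents, and the suite asserts
this equivalence trial-by-trial over many noisy sessions.

Calibration runs the identical chain in batch over a 200-trial tone oddball
(length configurable; the protocol does not pin it) and returns the
amplitude as the participant's maximal MMN. A floor of 0.5 µV guards the
subsequent normalization against division blow-up. The windowed-minimum
statistic is positively biased under noise (an extreme-value effect); the
tests quantify the bias by Monte Carlo rather than assuming it away.

## Game logic

All three games share one rule set; the scenario only changes labels.
Stage thresholds are exactly (0.20, 0.40, 0.50, 0.60) × maximal MMN, and an
attempt succeeds iff the routed amplitude *strictly* exceeds the threshold.
A stage is cleared when strictly more than half of its attempt block
succeeds. Two quantities the protocol leaves open are fixed as defaults and
configurable: 10 attempts per stage block, and one attempt per 30 sounds
(≈ every 24 s, matching continuous estimate availability after warm-up).
Stage state persists within a day and resets across days (also not
otherwise determined). Game order is drawn from the 6 permutations by a
Latin-square rule keyed on participant index + day index, so 6 consecutive
participants cover all orders and each participant's order rotates across
days. In yoked-sham mode the game reads a donor participant's recorded
estimate stream at the matching trial index and never the player's own.

## Synthetic data

The generator's defaults are the study conditions: 4 groups × 8
participants, 96 BAD trials per day (4 pair permutations × 12 per block ×
2 blocks), 12 NF sessions of 300 sounds at 800 ms SOA per training day,
60/240 deviants/standards per session with no two consecutive deviants
(sampled uniformly over non-adjacent subsets via the gap construction),
and a 200-trial tone calibration.

**EEG model.** Every sound evokes a stereotyped N1–P2 complex (−3 µV
Gaussian at 100 ms, σ 20 ms; +4 µV at 200 ms, σ 30 ms); deviants add a
Gaussian negativity at 170 ms (σ 40 ms) with peak −a, where *a* is the
controllable MMN amplitude. These shapes are inventions — the protocol
specifies none — chosen to put recovered amplitudes in a plausible µV
range. Crucially, the waveforms are defined **at the measurement plane**
(after the acquisition band-pass): the generator constructs the target
post-filter signal and pre-equalizes it by the inverse of the default
filter response (FFT division of the target spectrum by the filter's
frequency response, capped where the gain falls below 1 %, DC bin zeroed).
A 60 s lead-in lets the causal filter's start-up transient decay below
numerical noise. This makes "true amplitude" well defined independently of
the filter's passband sag — a raw-domain injection would be distorted by
1–3 % by the 0.1 Hz high-pass, leaving no exact ground truth for parameter
recovery. The residual round-trip error of the equalization is below
1e-4 µV and the suite asserts recovery to 1e-3 µV.

Noise is Gaussian, low-passed at 45 Hz and rescaled to `noise_sd`
(default 8 µV, a realistic single-trial amplitude for a frontal channel);
it is added in the raw domain and experiences the acquisition filter
normally, as do blinks: 150 µV Gaussian lobes (σ 60 ms) on EOG at
`blink_rate_per_min` (default 4), bleeding 10 % into EEG. Blinks are
rejected via the EOG threshold; the tests verify that they inflate the
rejection count without biasing the MMN estimate.

**Trajectories.** True MMN per training day is a fraction of the
participant's true maximal MMN (drawn N(6, 1) µV, clipped to ±2 SD):
0.45/0.55/0.65 across days for genuine-NF participants, flat 0.45 for
sham — a linear growth matching the direction of the reported day-3 >
day-1 effect; magnitudes are not calibrated to the original figures, which
publish only normalized group means.

**Behavior.** Per-trial correctness is Bernoulli with
logit(p) = x(group, day)·β + uᵢ, where β defaults to the 16 reference
coefficients of the original cohort and uᵢ ~ N(0, 0.1525). The counts-level
generator draws Binomial(n, p) directly — exactly the aggregated
distribution of the trial-level path — and the two are tested for
agreement.

**What passing tests do not show.** The simulator has stationary noise, a
single fixed evoked shape per participant, symbolic stimuli and a
policy-level responder; real EEG has non-stationarities, latency jitter
across trials and days, and real phonetic perception. Passing recovery and
calibration tests therefore validates the *machinery*, not claims about
real cohorts.

## Statistics

**Mixed logistic model.** The marginal likelihood (binomial constants
included) is maximized over (β, σ_u) with adaptive Gauss–Hermite
quadrature: an inner Newton finds each participant's posterior mode and
curvature, and an 11-node rule (1 node = Laplace; count configurable)
integrates the random intercept. Optimization is L-BFGS-B with σ_u bounded
in [1e-8, 10] and a binomial GLM as starting point. Fixed-effect
covariance is the inverse numerical Hessian at the optimum — full (β, σ)
Hessian so SEs reflect σ uncertainty, falling back to the β block when σ
sits on its boundary; forward differences first, central differences when
the forward result is not positive definite. The fit is cross-checked
against lme4's `glmer` (adaptive quadrature) in the suite; note `glmer`'s
reported logLik omits the binomial normalizing constants, so only
coefficients, SD and SEs are compared.

**Type III Wald tests** are block Wald χ² on the dummy-coded coefficient
groups: Group (df 3), Day (df 3), Group:Day (df 9). Under dummy coding the
Group block tests "groups equal on the reference day" and the Day block
"days equal in the reference group"; the interaction block is
parametrization-invariant, and the suite asserts exactly which blocks are
invariant under reference relabeling. Null simulations at a reduced cohort
confirm ~5 % type I error for all three terms.

**Contrasts.** log OR = (x_A − x_B)·β with delta-method SEs; families of
pairwise contrasts (6 group pairs per day, 6 day pairs per group) are
adjusted with the studentized-range distribution at asymptotic df —
the z-statistic analogue of Tukey's HSD. A Kenward–Roger correction is not
defined for a binomial GLMM, so asymptotic z statistics are used and
documented as a deviation; Sidak/Bonferroni are available for non-mean
families.

**Mixed ANOVA.** Classical balanced split-plot decomposition, 2 (NF) × 2
(BT) between × 3 (day) within: between effects tested against
subjects-within-groups (df ab(n−1) = 28 at n = 8), within effects against
the day × subject pooled error (df (c−1)ab(n−1) = 56 at n = 8), which also
supplies the MSe for simple main effects of day within each NF level and
the LSD day comparisons. The decomposition is verified against base-R
`aov` to 8 significant digits. For the 32-participant balanced design the
within-error df is 56; a published within-interaction df of 54 under this
design would imply 31 analyzed participants.

## Degenerate inputs and tie-breaks

- Empty epoch sets raise estimation errors; all-artifact calibrations and
  sub-floor maximal MMN raise calibration errors.
- A zero-variance ANOVA input yields F = 0 (effects below 1e-10 of a mean
  square are treated as zero, not divided by a zero error term).
- MMN latency ties break to the earliest sample; FIFO replacement is
  strictly oldest-first within type.
- Exhausted yoked donor streams raise a sham error rather than silently
  reusing feedback.

## Problem sizes in tests

The suite runs the estimator-oracle equivalence on 50 full 300-trial
sessions, the coefficient-recovery check on 20 cohorts at full study size,
and the Wald calibration on 500 reduced cohorts (16 participants, 48
trials/cell, 5 quadrature nodes); unit tests use smaller sessions. These
sizes keep the whole suite within a few minutes while leaving every
statistical check adequately powered.
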