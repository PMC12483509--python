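# Methods note

This note records the statistical model, the conventions the implementation
commits to, and the reasoning behind parameter defaults — including what the
synthetic generator does and does not emulate.

## Experimental structure assumed

Each recording session presents the canonical 11-stimulus panel (nine male
urine stimuli: 3 strains x {naive, dominant, castrated}; two ICR female
stimuli: non-estrus, estrus) in randomized blocks, typically five
presentations per stimulus. A trial consists of a 17 s pre-application
baseline, stimulus application, sympathetic nerve trunk (SNT) stimulation
20 s later, a response window ending 40 s after SNT stimulation, and an
inter-trial interval. Units are single neurons recorded in one session from
an animal whose reproductive state (estrus / non-estrus) is known.

## Response quantification

- **Windows.** Baseline: `[t_application - 17 s, t_application)`. Evoked:
  `[t_application, t_snt + 40 s)`. All windows are half-open so a spike on a
  boundary is counted exactly once, and baseline and evoked windows are
  disjoint by construction.
- **Magnitude.** Per trial, evoked rate minus that trial's own baseline rate;
  per unit x stimulus, the mean over the stimulus's trials. Per-trial
  baseline subtraction absorbs slow drift that a session-mean baseline would
  not. Fewer than 4 presentations triggers a warning (or an error in strict
  mode) because a 3-trial mean is dominated by single-trial Poisson noise.
- **Significance.** Two-group Kruskal–Wallis (equivalent to a two-sided
  rank-sum test) of the stimulus's evoked rates against the unit's baseline
  rates pooled over all trials of the session, at cell-level alpha = 0.05.
  Fully tied data (e.g. a silent unit) are defined as p = 1. Pooling
  baselines raises the reference sample size from 5 to ~55 per unit.
- **Normalization.** Per unit, divide by the maximal absolute response,
  optionally after zeroing nonsignificant cells; all-zero rows stay zero and
  the operation is idempotent. Normalized values lie in [-1, 1] with at
  least one cell at ±1 for responsive units.

A caveat worth stating: the evoked window (60 s) is much longer than the
baseline window (17 s), so under a homogeneous Poisson null the two rate
estimates have unequal variances. The rank test's type-I error is then
*conservative* (simulations with the real window geometry give ~0.7%
rejections at alpha = 0.05, versus ~5% when both samples share a
distribution). Calibration tests therefore draw both groups from the same
distribution; with the real geometry the test errs on the side of missing
weak responses, not inventing them.

## Receptive-field patterns

A pattern is a conjunction of conditions `min(preferred) > max(compared)`
with strict inequalities (ties fail), evaluated on the raw magnitude vector.
Basic patterns compare a preferred set against the rest of the panel; the
registry ships 8 (FEMALE, MALE, MALE per strain, and NAIVE/DOM/CAST across
strains) plus their complements (all inequalities reversed), a Bonferroni
family of 16. Adjusted patterns impose the preference within each strain (or
each virility status) separately, restricted to male stimuli: 6 + 6
complements, family of 12. The registry is a YAML file
(`aobpop/data/default_registry.yaml`) so the families can be audited or
replaced.

**Shuffle null.** Each iteration permutes every stimulus column of the
magnitude matrix independently, preserving per-stimulus marginal
distributions while destroying within-unit correlation structure, and
recounts each pattern. The p-value is the fraction of shuffles with a count
at least the observed count (observed-inclusive, so p is never exactly 0 in
spirit; the strict tail is available as an option). 100,000 shuffles is the
default for reported analyses; tests use fewer where the binomial error of
the p estimate is accounted for explicitly.

## Tuning metrics

- **Preference index.** `PI_AB = (R_A - R_B) / (R_A + R_B)` on *rectified*
  responses (negative magnitudes set to 0), in [-1, 1]. A unit enters a pair
  only if it responds significantly to at least one of the two stimuli, and
  is excluded when both rectified responses are 0 (which includes pure
  suppression — a deliberate consequence of rectification). |PI| is the
  pairwise selectivity.
- **Lifetime sparseness.**
  `S = [1 - (Σ|r_i|/N)² / (Σ r_i²/N)] / (1 - 1/N)` with N = 11; 0 for
  uniform, 1 for one-hot, defined as 0 for an all-zero vector (uniform
  limit). Two equal nonzero responses among 11 give exactly 0.9.
- **Selectivity index.** For a stimulus triplet, rectified responses are
  normalized to weights summing to 1 and placed in a triangle via three unit
  vectors 120° apart (first vertex at 90°);
  `Si = sqrt(Σ(w_k - 1/3)²) / sqrt(2/3)` equals the distance of the point
  from the triangle centre exactly (an algebraic identity the test suite
  verifies), so the plotted geometry *is* the statistic.
- **State test.** The difference between estrus and non-estrus mean PIs is
  tested by randomly reassigning included units to states (group sizes
  preserved); p is the fraction of reassignments with |Δmean| at least the
  observed value.

## Population geometry

Stimuli are columns of the normalized, nonsignificant-zeroed matrix.
Correlation distance is 1 - Pearson (range [0, 2]); a zero-variance column
(no responsive units) has no defined correlation and is assigned distance 1
with a logged warning. Representational stability across states is the
Pearson correlation of the 55 pairwise distances — reported with the caveat
that pairwise distances are not independent, so the attached p-value is a
descriptive convention.

Classical (Torgerson) MDS is implemented directly (double-centre -D²/2,
eigendecompose, keep the top-k nonnegative eigenpairs) rather than via an
iterative stress minimizer, because the classical solution is deterministic,
seed-free, and matches the textbook definition. Correlation distances are
generally non-Euclidean, so negative eigenvalues are clipped (and logged) and
the embedding is reported with its mean absolute distance error and the mean
original distance for scale.

## State comparisons

- **Responder fractions.** Min-of-four-tails binomial exact test: under the
  pooled responder probability, the smallest of P(X₁≥k₁), P(X₁≤k₁),
  P(X₂≥k₂), P(X₂≤k₂) without doubling. This is deliberately sensitive and
  nonstandard (roughly half a two-sided p); outputs carry the caveat in
  metadata so downstream users are not misled.
- **Magnitudes.** Per-stimulus two-group Kruskal–Wallis, Bonferroni alpha/11;
  plus a stimulus x state two-way ANOVA (full model with interaction,
  type-II sums of squares — appropriate for unbalanced state group sizes).
- **Pattern frequencies.** The same binomial convention per pattern,
  Bonferroni alpha/16 (basic) and alpha/12 (adjusted).
- **Selectivity.** 23 ethologically grouped pairwise comparisons (1
  female–female, 4 male–female, 9 status-within-strain, 9
  strain-within-status), Kruskal–Wallis on |PI| at alpha/23.
- **Rank Tukey–Kramer.** Follow-up pairwise stimulus comparisons on jointly
  ranked magnitudes with tie-corrected variance, corrected via the
  studentized range distribution with infinite degrees of freedom.

## Synthetic generator

Spikes are drawn from a piecewise-homogeneous Poisson process: baseline rate
outside the evoked window, baseline plus a per-stimulus rate change inside
it. Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| baseline rate | lognormal(0, 1) Hz | median 1 Hz, heavy right tail — typical of AOB spontaneous rates; strictly positive |
| p_excitatory | 0.85 | responses are predominantly rate increases; suppression exists but is the minority |
| effect size | gamma(2, 1.5) Hz | mean 3 Hz, mode ~1.5 Hz: mostly modest changes with occasional strong ones, comfortably detectable at 5 trials |
| breadth mixture | mode at 1, mass 0.25 at 0, 0.06 at 11 | emulates a population dominated by narrowly tuned units with an unresponsive fraction and a minority of broadly responsive units |
| trials/stimulus | 5 | the analysis minimum of 4 plus one |
| timing | 17 + 20 + 40 + 18 s | matches the analysis windows; the ITI keeps slots disjoint |
| matrix_noise_sd | 0.5 Hz | matrix-level shortcut only: roughly the trial-averaged rate-difference SE at typical rates |

Structure can be implanted: a configured fraction of units per state is
built to fulfil a named pattern (preferred rate changes ~U(2.5, 4) Hz,
compared ~U(0, 1) Hz, asserted against the pattern definition), and
state-specific multiplicative gains can be applied to chosen stimuli.
Negative total rates are clipped at 0 Hz with a warning.

Randomness is organized with `numpy.random.SeedSequence(seed).spawn()`:
independent streams for ground truth, trial schedules, and each unit's
spikes, so output is bit-reproducible for a given seed and insensitive to
unit iteration order.

**What the generator does not emulate:** spike-sorting artifacts and unit
contamination; adaptation, habituation, or any within-session
nonstationarity; temporal response dynamics inside the evoked window (the
rate change is flat); correlated noise between simultaneously recorded
units; and inter-animal variability beyond the two-state split. Conclusions
about those phenomena cannot be validated with it. The waveform
`shape_symmetry` QC metric is provided for real data but has no synthetic
counterpart.

## Numerical choices

- Exact rational constants are kept at full precision; Bonferroni
  thresholds are rounded only for display.
- The shuffle null is evaluated in batches with per-column permutations from
  argsorted uniform keys, with memoized group min/max reductions composed
  from reusable column blocks; correctness against a direct recount and
  determinism across batch sizes are tested.
- Permutation p-values are observed-inclusive (`ge`), the conservative
  convention; the strict tail is available where needed.
- CSV output writes times with `%.17g` and reads with round-trip float
  parsing, making dataset round trips bit-exact (and tested as such).

## Limitations

- The binomial state test's min-of-four convention inflates sensitivity;
  treat near-threshold results with care (the caveat travels with the
  output).
- The cell-level response test is conservative under the real
  unequal-window geometry (see above), biasing responder fractions downward
  for weak responses.
- Pairwise-distance correlations and MDS diagnostics are descriptive; no
  inferential claims are attached to them.
- With few units per state, zero-variance stimulus columns appear after
  zeroing nonsignificant responses; their imputed correlation distance of 1
  is a convention, and affected analyses log it.
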