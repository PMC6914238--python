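# Methods notes

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the places where the design was genuinely open.

## Screening model

The four exclusion criteria form a multiple-hurdles rule: a respondent is
excluded when *any* criterion flags. All criteria are computed in the
respondent's own presentation order, because the patterns they target
(straight-lining, mechanical alternation) are artifacts of the rendered
questionnaire, not of the catalog order.

**LongString (criterion 1).** Longest run of consecutive "yes" responses
over the 42-item lifetime prescription block; the flag requires the run
to reach 22 items (over half the block) *and* to span at least two drug
classes, so a genuine heavy user of one class cannot trip it. Ties
between equal maximal runs resolve to the earliest run.

**Even-odd consistency (criteria 2 and 3).** The even-odd index is
defined in the careless-responding literature for multi-item rating
scales; for a binary endorsement block its computation is
underdetermined. Two operationalizations are provided:

- `serial` (default): Pearson correlation between the response sequence
  and itself shifted by one presentation position. This is the only
  variant that yields −1 for strict alternation, ≈0 for random
  responding, and is undefined (NaN) for constant rows — the three
  properties the index needs here. A positional odd-half/even-half
  pairing fails the first property: for a strictly alternating row both
  halves are constant and the correlation does not exist.
- `split`: the positional pairing (odd-position vector vs even-position
  vector, paired element-wise, trailing element dropped), for
  comparability with split-half conventions.

Undefined correlations never flag: the modal honest row (about 91% of
respondents endorse nothing in the last 12 months) is constant, and
flagging it would be absurd. Thresholds are strict inequalities
(flag when r < −0.6 on the 42-item prescription block, r < −0.8 on the
10-item illicit block); the stricter illicit threshold compensates for
the much shorter block, where moderate negative correlations arise by
chance more easily.

**Overendorsement (criterion 4).** Count of last-12-month products
endorsed out of 298, flagged at ≥ 35 (boundary inclusive — the cut is
described as conservative, and an inclusive reading is the conservative
one). The cut sits far above the endorsing-respondent median (~3).

**Validation metrics.** Mahalanobis distances are computed over the
combined lifetime prescription + nonprescription + illicit matrix with
the sample mean and covariance; when the covariance is singular (binary
blocks routinely contain zero-variance items) a ridge
`eps = 1e-6·trace(S)/p` is added. Contradiction counts compare
first-use vs most-recent-use answers on the shared four-level recency
scale; a most-recent answer strictly less recent than the first-use
answer is a contradiction. The introductory-timing rule (<16 s over the
introductory questions) is computed and reported but never flags — it
adds no discriminatory value over the four criteria, and is kept only so
other datasets can re-evaluate it.

## Raking

Weights start at the uniform base weight `w_b = N/n` and are updated by
classic IPF sweeps in the order the scheme lists its variables (the
fixed point does not depend on this order; the path does, so the order
is fixed and recorded). Two tolerances appear:

- the **stopping rule** is on weighted marginal *proportions* — every
  scheme variable within 0.1 percentage points (1e-3) of target. The
  proportion rule is scale-free, which avoids the classic
  percent-vs-proportion bug;
- the weighted-*frequency* discrepancy (persons) is computed and
  reported against a 0.1 reference, for comparability with raking
  software that reports frequency tolerances.

Target categories absent from the sample are dropped from that
variable's constraint with a warning and the remaining proportions are
renormalized (incomplete stratification); a sample category with no
positive target is an error, since raking would have to assign it zero
or undefined mass. Weights stay positive by construction and are never
trimmed; a `w > 5·median` count is reported so extreme weights surface
on other data. `max_iter` (default 100 full cycles) exceeded returns the
current weights flagged unconverged rather than raising.

## Benchmark scoring and scheme selection

`D_i = 100·|p_i − π_i|/π_i` is scale-invariant, so estimates and
benchmarks may be supplied on any common scale; the package carries
proportions internally and percentages only at report boundaries.
Reference/complement levels of binary or exhaustive benchmark variables
carry `included=false` and do not enter the average (their D_i is
redundant with the included level); inclusion flags are data, not logic.

The candidate set is the unweighted baseline plus the core demographics
unioned with every subset of the optional variables — with five optional
variables, 33 configurations. The relative standard error of a benchmark
estimate is `SE/estimate`, averaged over included benchmarks. Selection
uses a parsimony rule: the smallest scheme whose D̄ is within 1
percentage point (of D̄) of the global minimum. This replaces a visual
choice with a reproducible one; the slack is configurable. D̄ is also
split into health vs nonhealth benchmark groups, since weighting on
health-related variables moves health benchmarks far more than
demographic ones.

## Estimation

Weighted prevalences are Hajek ratio means; their variance is the
single-stage Taylor linearization
`V = (n/(n−1))·Σ w_i²(y_i − p̂)² / (Σw)²` with z = 1.96 intervals
truncated to [0, 1]. Quota strata are deliberately ignored in the
variance: the base sample is self-weighting and the strata are
recruitment controls, not sampling strata. With an opt-in panel the
intervals describe precision within the sampling framework rather than
true frequentist coverage — inference should always be read jointly with
how the sample was obtained and weighted. No finite-population
correction (n ≪ N), no degrees-of-freedom adjustment (large n). Cells
with fewer than 5 unweighted respondents are marked suppressed;
suppression is a display convention and never alters stored values.

The order-effect diagnostic reports the endorsement rate at each
presentation position and a Spearman trend test across positions. It is
a diagnostic only; no correction is applied. Note that with
heterogeneous item prevalences, block randomization itself induces real
position-composition structure (late positions can only host certain
class layouts), so a detected trend is not automatically a respondent
fatigue effect; the null-calibration tests therefore use a
uniform-prevalence design, where any trend is spurious by construction.

## The synthetic generator

The generator emulates the structure the pipeline assumes, with all
randomness drawn from one seeded NumPy generator (same seed, same panel,
byte for byte):

- **Quota strata**: 8 sex × Census-region cells with targets from the
  2017 adult-population marginals and a −25%/+10% acceptance band. The
  default fill factors (male 1.08, female 0.88) reproduce the observed
  ~54% male completed sample against a 48.7% target while staying inside
  the band. Panels too small to give every stratum a feasible quota are
  rejected.
- **Demographics** are drawn from national-ish marginals tilted by
  selection-bias odds multipliers. The default bias direction — older,
  lower-income, less healthy, more smoking — mirrors the observed
  online-panel skew. Household size, health status, activity limitation
  and smoking marginals are package defaults (invented, realistic);
  income follows the published distribution renormalized to sum to one.
- **Endorsements** follow a two-class mixture: a latent "drug-involved"
  indicator gates endorsement, and conditional item prevalences are set
  to `p_j / P(user)` so the configured marginal `p_j` is preserved.
  Defaults: 25% lifetime involvement; 9% last-12-month involvement
  (hence ~91% empty product rows, matching the observed zero-endorsement
  mass) with conditional product prevalences decaying as `1/(rank+8)`
  scaled to ~4 endorsements per user (endorsing median ≈ 3). Last-12-
  month involvement is tilted by age and smoking multipliers (normalized
  so the population mean stays at 9%), which is what lets calibration
  demonstrably de-bias drug-use estimates. Opioid lifetime prevalences
  scale with the published dispensing volumes. Beyond the shared latent
  indicator, items are conditionally independent: real inter-item
  correlation (poly-use patterns) is *not* modeled, so passing tests say
  nothing about detector behavior under strong honest item clustering.
- **Presentation orders** are block-randomized per respondent: class
  order uniformly random, item order uniform within class.
- **Careless profiles** overwrite honest draws: straightliners write an
  unbroken run (default the full 42-item block); alternators write
  strict yes/no alternation with a per-item flip probability
  (defaults: 0.02 on the prescription block, 0 on the illicit block —
  fixed by a design-stage power analysis against the −0.6/−0.8
  thresholds, since on a 10-item block even 1% noise lets alternators
  escape the −0.8 cut); overendorsers endorse `40 + Poisson(25)` random
  products; speeders scale section times by 0.3. Careless rows plant a
  contradictory timeline pair with probability 0.4; honest rows never
  contain planted contradictions. Default planted rates (0.1%, 0.1%,
  0.05%, 0.3%) keep the overall careless fraction near the ~0.5%
  observed in fielded panels. Speeders are not in the default planted
  set: the timing rule is reported-only, so no criterion can recover
  them by design.
- **Section times** are log-normal (median 110 s for the prescription
  section, σ=0.45; median 45 s introductory, σ=0.40).
- An optional linear **position effect** multiplies endorsement
  probabilities by `1 − β·position/(m−1)` for order-effect power
  studies.

## Problem sizes in the test suite

The suite favors the smallest sizes at which each property is sharp:
panels of 800–2,500 respondents for unit-level behavior, 4,000–8,000 for
bias-recovery and attrition properties, one 30,000-respondent panel for
planted-profile recovery at fielded scale, 1,000 replicates for interval
coverage, and 200 seeded generator runs for the order-effect null
calibration. The full suite runs in well under a minute on one CPU.

## Known limitations

- No nonresponse adjustment: information on nonresponding panelists is
  not available from panel vendors, and none is modeled.
- The variance estimator ignores quota strata and weight estimation;
  intervals are precision descriptions, not true coverage statements.
- The even-odd index for binary blocks is an interpretation (two modes
  provided, documented above).
- The generator's honest-correlation structure is a single shared latent
  class — a stand-in, flagged as such, not an estimate of real inter-item
  dependence.
- Propensity-score and sample-matching weighting, bounded/logit raking,
  and machine-learned careless detection are out of scope.
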