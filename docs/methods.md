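# Methods

This note documents the models implemented in `affectvar`, the choices made
where reasonable alternatives exist, and what the synthetic-data generator
does and does not emulate.

## Circumplex scoring and variability metrics

Affect reports come from a 16-adjective checklist rated 1–9, with four
subscales: positive-activating (3 items), positive-deactivating (3),
negative-activating (6), negative-deactivating (4). Subscales are scored as
**item means** (not sums), so all four share the 1–9 response metric and the
composites `valence = (PA + PD) − (NA + ND)` and
`activation = (PA + NA) − (PD + ND)` lie in [−16, 16]. Item-sum scoring is
available (`aggregate="sum"`) but changes only the scale, not correlations.

Per person, the variability metrics over the session series are:

- **valence / activation variability** — plain SDs of the two composites;
- **pulse** — SD of the vector lengths `d_t = √(valence² + activation²)`,
  measured from the neutral origin (not from the person's mean affect
  point; the origin convention follows the displayed distance formula in
  the tradition this measure comes from, and the alternative would fold
  mean affect into the intensity metric);
- **spin** — the circular standard deviation `√(−2 ln ‖R‖/n)` of the
  angular positions, where `‖R‖/n` is the mean resultant length of the
  per-session unit vectors. The same quantity without the radical
  (`variant="neg2log"`) is exposed because the measure is sometimes
  displayed that way; the square-root form is the standard circular SD that
  the verbal definition names, and it is the default.

Numerical conventions:

- All SDs use the sample (n−1) denominator by default (`ddof`
  configurable), matching common psychometric practice.
- A session at the exact origin has no direction: it is excluded from the
  unit-vector sum (with the count reported in the profile) but contributes
  distance 0 to pulse. Fewer than two usable sessions raises an
  insufficient-data error carrying the counts rather than returning NaN.
- `‖R‖/n = 0` (perfectly cancelling directions) yields a spin of +∞;
  downstream model fitting refuses non-finite predictors with an error
  naming the affected participants instead of silently imputing.
- `‖R‖/n` is clamped to [0, 1] against floating-point overshoot so the
  bound invariants hold exactly; spin is exactly 0 iff the ratio is 1.
- Missing sessions are tolerated: metrics are computed over the available
  sessions with `n_sessions_used` recorded; no imputation.

## Performance scoring and screens

A trial score is `100 × (kills/(kills + deaths) + rank_term)`. The rank
component of the source formula is cited to earlier work without a numeric
definition; here `rank_term = (n_competitors − place)/(n_competitors − 1)`
∈ [0, 1] (1 = first place), which keeps both addends on comparable scales
and the score bounded near [0, 200]. Consecutive trial pairs are averaged
into session scores (28 trials → 14 sessions).

A trial with `kills + deaths = 0` is uninformative and is flagged as a
*flatline* (its session's performance becomes NaN) rather than scored.
Participants are excluded with a reason code when any session is missing
(`incomplete`) or when at least 2 sessions flatlined (`flatline`;
threshold configurable — "repeatedly" is not defined more precisely in the
source tradition). The screen is deterministic and order-independent.

The video-game-experience composite z-scores its four items within cohort,
averages each frequency/hours pair, then averages the pair means; its
cohort mean is 0 by construction and its SD is ≈1 but not exactly 1
(an average of correlated z-scores).

## Discontinuous growth design

For `n_sessions` sessions with a change after session `c` (study default
14 and 7), session `s` receives codes `SA = s−1`, `TA = 1{s > c}`,
`RA = max(0, s−c−1)`, `SA² = min(s−1, c−1)²`, `RA² = RA²`. TA is read
relative to the value SA predicts just after the change; RA is the
post-change slope relative to the pre-change slope. The quadratic
acquisition code freezes at its last pre-change value, `(c−1)²`, so
post-change curvature is carried entirely by RA²; this generalises the
cap of 36 = 6² in the 14/7 design to arbitrary change points.

## Mixed-model fitting and bookkeeping

All models are two-level linear mixed models with a participant random
intercept only, estimated by **maximum likelihood** (not REML) so that
log-likelihoods are comparable across the fixed-effect ladder.
Estimation is delegated to `statsmodels` `MixedLM`; the optimizer tries
lbfgs first and falls back to bfgs/cg/powell on the occasional singular
Hessian. The degenerate `fix_tau2=0` fit is computed in closed form
(normal equations + ML residual variance) and equals OLS, which the tests
verify against an independent OLS implementation; a hand-written profiled
marginal likelihood serves as an oracle for the general fit on small
instances.

Denominator degrees of freedom follow a two-level counting convention:

- a term is **level-1** iff it contains a time code (SA, TA, RA, SA², RA²):
  `df = n_obs − n_participants − (number of level-1 terms)`;
- every other term — *including* session-level effort and trait × effort
  products — is **between-person**:
  `df = n_participants − (number of between terms) − 1`.

Classifying effort as between-person is deliberate: it is the convention
under which the rule reproduces the full set of dfs reported for this
design (2777, 2775, 2771, 2769, 2763 at level 1; 203, 201, 200 between,
for 2996 observations on 214 participants), even though effort varies
within person. One reported df (a t(200) for a trait main effect in the
full two-way performance model, where the rule gives 198) is internally
inconsistent with the others and cannot be resolved without the original
software's bookkeeping; the rule is reproduced, not rationalised.

The model ladders are refitted from scratch at each step on identical
rows: for effort — time codes; + covariates; + spin/pulse mains; + SA
products; + TA/RA products. For performance — the same through the trait
mains, then + effort, + all two-way products, + the six three-way
trait × effort × time-code products. A quadratic reacquisition term that
is non-significant at step 1 (two-tailed, α = .05) is dropped from all
later steps. p-values are two-tailed by default with one-tailed values
reported alongside; the hypothesis report flags the TA/RA-interaction
families as the directional tests evaluated one-tailed.

Covariates are not centred by default; simple-slopes tables evaluate
predicted trajectories at moderator mean ± 1 SD with all other predictors
at their grand means. The ancillary refits substitute emotional stability
for every spin/pulse term (products collapse 2 → 1; trait mains map onto
the emotional-stability covariate already present).

## Synthetic-study generator

The generator emulates the study conditions: 214 participants × 14
sessions × 2 trials, change after session 7. Per participant *i*:

- **Affect directions** `θ_t ~ wrapped normal(μ_θi, σ_θi)`. The wrapped
  normal is the default because its circular SD equals `σ_θ` exactly,
  making spin-recovery targets analytic; a von Mises option matches its
  κ to the same circular SD. Sessions are drawn independently — real
  affect series are likely autocorrelated, a simplification to keep in
  mind when generalising test results.
- **Affect intensities** `d_t ~ N(μ_di, σ_di)` truncated at 0 (the small
  truncation bias on pulse is tolerated in stochastic tests).
- **Person parameters**: spin targets `σ_θi` are drawn from a truncated
  normal anchored at the cohort descriptives (mean 0.83, SD 0.51, floor
  0.05) and pulse targets `σ_di` likewise (2.49, 0.94, floor 0.2). The
  circumplex location parameters are not reported anywhere, so they were
  fixed once at plausible values: `μ_θi ~ N(0.5, 0.6)` rad (mostly
  pleasant-activated reports) and `μ_di ~ N(8, 2.5)` truncated at 1
  (comfortably inside the [0, ~22.6] attainable intensity range).
- **Subscale back-fill**: PA/ND and PD/NA are solved around scale-midpoint
  baselines (5) as `PA = 5 + (v+a)/4`, `ND = 5 − (v+a)/4`,
  `PD = 5 + (v−a)/4`, `NA = 5 − (v−a)/4`, clipped to [1, 9] with clipping
  flagged per row; the inversion reproduces the composites exactly on
  unclipped rows.
- **Outcomes** follow the discontinuous growth model with the full
  cross-level structure; default coefficient vectors encode the reported
  effect pattern for each outcome (effort rising at the change then
  decaying; performance improving pre-change, dropping ~19 points at the
  change, reacquiring more slowly, with harmful spin/pulse terms). The
  variance components are not reported for the original fits, so they
  were chosen once to bring the marginal outcome SDs near the printed
  descriptives: effort τ = 1.55, σ = 1.10; performance τ = 8, σ = 9.
  Effort is generated first and enters the performance predictor.
- **Trials** invert the trial-score formula: each trial takes the feasible
  rank-grid point nearest a uniform draw, so the kill ratio absorbs the
  residual and integer rounding of kills (Poisson-drawn engagement counts,
  mean 14) is the only inversion error. Flatline participants can be
  injected to exercise the exclusion screen.
- A single seed expands into per-participant substreams
  (`SeedSequence.spawn`), so any subset of participants reproduces
  bit-identically regardless of cohort size.

**What passing tests show, and what they do not.** The generator draws
i.i.d. sessions from the exact parametric families the metrics and models
assume; recovery results therefore certify the pipeline's arithmetic, not
robustness to autocorrelated affect, non-normal outcomes, skill-dynamics
misspecification, or item-level measurement error (items are back-solved
from composites, not generated from an item-response model).

**A note on dispersion-estimate attenuation.** A person's spin/pulse is
estimated from only 14 sessions, so it carries sampling noise of order
`σ/√(2·13)`. This attenuates the correlation between realized and
generating dispersions to ≈0.88 (spin) and ≈0.83 (pulse) at cohort scale —
a property of the study design, not the cohort size: with 56-session
series the same generator yields r ≥ 0.94. The tests assert both the
attainable 14-session level and the recovery of high correlation with
longer series. The same noise slightly biases mean realized spin below
`σ_θ` (≈0.763 at σ_θ = 0.8 with 14 sessions), which stays within the
±0.05 recovery band used in the tests.

## Problem sizes used in the test suite

Structural and property tests run on 20–30-participant cohorts; parameter
recovery refits the step-1 model on 200 replicates at full study scale
(214 × 14); null calibration of the trait terms uses 500 replicates at
full scale; spin recovery uses 500 persons. These sizes keep Monte-Carlo
error well below the asserted tolerances.

## Known limitations

- Only one change point; no continuous-time (unequal-spacing) codes.
- Random-intercept-only covariance; no random slopes, autoregressive or
  heteroscedastic residuals, and no Bayesian estimation.
- The rank term in the trial score is a documented stand-in for an
  operationalisation the source literature does not define numerically.
- The level-1/between df bookkeeping is a reproduction of reported
  conventions, not a claim about optimal inference; Satterthwaite or
  Kenward-Roger approximations would differ.
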