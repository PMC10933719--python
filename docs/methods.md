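# Methods

## The measurement model

All scoring rests on single-parameter hyperbolic discounting,

    V = A / (1 + k D),

with `V` the immediate (indifference-point) value in US $, `A` the delayed
reward ($100 throughout the default banks), `D` the delay in days, and `k`
the discounting rate per day.  Larger `k` means steeper devaluation of
delayed rewards.

Each continuous item fixes two of the three quantities and lets the
respondent set the third on a slider:

* **Time-selection** items fix `V` ∈ {10, 30, 40, 50, 70, 80, 99} and ask
  for the longest acceptable wait `D`; inversion gives `k = (A/V − 1)/D`.
* **Monetary-selection** items fix `D` ∈ {1, 7, 14, 30, 91, 182, 364} days
  and ask for the acceptable immediate amount `V`; the same closed form
  applies.

The per-person, per-occasion scale score is the geometric mean of the item
rates, `k_gm = exp(mean(ln k_i))`; all downstream statistics operate on
`ln k_gm` because rates are approximately log-normal.  The log is natural;
base only shifts scale.

### Units and calendar conventions

The canonical time unit is the day.  One year = 364 days (52 weeks exactly,
consistent with the 52-week time slider), 6 months = 182, 3 months = 91,
1 month = 30, tomorrow = 1.  These conversions live in one place
(`items.parse_delay`) and bank configs may override any delay in days.

### Slider floor, clamping, rounding

The time slider nominally starts at 0 weeks, but a zero wait is
non-invertible (division by zero) and the deployed instrument's effective
floor is one day.  Scoring therefore clamps delays below `min_delay_days`
(default 1.0) up to the floor and records a `clamped` flag per response;
both the floor and the upper bound are configurable on the bank.  Monetary
sliders run $1–$99, which keeps every response invertible ($99 still
implies a small positive rate; amounts ≥ $A are rejected as
non-invertible).  The simulator rounds responses to the slider resolution
(1 day / $1) after clamping; rounding can be disabled for exact-recovery
work.

A structural consequence worth knowing: **no single rate keeps all seven
time items on-slider.**  The $10 item needs `k ≥ 9/364 ≈ 0.025`/day to stay
under 52 weeks, while the $99 item needs `k ≤ 1/99 ≈ 0.010`/day to imply a
wait of at least one day.  The two windows are disjoint, so the $99 item is
floor-clamped for any respondent whose other answers are interior.  This is
exactly the mechanism that makes that item uninformative (below), and it is
why exact-recovery checks use the six-item time bank.

## MCQ scoring

Each binary item ($V today vs $100 in `D` days) implies an indifference
rate `k_ind = (A − V)/(V·D)`; a respondent with personal `k` above it
should take the immediate option.  The default 7-item bank pairs
V ∈ {10, 30, 40, 50, 70, 80, 99} with delays 61–364 days so the seven
`k_ind` values are distinct and roughly log-spaced over ~2.8e−5 to 0.15 per
day (delays spanning two months to a year, amounts $10–$99).  Bank size and
the (V, D) grid are fully configurable via the same YAML dialect as the
continuous banks.

Scoring is Kirby-style consistency maximization, the standard for
MCQ-family instruments.  The sorted indifference rates partition the
positive axis into 8 intervals; one candidate rate per interval (geometric
mean of its endpoints, using `k_min/2` and `2·k_max` as outer endpoints)
is evaluated by the number of observed choices it predicts, and the best
candidate wins.  Ties are broken by the geometric mean of all maximizing
candidates, which keeps the estimator symmetric for the two all-one-side
patterns.  Because predicted choices are constant within an interval, the
candidate scan is exhaustive: its maximum provably equals a dense grid
search's, and the test suite checks this on all 2^7 patterns.

## Quality control

Two rules, applied in this order per phase (phase 1 and phase 2 baseline)
and scale:

1. **Straightliners** — every continuous response in the phase at the
   slider minimum (`straightline_min`) or every one at the maximum
   (`straightline_max`).  "Every" is literal: one interior response
   retains the participant.  The effective time-slider minimum is the
   1-day floor.
2. **3-SD outliers** — log scale scores standardized within phase × scale
   (straightliners already removed) and flagged at `|z| > 3` in a single
   pass.  Standardizing log rather than raw scores is deliberate: raw
   rates are heavy-tailed and a 3-SD rule on them over-flags.  A config
   switch (`on="k_geomean"`) provides the raw-scale reading for
   sensitivity analyses.  Zero-variance groups warn and flag nobody;
   groups under 3 estimates are an error.

The analytic sample is the intersection of participants retained in every
screened phase.  Re-screening a retained sample can re-flag clean normal
tails at 3 SD (any finite-sample rule does); it never re-finds
planted-magnitude (≥ 5 clean SD) contamination, which the tests assert.

## Psychometric analyses

* **Item–total correlations** (per scale × phase, analytic sample): Pearson
  r between each item's log rate and the scale's log geometric mean.  The
  total includes the item, matching how full-scale totals are usually
  reported; `include_item=False` gives the corrected variant.  Items with
  an exactly constant log rate (fully clamped) are reported as undefined
  rather than silently dropped.  The informativeness cutoff defaults to
  r ≥ 0.5 — in deployed versions of this instrument the poorly performing
  item sat near r ≈ 0.4 and the rest near 0.9, so any cutoff between those
  regimes reproduces the same decision; it is configurable.
* **Test–retest**: Pearson r of log scores across phase 1 and phase 2
  baselines, listwise complete pairs.
* **Convergent validity**: the full symmetric r/p/n matrices over all
  scale × phase scores (six variables with the MCQ included), diagonal
  exactly 1.
* **Abbreviation**: for each subset size N, `iterations` (default 100)
  uniform random N-item subsets of the informative items, without
  replacement within a draw, one seed governing the whole curve; r between
  subset and full-scale log scores.  The full-scale denominator defaults to
  the informative set (the same items the subsets draw from), with an
  option to use the complete bank instead; reports state which was used.
  Requesting N = full length is allowed only in an explicit check mode
  (`allow_full=True`), where r = 1 by construction.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
any particular dataset:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_participants` | 97 | analytic-sample size of a realistic two-phase EMA cohort |
| `n_followups` | 18 | 3 momentary surveys/day × 6 days (+1 baseline = 19) |
| `mu_log_k`, `sigma_log_k` | −3.0, 1.0 | latent ln-rate distribution; centers ideal responses of the central time items inside the 1–364-day slider while putting most of the cohort past the $99 item's 1-day threshold, the regime a general-population sample plausibly occupies |
| `rho_phases` | 0.75 | latent between-phase stability; with default noise the *observed* test–retest lands near 0.7, the regime reported for trait-like discounting |
| `tau_time`, `tau_money` | 0.3, 0.55 | occasion-level instrument noise SD on ln k, independent across items within a survey; the monetary instrument is noisier, reflecting its weaker observed psychometrics |
| `mcq_choice_scale` | 0.6 | logistic choice-noise scale on ln k − ln k_ind |
| `compliance` | 15/18 | per-follow-up completion probability ⇒ ≈16 of 19 surveys completed |
| `endorse_intercepts/slopes`, `endorse_person_sd` | ≈ −4.5 / tobacco 1.2 others 0.3 / 2.0 | per-survey logistic endorsement on the standardized latent rate plus a person random intercept; yields 4–9% endorsement with the strongly right-skewed, near-bimodal per-person percentages real EMA substance data show, and a planted positive tobacco association |
| `outlier_shift` | 2.2 | planted contaminants sit at exactly `mu + shift` (fixed, not drawn) so their separation from the clean cohort is controlled |

Presets: `clean_config()` (defaults, no contamination),
`contaminated_config()` (σ = 0.2, τ = 0.15, 2+1 straightliners, 5 planted
outliers — the narrow clean spread keeps the plants > 5 clean SDs out so
the 3-SD rule must recover exactly them), `null_config()` (all endorsement
slopes 0), and `calibration_config()` (six-item time bank, σ = 0.25 around
μ = −2.5, rounding off, n = 500 — a clamp-free regime for exact-recovery
and attenuation checks).

What the generator does **not** emulate: within-survey correlation of item
noise, time-of-day or withdrawal dynamics of discounting, demographic
structure beyond marginal sex/age frequencies, attrition that depends on
the trait, and item-order effects.  Passing tests therefore demonstrate
that the *pipeline* recovers what the generative model puts in — not that
real respondents obey the hyperbolic model or that real tobacco effects
have the planted size.

### Quantitative oracles used in testing

* Noiseless cohorts in the clamp-free regime must score back each latent
  rate exactly (closed-form inversion, no rounding).
* With occasion noise τ per item and m items, the score noise is τ/√m and
  the observed test–retest correlation should follow the attenuation law
  r ≈ ρσ²/(σ² + τ²/m); checked against 20 replicate cohorts of n = 500
  within the replicates' own Fisher-z 95% interval.
* OLS recovery: outcomes generated as an exactly linear function of the
  log score plus Gaussian noise (`simulate_linear_outcomes`) give known
  coefficients; 95% CI coverage and null type-I error are checked over 100
  replicates.

## Regression models

Per-person outcomes are `100 × endorsing / completed` follow-up surveys,
computed from completed surveys only (non-completers of a survey simply
contribute no row; participants with zero completed surveys drop out of
the table).  Each outcome is fit by OLS on the phase-2 baseline log score
with age, sex and completed-survey count as covariates; continuous
predictors are mean-centered (which provably leaves the slope, CI and p
identical to the uncentered fit — asserted numerically in the tests), sex
enters as a single male indicator with female the reference level, and age
is continuous.  Percentages are regressed on the 0–100 scale, so
coefficients read as percentage-point adjusted mean differences per unit
ln k.  No multiple-testing correction is applied by default (18 tests are
reported as-is); a Benjamini–Hochberg column is available via
`bh_correction=True`.

## Numerical and design choices

* Ties, degenerate inputs: empty or non-positive rate vectors raise;
  MCQ scoring requires a complete, strictly binary pattern and names
  missing items; rank-deficient regression designs raise naming the most
  collinear column pair.
* Determinism: every stochastic routine takes a seed or `Generator`; a
  study config's seed fixes the full dataset byte-for-byte, and pipeline
  artifacts are stamped with a config hash.
* Problem sizes: the test and acceptance runs use cohorts of 97–500
  respondents, 20 replicates for the attenuation check and 100 for
  regression calibration — sizes at which each check's Monte-Carlo error
  is well below the effect it verifies.  The acceptance script measures
  the $99-item informativeness contrast on an n = 500 cohort because that
  item's correlation is carried by its small patient tail and is unstable
  at n = 97 (occasionally the tail is empty and the correlation is
  undefined); the count of uninformative items is robust at either size.

## Known limitations

* Only the single-parameter hyperbolic model is supported — no
  exponential or β-δ discounting, no area-under-curve scoring, and no
  reward-magnitude effects.
* The MCQ consistency maximizer returns a point estimate; it does not
  quantify within-pattern inconsistency beyond the consistency count.
* The abbreviation analysis resamples items, not respondents; its
  Monte-Carlo SE reflects subset choice only.
* Associations are cross-sectional adjusted differences; no
  within-person (momentary) or temporal modeling is attempted.
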