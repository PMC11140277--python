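# Methods

## The evaluation model

`trialcea` performs a trial-based economic evaluation of two strategies —
a web-based psychological intervention and treatment as usual (TAU) — over
a 6-month horizon, from a social perspective, in 2018 euros. The analysis
is fully incremental: for each effectiveness measure E it reports

    ΔC = C_int − C_tau,   ΔE = E_int − E_tau,   ratio = ΔC / ΔE

where the ratio is the ICER (euros per additional responder, effects being
responder proportions) or the ICUR (euros per QALY). Strict dominance
(cheaper *and* more effective) suspends the ratio; otherwise the point
(ΔE, ΔC) is classified on the cost-effectiveness plane with incremental
effect on x and incremental cost on y: NE = more effective and more
costly, SE = dominant, SW = less effective and cheaper, NW = dominated.
Points on an axis belong to no quadrant. In the SW quadrant the ratio is
still reported but flagged: there it reads as savings forgone per unit of
effect lost, not a price paid for benefit.

### Costing

Per participant, total cost is the sum of four components:

* **Direct healthcare** — Σ (resource-use count × unit price) over eight
  primary/specialist-care categories. Medication costs are out of scope.
* **Capital** (intervention arm only) — platform development annualised by
  the equivalent annual cost, EAC = K·r / (1 − (1+r)^(−L)), scaled to the
  treatment duration and divided by the patients served. Defaults: rate
  r = 3%/yr, life L = 5 yr; the shipped configuration uses the known
  per-patient figure of 65.06 EUR as an override because the full
  annuity inputs behind it are not public. At r → 0 the EAC reduces to
  straight-line K/L.
* **Personnel** (intervention arm only) — two 25-minute psychologist
  sessions at 25.55 EUR each, 51.10 EUR per patient.
* **Indirect** — human-capital productivity losses, sick-leave days times
  the 2018 minimum interprofessional daily wage (24.53 EUR/day; the wage
  is a config parameter, the analysis is homogeneous of degree one in all
  prices and wages).

Arm-level SDs are computed from participant-level totals (component SDs
are not additive); per-patient constant components have SD 0. Totals equal
the sum of component means at full precision; rounding to cents happens
only at display time.

### Effectiveness

Responder criteria are inclusive thresholds on baseline-to-6-month change:
PHQ-9 reductions of ≥3 and ≥5 points, a ≥50% *relative* PHQ-9 reduction,
and an *absolute* HbA1c reduction of ≥0.5 percentage points (the
diabetes-trial MCID convention; not 0.5% relative). Relative criteria are
undefined at baseline 0; such participants are flagged not evaluable.

The default analysis population is per-outcome complete case: a
participant enters a criterion's denominator only with both baseline and
6-month values of that outcome. This is the only population that
reproduces the published responder percentages (10/13 and 5/16 for the
3-point criterion, 7/13 and 2/16 for the 5-point and 50% criteria, 1/12
and 2/14 for HbA1c). An `itt_locf` population (last observation carried
forward, everyone with a baseline evaluated) is available for sensitivity.
Cost means feeding each comparison are taken over the same evaluable
population, which is why the HbA1c comparison carries different arm costs
(481.59 vs 571.53 EUR) than the PHQ-9 comparisons (503.91 vs 418.61 EUR).

### QALYs

QALYs are trapezoidal areas under the utility trajectory across visits at
0, 3 and 6 months; a missing interior visit interpolates linearly across
the gap; no extrapolation beyond the last visit; no discounting (horizon
< 1 year). Because arms can start from different utility levels, the
headline quantity is the baseline-adjusted gain Q_gain = Q − u₀·T. This
closed-form adjustment reproduces both published arm-level gains from the
published QALYs and baseline utilities (0.3270 − 0.5898/2 = 0.0321
exactly; 0.3063 − 0.5935/2 = 0.00955, printed as 0.0095), which is the
package's end-to-end check of the adjustment convention. A
regression-based adjustment would be a reasonable extension; it is not
implemented. The instrument layer (SF-12) is abstracted behind a utility
mapping registry whose default is a passthrough of a precomputed utility
column; no tariff is bundled as authoritative because the source tariff of
the published utilities is unknown.

### Uncertainty

Printed-style confidence intervals are nonparametric percentile bootstrap
intervals (default B = 1000, configurable), resampling participants with
replacement within each arm, seeded and reproducible. The bootstrap is the
field default for right-skewed cost data. These intervals are *not*
expected to equal any published interval, whose method is unstated.

The deterministic sensitivity analysis perturbs one component at a time by
±20% in both arms and recomputes the ratio through the same arithmetic as
the base case. Cost components scale the corresponding per-arm mean;
effectiveness components scale the matching responder proportions (capped
at 1.0); the QALY component scales both arms' mean (gained) QALYs.
Components not entering an outcome leave its ratio unchanged (zero-width
tornado bar). Tornado entries are sorted by descending range width, ties
broken alphabetically, so the ordering is invariant to input order.

## Synthetic data

### Stochastic generator

`generate_trial` emulates the study conditions: arm sizes 22/27, dropout
probabilities 8/22 and 9/27, PHQ-9 baselines from a
truncated normal matched to mean 12.71, SD 3.60 on the 5–19 inclusion
window (scores rounded to integers), HbA1c baselines 7.16%/7.78%, utility
baselines 0.59 ± 0.18, and arm-specific change/drift distributions chosen
so the mean 6-month changes match the benchmark dataset's arm means
(PHQ-9 −5.5 vs −2.3 points; utility drift +0.2568 vs +0.0764 per year).
Costs are drawn per category from zero-inflated lognormal distributions
whose zero mass and lognormal moments are solved exactly from the target
mean and SD — the published cost summaries have SD ≥ mean, which forces a
point mass at zero plus heavy right skew. Requesting an SD too small for
the zero mass raises an error naming the category. Truncated-normal
parameters are likewise solved so the *truncated* distribution has the
configured mean and SD; configured moments are therefore recovered within
sampling error, which the tests check at n ≥ 2000 within 3 standard
errors. Sick-leave days are zero-inflated lognormal (fractional days
allowed), nonzero only in the control arm by default. Costs and outcomes
are drawn independently within participant.

What the generator does **not** emulate: within-participant correlation
between costs and outcomes (unreported in the source data), engagement
effects of therapy modules on outcomes, visit-schedule irregularity, and
administrative censoring patterns. Passing tests on generated data
therefore demonstrate statistical correctness of the pipeline under the
stated data-generating process, not robustness to every feature of real
trial data.

### Deterministic benchmark dataset

`benchmark_trial` is constructed by closed-form arithmetic, not sampling,
so that every arm-level aggregate equals the published base case: cost
component means and SDs to the cent (healthcare 387.75 (508.91) vs 356.94
(500.49); indirect 61.67 (246.67); totals 503.91 (508.91) vs 418.61
(567.42)), the per-outcome subsample cost means (481.59/571.53 for the
HbA1c complete cases), responder counts, baseline utilities
0.5898/0.5935 and mean QALYs 0.3270/0.3063. Healthcare and indirect cost
vectors were solved from subgroup-mean and SD moment equations (a few
high-cost participants against many low-cost ones — the same right-skew
pattern the generator samples); responder layouts place strong responders
(satisfying both the 5-point and 50% criteria), moderate responders
(3-point only) and non-responders in the first 13/16 ids; utility
trajectories are linear with zero-sum perturbation pairs so arm means are
exact. Conventions to be aware of: visit counts and sick-leave days may be
fractional (only priced totals matter to the pipeline; integer-valued
realism is the generator's job), utility trajectories are complete for all
49 participants (making the cost-utility population the full arm, whose
component split is exactly the cost table), and the responder denominators
13/16 and 12/14 are reconstructions from published percentages, not
observed data.

## Numerical choices and edge cases

* Inclusive responder thresholds (change ≥ threshold), the standard
  responder convention; only the inclusive reading yields consistent
  integer responder counts.
* ΔE for the CEA is carried as a proportion and displayed as percentage
  points; the ICER divides by the proportion, so it prices a whole
  additional responder.
* ΔE = 0 leaves the ratio undefined (NaN, flagged) rather than infinite.
* Degenerate bootstrap samples (all values identical) give zero-width
  intervals, not errors.
* Money is plain floating-point euros with a currency-year label; no
  inflation adjustment (single-year study). Display rounding: money to 2
  decimals, percents to 2 decimals, QALYs to 4; JSON output keeps full
  precision.
* Validation is fail-fast with named offenders (unknown resource
  category, negative counts or prices, duplicate ids, out-of-range
  scores); missing values are preserved, never silently imputed; the CLI
  computes everything before writing anything, so a failing stage never
  leaves partial output.

## Known limitations

* The capital-cost default relies on the per-patient override; the
  general annuity path is implemented and tested but the original
  annuity inputs are not public.
* No probabilistic sensitivity analysis (CEAC / net-benefit curves) —
  the evaluation this package operationalises is deterministic univariate.
* The bootstrap prices uncertainty within the observed trial only;
  with 49 participants the intervals are wide and percentile intervals
  can undercover for very skewed statistics.
* Baseline hypothesis testing (t, χ², Mann-Whitney) is out of scope;
  standard statistics packages cover it.
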