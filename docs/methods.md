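# Methods

## The costing model

An episode's *excess* length of stay is the number of days beyond the
all-ages overnight average LOS for its DRG, taken from a reference table
(published casemix figures with day-stays removed), never recomputed from
the analysis cohort. Only episodes strictly longer than the average are
"above average": an episode exactly at the average has stayed no *longer*
than average, and the above-average sample therefore has strictly positive
extra cost, which keeps the log outcome defined.

Costs are attributed per day from the DRG's *variable* cost only. The
sixteen treatment-expense subcategories are partitioned once: eleven
variable (ward nursing, ward medical, non-clinical salaries, pathology,
imaging, allied health, pharmacy, supplies, on-costs, hotel, depreciation)
and five fixed (critical care, operating rooms, emergency departments,
special procedure suites, prosthesis). Fixed costs are one-off and do not
change with LOS, so they never enter the extra-cost calculation:

    daily_variable_cost = variable_total / avg_overnight_los
    extra_cost          = (los_days − avg_overnight_los) × daily_variable_cost

`extra_days` is kept as a real number (state average LOS is generally
fractional); nothing in the method requires rounding it, and rounding would
break the multiplicative identity the tests verify. Currency is
unit-agnostic; an optional purchasing-power-parity multiplier can rescale
outputs but is off by default.

## Coding

**Matching.** All ICD-10 matching is prefix-based on normalised codes
(dots stripped, upper-cased), the standard convention for administrative
data.

**Dementia** is ascertained at the person level: any episode of the person
within the lookback window (default two years, anchored at the end of the
observation window) carrying F00/F01/F02/G30/G31 as principal *or*
additional diagnosis flags the person, and the flag propagates to all their
episodes. This linkage captures dementia documented on an earlier stay even
when the index episode does not code it.

**Complications** are conservative: the inclusion code must appear among
the *additional* diagnoses (a principal diagnosis is, by definition, the
reason for admission, not hospital-acquired), and an aetiology exclusion
vetoes the flag. Exclusion scope is per rule: urinary tract infection is
vetoed by a urinary-tract *principal* diagnosis only; pressure injury is
vetoed by paralysis codes (G81/G82) as principal or additional. The
packaged rule table is an editable, illustrative ICD-10-AM-style
vocabulary — the engine, not the vocabulary, is the artifact — and the
pneumonia (excl. J69/J80/J95) and delirium (excl. F10/G92) exclusion sets
are explicitly assumptions in the same conservative spirit, not validated
clinical rule sets.

**Charlson index.** Classic weights (1 for most chronic conditions, 2 for
hemiplegia/paraplegia, renal disease and any cancer, 6 for HIV/AIDS)
restricted to the named condition list, each condition counted at most once
regardless of code multiplicity, summed flat (no severity hierarchy such as
metastatic-overrides-cancer — the restricted list has no such pairs).
Dementia is in the table but excluded from the score by default since it is
its own model term. Weights and code map are configurable.

**Filters.** Age ≥ 50 and 1 ≤ LOS ≤ 90 days, boundaries inclusive. Each
excluded row is logged under exactly one reason (age checked first) so the
waterfall sums to the input row count.

## Regression

Fixed-order block entry, not data-driven selection: both blocks are
pre-specified, so "hierarchical" means step 1 (age, male indicator) and
step 2 (full model) are fitted as two nested OLS models, reporting R² for
each, adjusted R² and F for the full model. Sex is coded male=1, female=0;
age enters in years, uncentered; complications enter as the 0–4 count by
default (an any-complication binary is a config alternative). Rows with
missing model fields are dropped listwise with a logged count. Plain OLS
standard errors by default — the data are heteroscedastic in real
applications, and HC1 robust errors are available behind a flag, but the
default mirrors the conventional reporting for this design.

**Back-transformation.** Log-scale standard errors cannot be honestly
converted to dollars, so only point effects are back-transformed. The
default is `(e^b − 1) × mean(extra_cost)`: the per-unit multiplicative
effect evaluated at the sample mean, which makes the percentage-of-mean
column `round(100·(e^b − 1))` by construction. Alternatives (selectable via
`ModelSpec.back_transform_method`): the same multiplier at the median, and
the prediction-at-covariate-means scale. Percentages round half away from
zero.

**Degenerate inputs.** A rank-deficient design raises an error naming the
collinear predictors (found by testing which column's removal restores full
rank); n ≤ p+1 raises; a zero-variance predictor cannot be standardised and
raises.

## Synthetic data generator

The generator emulates one financial year of state overnight discharges for
adults 50+, with a two-year window so the dementia lookback is exercised.
Defaults are the study conditions: 53% female, 23.7% surgical, 11.9%
dementia (person level), complication prevalences 8.2% UTI / 2.6% pressure
injury / 3.7% pneumonia / 1.9% delirium drawn independently per episode
(multiple complications are correspondingly rare, under 1%), age uniform on
50–107, and 37% of episodes above their DRG average. True log-scale
effects default to: dementia 0.14, per-complication 0.13, per-cost-weight
0.05, per-Charlson 0.04, per-year-of-age 0.003, with residual SD 0.9; the
male (0.015) and surgery (0.008) effects are small positive values chosen
so their dollar effects at the mean are of the order of tens of dollars.
The intercept (7.85) sets the mean extra cost near $5.9k. About 15,400
persons at a mean 1.3 episodes each give ≈20,000 episodes, of which ≈7,400
form the above-average regression sample.

Mechanics: excess cost is drawn from the Gaussian log-linear model, and LOS
is back-derived as `round(avg_los + extra_cost/daily_variable_cost)`, so
the cost stage reproduces the intended cost up to whole-day rounding.
Diagnosis lists are constructed to be exactly recoverable: complication
episodes carry the rule's inclusion code and never a matching exclusion
code (in particular, a pressure-injury episode never receives the
hemiplegia Charlson condition, whose codes are that rule's exclusion — the
ground truth reflects the suppression); each Charlson condition contributes
one representative code; dementia persons carry a qualifying code on at
least one episode (re-documented on others with probability 0.5); filler
codes come from a vocabulary disjoint from every rule and index prefix.

DRG reference: 300 DRGs (the real casemix system has ~660 classes; 300
keeps ≈70 episodes per DRG at this scale), cost weights lognormal around
1.5 clipped to [0.1, 46], average LOS lognormal around 4 days and rising
sub-linearly with cost weight — resource-intensive DRGs keep patients
longer, which also keeps the daily variable cost in a realistic band
(~$600–1,700/day) instead of letting high-weight DRGs imply absurd per-day
rates with sub-day excess stays. Total DRG cost is cost weight × $3,800
(an illustrative all-separations average), with a 60–85% variable share
spread by Dirichlet draws over the subcategories.

What the generator does **not** emulate: hospital transfers and readmission
dynamics, realistic full ICD-10 coding depth, within-person correlation of
illness across episodes (age and sex persist per person; conditions are
redrawn per episode), correlation between surgery and cost weight, LOS
distributions calibrated to any particular DRG, or coding error. Passing
parameter recovery therefore shows the pipeline is correct and calibrated
under the model's own assumptions — not that the model is correct for real
discharge data, where heteroscedasticity, clustering and miscoding will
widen honest uncertainty.

## Calibration and numerical choices

Parameter recovery is the end-to-end test: 100 generator seeds at ≈20,000
episodes, full pipeline (filter → code → cost → fit), requiring each true
effect inside its nominal 95% CI in ≥ 90 runs and `r2_step2 ≥ r2_step1` in
all. Whole-day rounding of LOS perturbs the log outcome by O(1/days²),
which is second-order at these problem sizes; with too few DRGs this
perturbation is shared within DRG and deflates the SE of the (DRG-level)
cost-weight coefficient, which is why the DRG count defaults to hundreds,
as in real casemix systems. OLS solutions agree with a brute-force
normal-equations solve to 1e-8 relative tolerance; the cost identity
`extra_cost = extra_days × daily_variable_cost` holds to floating-point on
every row; day-level comparisons use exact arithmetic on integers versus
floats with no tolerance tricks.

## Known limitations

- The packaged code vocabularies are illustrative, not clinically
  validated; real deployments should substitute audited rule tables.
- The pipeline treats multiple episodes of one hospital stay as
  independent episodes, as the source data convention does.
- Fixed costs are assumed fully LOS-invariant and variable costs fully
  proportional to days; front-loading of variable costs within a stay is
  not modelled.
- No dementia × complication interaction term is fitted; subtype breakdowns
  of dementia and condition-onset flags are out of scope.
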