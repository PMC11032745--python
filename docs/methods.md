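# Methods

## Model and procedure

The package operationalizes a supply-side index of drug lethality. The unit
of analysis is the *drug category* (six indexed: fentanyl, cocaine,
prescription opioids, heroin, amphetamines, benzodiazepines; everything else
is an open `other:<name>` category). Deaths are restricted to ICD-10
underlying cause X40–X44 (accidental drug poisoning), matched on the first
three characters, case-insensitively, so exports with decimal suffixes pass.

For a reference year the Lethality Ratio of drug X is

    LR(X) = single-drug deaths(X) / single-drug seizures(X),

where "single-drug" means the deduplicated category set has size one.
Single-drug status is decided **after** normalization: two raw names that
map to one category (oxycodone + hydrocodone → prescription opioids) still
count as single-drug, which treats the category as the pharmacological unit.
Non-indexed (`other:*`) substances count against single-drug status by
default — a fentanyl + alcohol toxicology is not a pure fentanyl death — but
the `ignore_other_substances` flag inverts this, since registry practice on
non-abuse co-intoxicants varies and no single convention is clearly right.

SDLI(X, y) = LR(X) × all seizures of X in year y (mixed seizures count once
per involved drug), and SALI(y) sums SDLI over exactly the drugs present in
the lethality table. Deaths influence SALI only through the reference-year
ratios; everything year-varying comes from the seizure stream. The ratio is
carried at full floating precision; only reports round, to three decimals
half-away-from-zero, matching spreadsheet conventions.

Annual deaths are modelled by OLS on the square-root scale,
√(deaths_y) = a + b·SALI_y + ε_y. The sqrt transform corrects the right
skew of count residuals. Inference on b is a two-sided t test with
df = n − 2; the CI level defaults to 0.95. Predictions back-transform by
squaring the linear predictor, clamped at zero first (squaring a negative
predictor would fabricate deaths under extreme downward extrapolation); no
smearing correction is applied, because the method is meant to be
reproducible in a spreadsheet, though a `bias_correction` hook could be
added without changing the interface. Residual independence is screened
with the Durbin–Watson statistic Σ(eₜ−eₜ₋₁)²/Σeₜ² over year-ordered
residuals (≈2 under independence, range [0,4]); normality and
homoscedasticity are assessed from the emitted histogram, Q-Q plot and
residual-vs-fitted scatter — deliberately descriptive, with no automated
pass/fail.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `reference_year` | 2017 | year anchoring steps 1–3 (peak-mortality year in the original application, maximizing death counts behind each ratio) |
| `ci_level` | 0.95 | two-sided slope CI level |
| `unmapped_policy` | `keep_as_other` | unmapped raw substance names become `other:<name>`; `drop` discards them; `None` raises |
| `ignore_other_substances` | `False` | whether `other:*` categories are ignored when deciding single-drug status |
| `deaths_scope` | `all_unintentional` | dependent variable counts all X40–X44 deaths; `indexed_drugs_only` restricts to deaths involving an indexed drug |

Drugs with zero single-drug seizures in the reference year are excluded from
the table with a warning rather than given LR = 0 or ∞: either imputation
would fabricate lethality information the data do not contain.

## The synthetic market

`generate_market` emulates the administrative data the method consumes.
Per (drug, year), seizure events are Poisson with mean set by a per-drug
base intensity times a per-year availability trend; each event is mixed with
probability `p_mixed`, in which case one partner drug (a second with
probability `p_third`) is drawn with probability proportional to
co-occurrence weight × that year's intensity, so scarce drugs rarely appear
as partners. Single-drug deaths are Binomial(single seizures, θ_d), making
θ_d the quantity the pipeline's LR estimates. Under the `linear_sqrt` deaths
model, multi-drug death records (always ≥2 toxicology substances, so they
cannot leak into the single-drug counts) are appended until annual totals
equal round((a + b·SALI(y) + ε)²), with SALI computed from the true θ and
the realized seizure tallies. If a year's target falls below the
mechanistically generated single-drug deaths the parameters are rejected as
infeasible with a pointer to raise `a`. Randomness comes from one seed via
per-(drug, year) `SeedSequence` substreams; identical parameters give
byte-identical CSVs.

The `ohio2017-like` preset sets the study conditions: six drugs over
2009–2018, reference year 2017, θ at the published ratio magnitudes
(0.393 … 0.005), reference-year primary-seizure volumes in the thousands,
half of exhibits mixed, opioid-heavy co-occurrence weights, availability
trends with fentanyl emerging late and sharply, and the death-total model
(a, b, noise_sd) = (12, 0.0095, 0.3). Its `scale` argument shrinks the
market proportionally for cheap runs by multiplying intensities by `scale`
and mapping the coefficients to (a·√scale, b/√scale), which scales death
totals by `scale` and preserves the deaths-to-seizures geometry. Because
Poisson/binomial noise grows relative to the feasibility margin as the
market shrinks, scales below about 0.1 can trip the infeasibility check for
some seeds; tests and demos use scale ≥ 0.1.

What the generator does **not** emulate: county/spatial structure,
within-year seasonality, polydrug interaction effects on death risk,
raw-name messiness of real lab exports (the generator emits category
tokens), and reporting artifacts such as late registrations. Passing tests
therefore show the pipeline's arithmetic and statistical behaviour are
correct under the stated generating process, not that the index predicts
real mortality in any particular jurisdiction.

## Test and simulation sizes

Parameter-recovery tests run the reference year with ~10,000 single
seizures per drug, where 3 binomial standard errors bound the LR−θ gap
tightly. Regression calibration uses 200 replicates of 12 annual
observations with sqrt-scale noise 0.3; slope-CI coverage is required to
land in [0.92, 0.98] around the nominal 0.95. End-to-end demonstrations use
the preset at scale 0.1 (≈40,000 seizures, ≈4,000 deaths per run).

In the end-to-end coverage test, SALI is taken from the generator's ground
truth (`true_sali`: true θ × realized tallies) rather than the estimated
ratios. That choice is deliberate: the estimated-LR pipeline injects a
per-replicate errors-in-variables term that plain OLS intervals do not
model, so nominal coverage is a property of the regression given SALI, not
of the two-stage estimate at small reference-year samples. LR estimation
accuracy is tested separately at binomial resolution, and a single
end-to-end run with estimated ratios is checked for a strong sqrt-scale fit
(r² > 0.8).

## Numerical and degenerate-input choices

- Reported ratios round half-away-from-zero at 3 decimals; internal values
  never round.
- The regression requires ≥3 matched years and nonzero SALI variance;
  violations raise typed errors rather than returning NaNs.
- Years with zero deaths are valid (√0 = 0).
- Durbin–Watson is undefined for all-zero residual vectors and raises; a
  noiseless exact fit stores DW = 0 in its result rather than failing the
  whole fit.
- Duplicate record IDs are merged (substance-set union) with a warning; a
  toxicology or exhibit list that becomes empty after `drop`-policy mapping
  drops the record with a warning.
- The pipeline is a pure function of (config, inputs): rerunning writes
  byte-identical tables.

## Known limitations

- The lethality ratio is a ratio of administrative counts, not a case
  fatality rate; it inherits enforcement priorities and lab submission
  practices, and seizure weight/volume/purity are intentionally out of
  scope.
- One reference year anchors all ratios; drift in per-drug lethality
  (e.g. analog turnover within "fentanyl") is not modelled.
- Plain OLS with a DW screen, not a time-series model: autocorrelation is
  checked, not corrected for.
- With ~10 annual observations the regression has low power against model
  misspecification; diagnostics are visual by design.
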