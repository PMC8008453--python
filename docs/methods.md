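# Methods

## Exposure model

Single-day dietary methylmercury intake is modelled as

    intake = Σ_g C_g · A_g / bw        [µg/kg bw/day]

over five raw-fish groups *g*, with C_g a group-specific log-normal
concentration (mg/kg ≡ µg/g), A_g a single-day consumption amount (g/day)
resampled from survey records, and bw a fixed 50 kg body weight. One C_g and
one A_g are drawn independently per group per iteration; 100,000 iterations
by default. Key assumptions:

- **Independence across groups within a day.** Eating tuna does not change
  the probability of eating salmon the same day. This is supported by the
  zero-intake closure: the product of the five non-consumer proportions,
  Π(1−p_g) ≈ 0.273, matches the ~27 % of simulated zero-intake days.
- **Independence of concentration and amount.** The mercury level of the
  portion eaten is unrelated to portion size.
- **Fixed body weight.** 50 kg for every simulated person-day, including the
  women-aged-16–45 subgroup run; per-person body weights are out of scope.
- **Single-day horizon.** The survey records one day per person, so weekly
  intake (the scale on which the guidance value is defined) cannot be
  estimated without consecutive-day data; the daily TDI = TWI/7 is used as
  the comparison threshold instead. Note the companion conversion ambiguity:
  TWI 2.0/7 = 0.2857… rounds to 0.286, while a figure of 0.292 also
  circulates for the same TWI; this package uses TWI/7 exactly and renders
  it as 0.286.

## Concentration model

Each group's concentrations are log-normal, stored in dual parameterization
(arithmetic mean/SD and log-scale μ/σ, consistent to 1e-9 relative).
Two estimators are offered:

- `moments` (default): matches the sample arithmetic mean and SD (ddof=1)
  exactly, so a printed mean/SD table reproduces the simulated distribution
  with no further information.
- `mle`: mean and population SD of the log-values. Note the standard
  normal-theory finite-sample effect: the MLE of σ is biased low by the
  factor c₄(n)·√((n−1)/n) (≈1 % at n=70); the test suite checks recovery
  net of that analytic expectation.

Model selection (CLI `fit`) compares log-normal, normal and gamma candidates
— all fitted by moments, location 0 — using the Kolmogorov–Smirnov statistic
D = sup_i max(|i/n − F(x₍ᵢ₎)|, |(i−1)/n − F(x₍ᵢ₎)|)
and the Anderson–Darling statistic
A² = −n − (1/n)Σ(2i−1)[ln F(x₍ᵢ₎) + ln(1 − F(x₍ₙ₊₁₋ᵢ₎))].
Parameters are estimated from the same data being tested (as commercial
fitting tools do); no Lilliefors-type correction and no p-values are
computed, because the statistics are used only to rank families. A family
whose fitted CDF underflows to 0 or 1 at an observation has its A² reported
as undefined rather than aborting the comparison.

## Truncation scenarios

Scenario 1 leaves the log-normal uncapped; scenario 2 caps sampled
concentrations at twice the observed group maximum; scenario 3 caps at the
observed maximum. Truncation semantics are rejection-with-redraw — the
renormalized distribution on (0, L] — not clipping, which would create a
point mass at the cap absent from observed concentration histograms. The
closed-form truncated mean (README) serves as the independent oracle for the
sampler and for calibration. Rejection below an acceptance probability of
1e-6 raises an error instead of looping. Scenario 2 is the headline
analysis: the observed maximum of the largest group rests on only 70
samples (likely an underestimate of the true maximum), while no cap at all
admits concentrations never observed in fish.

## Consumption model

Amounts are resampled with replacement from the raw record vector, zeros
included — equivalent to a Bernoulli(consumer proportion) stage followed by
resampling of positive amounts, but in one auditable step. No kernel
smoothing, no binning before sampling (binning is display-only), no
parametric fit: with most person-days at zero and a heavy right tail, no
standard continuous distribution is adequate. Processed fish and fish
products are excluded from the simulation entirely (their mean consumption
is roughly 0.25× that of raw fish, noted here for context only). Subgroup
analyses filter the records by demographic tags before resampling;
concentration models are unaffected.

The loader materializes implicit zeros: a person-day with no row for a group
consumed zero from that group, so every group vector is aligned one entry
per person. This treats the survey's "data points distinguished by fish
species" as person×group observations.

## Random-number discipline

One root seed; per-group substreams are split deterministically and keyed to
the canonical group order ((index, 0) for concentrations, (index, 1) for
consumption), so adding or removing a group never perturbs the other
groups' draws, and a concentration is drawn even on zero-consumption
iterations to keep streams aligned. Scenario comparisons reuse the same
seed: the untruncated base draws are then common random numbers and only
rejected tail draws differ, which stabilizes the scenario ratio estimates
without changing their expectations. Empirical quantiles use linear
interpolation between order statistics; at 100,000 iterations the choice of
convention is negligible.

## Synthetic survey generator

The real consumption microdata are protected by statute. The generator
emulates their published marginal structure for a default 28,706 person-days:

- consumer proportions per group: 17.5, 20.8, 25.2, 15.1, 34.2 %;
- positive amounts: log-normal with coefficient of variation 1.2, rescaled
  per group to the mean Ē_g = share_g · mean_intake · bw / (p_g · E[C_g|cap])
  that makes the pipeline reproduce the published mean intake
  (0.093 µg/kg bw/day) and contribution shares (10/2/14/47/27 %) in
  expectation. The resulting shapes match the published qualitative
  description (modal bin below 20 g/day; rare amounts ≥ 200 g/day);
- demographic tags: sex Bernoulli(0.5), age uniform on 1–90 years —
  conveniences for exercising subgroup filters, with no attempt to match
  real demographics;
- synthetic concentration datasets: 210 samples split 50/20/30/70/40 across
  the groups (the 20 and 70 are reported; the 50/30/40 split of the
  remaining 120 is a declared, configurable default), drawn from the
  published log-normals and rejected above each group's observed maximum.

**What calibration does and does not show.** The end-to-end closure test —
calibrated inputs reproduce mean 0.093 and the published shares — is
circular by construction; it validates the plumbing (units, independence,
stream handling, the closed-form mean), not the published estimates. The
log-normal/CV-1.2 positive-amount shape is a declared free choice: upper
intake percentiles and the TDI exceedance probability depend on the real
consumption tail, which was never published, so synthetic values of those
statistics characterize the generator, and any numerical agreement with
published upper percentiles is coincidental.

## Numerical choices and degenerate inputs

- Concentrations must be strictly positive (log-normal support); zero or
  negative values are rejected at load time.
- Datasets with zero variance are rejected as degenerate rather than fitted
  with σ = 0.
- Consumption groups with no positive amounts raise a degenerate-group error
  on use (an all-zero group in a *simulation* is permitted and yields zero
  intake).
- Dual-parameterization consistency is enforced to 1e-9 relative; variance
  factors use expm1/log1p so the near-degenerate small-σ limit is exact.
- A² requires every fitted CDF value strictly inside (0, 1); violations
  raise a numeric-domain error (or mark the family unusable in the CLI
  comparison).

## Problem sizes

Default runs use 100,000 iterations; the test suite runs its distributional
checks at the same 100,000 iterations (seconds on one core, since each run
is ~1M log-normal draws) and its replicate-recovery study at 1,000 fits of
n = 70.

## Known limitations

- Single-day intake only; no within-person day-to-day correlation, hence no
  weekly-intake distribution.
- No second-order Monte Carlo: the fitted concentration parameters are
  treated as known, so parameter uncertainty is not propagated.
- No species-level concentration modelling below the five groups, and no
  processed-fish pathway.
- The synthetic consumption tail is a modelling choice (see above); real
  upper-percentile estimates require the protected survey records.
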