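# Methods

## The costing model

`provcost` treats a healthcare system with three administrative hospital
levels (township, county, provincial), two service settings (outpatient,
inpatient), and a population split into urban and rural residents who
distribute their care across hospital levels according to hospital-seeking
behaviour. A single micro-costing study at a county-level hospital in a
base province supplies line items classified into five categories
(supplies, equipment, staff, drugs, programmatic); all other costs are
extrapolations of these items.

### Detailed reference method

*Price adjustment.* Line items are inflated in source currency through a
chain of annual medical-CPI factors and converted once at a fixed exchange
rate. Multiplication commutes, so the order is presentational; the combined
scalar is Π(factors)/fx.

*Hospital-level scaling.* County items are mapped to township and
provincial levels with per-category, per-setting multipliers. When derived
from published reference series (e.g. average staff expenditure or mean
visit/bed-day cost by hospital level), a multiplier is the series value at
the target level divided by its county value, making county multipliers
exactly 1 — a validated invariant, not a convention. The mapping from cost
category to reference series is configuration; the shipped default maps
staff to the staff-expenditure series and every other category to the
setting-matched cost series.

*Province extrapolation.* One scalar per (province, setting): the ratio of
the target province's unit cost (outpatient visit cost or inpatient bed-day
cost) to the base province's, applied uniformly to all hospital levels.
Level-resolved unit costs do not exist in the source yearbooks, so a single
per-setting scaler is the only defensible choice.

*Behaviour weighting.* For level costs A, B, C and urban fraction x, the
provincial mean is x(aA + bB + cC) + (1−x)(dA + eB + fC). Proportions are
stored as fractions in [0,1] (percent notation converted at parse time, to
preclude double-scaling). Each behaviour vector must sum to 1 within 1e−9;
the inpatient township entry is an explicit, validated zero rather than a
renormalised omission, because inpatient care is restricted to county and
provincial hospitals. A positive behaviour share pointing at a level with
no cost is an error (inconsistent inputs), not a silent zero.

*Aggregation.* Regional and national overall costs weight provinces by
total population; urban and rural strata are weighted by the urban/rural
sub-populations. This is the only weighting under which a group's overall
value remains the population-weighted blend of its strata. Total (not
female-only) population is used; the at-risk-population alternative would
only change the weights, not the machinery.

Internal arithmetic is never rounded. Presentation rounding (default one
decimal) uses half-up (ties away from zero) and is configurable, since the
convention behind published one-decimal tables is not documented.

### Simplified macro-index method

Province unit costs y are fitted against a macro-index x with
y = A·exp(B·x) + C by unweighted least squares on the natural cost scale
(C ≠ 0 rules out log-linearisation). Initialisation: C₀ = 0.9·min(y), then
(A₀, B₀) from a linear fit of log(y − C₀) on x; the optimiser is
Levenberg–Marquardt with predictors internally rescaled to unit range
(GDP is O(10⁴), HDI O(10⁻¹)) and up to 5 jittered restarts from a
fixed-seed generator, so fits are bit-reproducible. At least 4 points and a
non-constant predictor are required. Combined predictor sets use
A·exp(Σ_k B_k x_k) + C, the minimal generalisation of the single-index law.
Fits are unweighted across provinces; the base province is one of the
fitted points (nothing justifies excluding it). Costs for a target province
are the base province's detailed-method provincial costs times
λ = fitted(x_target)/fitted(x_base), per setting. Predictions outside the
fitted index range log a warning but are not refused.

### Method comparison

Agreement is measured as |estimate − reference|/reference × 100 per
(province, procedure). Summaries either average over provinces per
procedure and report min–max ranges within each setting, or average over
procedures per province. The per-province averages (in percent, which makes
provinces comparable; all procedures of a setting enter individually) feed
a paired t-test between two predictors, df = n−1, two-sided by default with
one-sided alternatives available — published comparisons of this kind do
not state sidedness, so the conservative default is two-sided. The base
province (λ = 1, zero difference by construction) stays in the averages and
the test. Identical inputs (zero-variance, zero-mean paired differences)
return t = 0, p = 1 by convention; zero variance with nonzero mean is an
error. No multiple-testing correction is applied across the predictor
ranking.

## Synthetic data generator

The generator draws a latent development index per province, uniform on an
HDI-like range, then per-capita GDP through a Gaussian copula on ranks — a
deliberate choice because only the rank relationship between competing
predictors matters for ranking experiments. Unit costs follow the
exponential law in the latent index times multiplicative log-normal noise;
hospital-seeking behaviour is one shared Dirichlet draw per (residence,
setting) with urban mass shifted toward county/provincial hospitals and the
inpatient township share forced to zero; urban fractions, populations,
micro-cost items and level multipliers are drawn from ranges a practitioner
would recognise for mainland China.

Default study conditions (chosen once, as the generator's definition of a
realistic regime): 31 provinces; HDI in (0.55, 0.90); GDP log-normal with
median $8,500 and log-sd 0.45 (≈ $4k–21k), copula correlation 0.85 with the
latent index; unit-cost law (A, B, C) = (2, 4, 5) outpatient and
(8, 4, 20) inpatient per unit HDI, giving ≈ 3.4× dispersion between the
least and most developed provinces — inside the 3–5× range that detailed
provincial costings exhibit; noise sd 0.05; urban fractions U(0.2, 0.95);
ten CPI factors of 4–6% and the 6.8632 exchange rate.

What the generator does **not** emulate: region-resolved behaviour
matrices (one national matrix is used, matching the input schema),
province-specific procedure mixes, systematic correlation between urban
fraction and development, reporting artefacts in yearbook unit costs, or
any attempt to impersonate real provinces' values. Tests passing on
synthetic worlds therefore validate the machinery and its statistical
behaviour under the stated assumptions — not the accuracy of any real-world
cost figure.

Degradation modes supply negative controls: permuting behaviour across
residence groups, flattening the unit-cost law (B = 0, implemented as
setting every province's unit costs to the across-province mean), and
corrupting a proportion row so load-time validation must reject the bundle.

## Numerical and design notes

- Validation is fail-fast with file/row/rule context; enums are closed.
- CSV round-trips are exact: values are written as `repr` and parsed with
  round-trip float precision.
- The detailed pipeline is deterministic and homogeneous of degree 1 in the
  component amounts; aggregation is invariant under uniform population
  rescaling; the behaviour weighting is a convex combination, so outputs
  are bounded by the level costs. These are enforced as property tests.
- When unit costs sit exactly on the index law and behaviour and urban
  fractions are shared across provinces, the simplified and detailed
  methods coincide algebraically; the test suite checks this equivalence
  numerically to < 0.01% and uses it as the structural justification for
  comparing the methods at all.
- Problem sizes in the test suite (bundles of 3–31 provinces, 50-seed
  recovery studies, 100-replicate ranking experiments) were chosen as the
  smallest sizes at which the statistical properties under test are stable.

## Known limitations

- No uncertainty intervals: the framework propagates point estimates only.
- No purchasing-power-parity conversion (province-level PPPs do not exist
  for the motivating setting) and no societal-perspective costs.
- The exponential family is assumed, not selected; the comparison module
  ranks predictors within that family only.
- The published per-province source tables for the motivating case are not
  redistributed here; provincial-resolution anchors can only be checked
  against a clearly-labelled synthetic stand-in unless users supply those
  inputs themselves.
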