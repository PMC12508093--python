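# Methods

This note documents the statistical models implemented in `shoalmix`, the
assumptions behind them, the synthetic-data generator used to validate
them, and the numerical and design choices a maintainer should know about.

## Data model and filters

Two record types carry the analysis. A **shoal record** is one observed
social aggregation with per-species individual counts; a shoal has at
least 2 individuals (size-1 rows are rejected at validation — an
aggregation of one fish is not a shoal, and observed size distributions
start near 3). A **foraging record** is one focal individual with body
length, shoal size and type, observation duration, and bite/bout counts;
`n_bouts ≤ n_bites` is enforced because a bout is a discrete feeding event
containing at least one bite.

Species are mapped to origin (`native` / `range_extending`) by a catalog
supplied as configuration (YAML/JSON), never hard-coded, so the pipeline
applies to any two-origin assemblage.

Inclusion rules for foraging records, applied in this order with exactly
one primary reason recorded per exclusion:

| rule | default | comparison |
|---|---|---|
| observation duration | 20 s | strict: records at exactly 20 s are excluded |
| focal body length | 10 cm | strict: only fish *larger than* 10 cm kept |
| shoal size | 50 | inclusive: shoals *greater than* 50 excluded (census accuracy) |

Rates are per-minute floats (`n / duration_s × 60`); raw counts and
durations are retained so rates are always recomputable.

## Association strength

Shoal records are compiled into a binary species × shoal matrix (rows in
catalog order, restricted to species observed at least once; duplicate
shoal ids rejected). The null model **fixes row totals** (each species'
occurrence frequency) and places each row's presences on a uniformly random
column subset, independently across rows. Column totals are free, so
richness-0 shoals can occur in null matrices — a direct consequence of not
fixing column totals, noted because it contributes to σ. A swap-based
null preserving both margins is provided (`randomize_fixed_rows_cols`) but
is not used by the default analysis.

For each unordered pair, α = (O − μ)/σ with μ, σ estimated from `n_null =
1000` randomizations (sample SD, ddof 1). Because rows are placed
independently and uniformly, the null law of O is exactly hypergeometric,
giving the closed form μ = rₐr_b/n, σ² = rₐr_b(n−rₐ)(n−r_b)/(n²(n−1)); the
`analytic` method exposes it and the test suite requires Monte Carlo and
closed form to agree within Monte-Carlo error. Pairs with σ = 0 (a species
in every shoal or in none) are flagged degenerate and reported as NA
rather than dividing by zero. With a fixed seed the Monte-Carlo table is
bit-reproducible; the delta-method Monte-Carlo standard error of α̂ is
√((1 + α²/2)/n_null), accounting for noise in both μ̂ and σ̂.

One wording ambiguity was resolved operationally: fixing row totals fixes
species *occurrence frequencies*; shoal species richness (column totals) is
what gets shuffled.

## Shoal configurations

Classification is by set of member-species origins (native-only /
range-extending-only / mixed-origin) and species count (mono-/
multi-specific); mixed-origin implies multi-specific. The 2×2 comparison
of multi-specific propensity uses only the two single-origin groups —
mixed-origin shoals belong to neither row, and the table-construction rule
is an explicit function argument rather than an assumption, because
published reports of such tests rarely print the cell counts.

Fisher's exact test uses probability-ordering two-sided p computed in
exact integer arithmetic (hypergeometric weights `C(R,k)·C(N−R,C−k)`
compared as integers, so ties are exact, then one float division); the
odds ratio is the conditional MLE with an exact inverted-test 95% CI
(via scipy), with the sample cross-product ratio also reported. The χ²
test is the standard Pearson statistic on margins-derived expected counts,
with optional Yates correction.

Log shoal size is modelled as Gaussian with the 3-level configuration
factor — a pure group-means model fitted in closed form. The full
configuration × type cell model is fitted only for its AIC (both AICs are
reported; the mean parameters plus one variance parameter are counted).
Pairwise contrasts use the Tukey–Kramer studentized range (exact for
unequal group sizes); the compact letter display assigns letters to
maximal cliques of the "not significantly different at 5%" graph, lettered
from the clique containing the largest mean, ties broken alphabetically.
Random effects for location and observer are not estimated: the original
mixed-model analysis of these data found them to contribute negligible
variance, and the reduced fixed-effects model is the one this package
implements.

## Foraging model

Bite and bout rates are continuous, non-negative, and contain exact zeros,
which selects the Tweedie family with 1 < p < 2 (compound Poisson–gamma:
positive mass at zero, variance φμᵖ). The linear predictor on a log link
carries the full origin × shoal-type × shoal-size interaction plus body
length; treatment coding with reference levels origin = range-extending
and type = mono-specific, so the origin coefficient reads directly as the
log rate ratio of natives to range-extenders. Shoal size enters
untransformed (slopes are per individual fish). Species identity can be
added as a fixed term (`include_species`); random effects are not
estimated (see above). Zero rates are retained, never dropped or offset.

Fitting is IRLS with working weights μ^(2−p), stopping when the relative
deviance change falls below 1e-8 (relative to |deviance| + 0.1, so
near-zero deviances are safe); non-convergence returns a flagged fit with
a warning instead of raising. The Tweedie unit deviance is
2[y^(2−p)/((1−p)(2−p)) − yμ^(1−p)/(1−p) + μ^(2−p)/(2−p)], with the gamma
limit used at p = 2 (supported for cross-checks against a gamma GLM).
Dispersion is the Pearson estimate χ²/(n−k) and the coefficient covariance
φ(XᵀWX)⁻¹. Rank-deficient designs raise an error listing the aliased
terms (QR-style sequential rank check). The linear predictor is clipped to
±30 on the log scale during iteration to keep exp() finite; this is never
active at a genuine optimum.

The power p is not estimated jointly: it defaults to 1.5 (the midpoint of
the compound-Poisson range) and can be profiled over a grid with the
extended quasi-likelihood objective Σ[dᵢ/φ̂ + log(2π φ̂ max(yᵢ, ε)ᵖ)],
ε = 1e-3 guarding exact zeros. EQL is known to be slightly biased toward
low p but orders datasets by their true variance exponent reliably at
n ≳ 1000, which is what the package uses it for.

Derived quantities: per-cell shoal-size slopes are linear combinations of
coefficients; between-cell rate ratios are computed at a reference shoal
size of 3 fish (body length cancels in every between-cell contrast);
standard errors come from the delta method and adjusted p-values from the
studentized range over the 4-cell family with the fit's residual df.

## Synthetic-data generator

The generator exists so every analysis stage can be tested against known
truth. It emulates:

* **Shoal assembly** — the species subset of each shoal is i.i.d. from a
  log-linear law P(x) ∝ exp(Σθᵢxᵢ + Σθᵢⱼxᵢxⱼ) renormalised over non-empty
  subsets (exact enumeration, ≤15 species). Shoal size is log-normal per
  origin configuration, rounded, floored at 2 (and at the subset's species
  count) and capped at 50 so generated data never trip the analysis
  filters; individuals are allocated to member species by a symmetric
  multinomial (a modelling choice — no within-shoal abundance law was
  available to copy). Locations and observers cycle deterministically.

* **Foraging** — μ = exp(linear predictor) per design row, bite rate drawn
  by an exact compound-Poisson–gamma sampler (Poisson number of gamma
  jumps; no density evaluation needed), `n_bites = round(rate ×
  duration/60)`, bouts a binomial thinning of bites with per-origin
  thinning fractions.

**Default parameters are the emulated study conditions, chosen once.** The
assembly defaults (4 species, 7 locations, 250 shoals) were calibrated
against the exact subset law to reproduce the field pattern: ≈29/43/28%
native-only/range-extending-only/mixed split, *S. salpa* the commonest
shoal-former and the parrotfish the rarest, native multi-specific shoals
rare (<3%), and long-run pairwise α values matching the published table
(+1.5 for the two rabbitfish, +1.0 for *S. salpa*–*S. rivulatus*, negative
for the native pair). The foraging defaults use the published slope
structure (0.017 / 0.015 / 0.021 / −0.008 per cell; length −0.020), p =
1.5, φ = 1.2, and an intercept and origin/type terms set so that at ~3
fish and mean length natives bite at ≈65% (mono) and ≈73% (multi) of the
range-extenders' rate and the range-extenders average ≈33 bites/min.
These are generative settings, not estimates.

**The non-emptiness constraint matters.** Because a shoal must contain at
least one species, the subset law is conditioned on non-emptiness. At
field-like occupancies this induces genuine negative cross-species
dependence — relative to the fixed-rows null, every pair's expected α is
shifted by ≈ −(n−1)·pₐp_b·P(empty)/((1−P(empty))²σ). Two consequences:

1. In the field-flavoured defaults all raw affinities θᵢⱼ are positive;
   association vs avoidance is encoded in their *differences*.
2. The SES-calibration experiments (generator with θ_pair ≡ 0 feeding the
   association index) use inclusion intensities θ = 2 (per-species
   occupancy ≈0.88, P(empty) ≈ 2×10⁻⁴), chosen a priori so the residual
   shift (≈0.02 in α) is negligible and the experiment isolates the
   calibration of the index itself rather than the generator's constraint.

**Calibration experiment design.** The SES check pools all pair ×
replicate α values (6 pairs × 100 replicates of 250 shoals) and requires
the pooled mean in [−0.1, 0.1] and pooled variance in [0.8, 1.2]: with 600
draws of a unit-variance statistic these bands sit at ≈2.4 and ≈3.5
standard errors. A per-pair version of the same bands would be rejected
with high probability by a *perfect* implementation (the Monte-Carlo SE of
a 100-replicate per-pair mean is exactly 0.1), so pooling is the
statistically meaningful form of the check. The Tweedie coverage check is
pooled across the 9 coefficients × 100 replicates (2-SE coverage ≥93%,
nominal ≈95.4%) for the same reason. The Monte-Carlo-vs-closed-form check
bounds each pair's |α_MC − α_analytic| by 4 delta-method SEs of α̂_MC —
the SE must include the σ̂ noise term α²/(2n_null), otherwise pairs with
|α| ≳ 2 fail spuriously.

**What the generator does not emulate**, hence what passing tests do not
show about real field data: within-shoal abundance structure (symmetric
allocation only), spatial or temporal autocorrelation between shoals
(i.i.d. draws; no location effects on composition), observer effects,
fission–fusion dynamics within an observation, and any dependence between
a focal fish's shoal and the shoal-composition census (the two tables are
generated independently). Tests validate the statistical machinery, not
ecological conclusions.

## Problem sizes and runtimes

The test suite's simulation experiments use: 50 random matrices (4–8
species × 20–100 shoals) at 10,000 nulls for the Monte-Carlo/closed-form
comparison; 100 replicates of 250 shoals at 1,000 nulls for SES
calibration; every 2×2 table with grand total ≤ 40 (≈136k tables) for the
exact-test oracle; 100 replicates of n = 2000 for Tweedie recovery; 1,000
three-group datasets (30 shoals per group) for familywise-error
calibration; and 50 replicate pairs of n = 1500 for power-profile
ordering. The full suite runs in about a minute on one CPU;
`scripts/acceptance.py` in about half a minute.

## Known limitations

* The foraging model is fixed-effects only; with strong location or
  observer heterogeneity its SEs will be optimistic relative to a mixed
  model.
* EQL power profiling is biased low and is only trusted for ordering, not
  point estimation, of p.
* The exact Fisher CI comes from inverting the exact test at 2.5% per
  tail, which is conservative (as is conventional).
* Bout rates are generated as thinned bites, so the generator cannot
  produce bout–bite correlation structures other than binomial thinning.
* The association index is a pairwise SES; no community-level metrics
  (C-score, nestedness) are computed.
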