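# shoalmix

Analysis pipeline for **mixed-species shoaling in tropicalizing reef-fish
assemblages**: do range-extending herbivores (here the Lessepsian
rabbitfishes *Siganus luridus* and *S. rivulatus*) form non-random
associations with native Mediterranean herbivores (*Sarpa salpa*,
*Sparisoma cretense*), and does shoaling with other species change an
individual's foraging rate?

The package is written for behavioural and community ecologists working
with shoal-composition censuses (one row per observed shoal, per-species
counts) and focal-individual foraging observations (body length, shoal size
and type, observation duration, bite/bout counts). It implements three
linked analyses plus a synthetic-data generator so that every stage can be
validated against known ground truth without the field dataset.

## The statistics at the core

**Pairwise association strength.** Shoal compositions are compiled into a
binary species × shoal presence–absence matrix. The null model fixes each
species' number of occurrences (row totals) and reassigns them to shoals
uniformly at random; column totals are free. For species pair *(a, b)* with
observed co-occurrence count *O*,

> α = (O − μ) / σ,

where μ and σ are the mean and SD of the co-occurrence count across 1000
null matrices (Monte Carlo) or, equivalently, from the closed form of this
null — *O* is hypergeometric under independent uniform row placement, so
μ = rₐr_b/n and σ² = rₐr_b(n−rₐ)(n−r_b)/(n²(n−1)). Positive α = association,
negative = avoidance; under the null α is a calibrated standardized effect
size (mean 0, variance 1).

**Shoal configurations.** Each shoal is classified by origin
(native-only / range-extending-only / mixed-origin) and type
(mono-/multi-specific). The propensity of the two single-origin groups to
form multi-specific shoals is compared with Fisher's exact test
(probability-ordering two-sided p, conditional-MLE odds ratio, exact 95%
CI) and a χ² test; log shoal size is modelled on the configuration factor
with Tukey-adjusted pairwise contrasts and a compact letter display.

**Foraging rates.** Bite and bout rates (per minute) are non-negative with
exact zeros, so they are modelled with a Tweedie GLM (log link, variance
φμᵖ, 1 < p < 2 — a compound Poisson–gamma law), fitted by iteratively
reweighted least squares:

> log μ = origin × shoal type × shoal size + body length

From the fit the package derives per-cell shoal-size slopes, their
pairwise differences, and between-group rate ratios at a small reference
shoal (~3 fish), all with studentized-range (Tukey) adjusted p-values. The
power p defaults to 1.5 and can be profiled over a grid by extended
quasi-likelihood.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data drawn from the default generator, whose parameters are calibrated to
emulate the field conditions (250 shoals over 7 locations, ≈29/43/28%
origin split, the published association pattern, and 294 foraging records
with the published slope structure):

```bash
python analysis/01_simulate.py --seed 1         # writes data/synthetic/
python analysis/02_shoal_configurations.py      # writes results/
python analysis/03_association_strength.py --seed 1
python analysis/04_foraging_rates.py
```

Output of `02` (one seed-1 realization of 250 shoals):

```
250 shoals:
  native_only              71  (28.4%)
  range_extending_only    112  (44.8%)
  mixed_origin             67  (26.8%)
multi-specific shoaling, native vs range-extending: OR = 0.056 (95% CI 0.001-0.361),
exact p = 0.0001; chi2 = 13.952, p = 0.0002
log shoal-size model (Tukey letters):
  mixed_origin           mean log size 2.246  [a]
  native_only            mean log size 1.351  [c]
  range_extending_only   mean log size 1.911  [b]
```

Native-only shoals are the smallest (their own Tukey letter), and
native-only shoals are far less likely than rabbitfish shoals to be
multi-specific (odds ratio ≪ 1).

Output of `03` — the association index, Monte-Carlo vs closed form:

```
  Sarpa_salpa          Sparisoma_cretense   O=  24 alpha= -0.48  (closed form  -0.51)
  Sarpa_salpa          Siganus_rivulatus    O=  48 alpha=  1.02  (closed form   1.01)
  Siganus_luridus      Siganus_rivulatus    O=  66 alpha=  1.47  (closed form   1.52)
  ...
```

*S. rivulatus* associates positively with both *S. luridus* and the native
*S. salpa*; the native pair avoids each other — the qualitative pattern the
generator was parameterised to produce.

Output of `04` (bite/bout summaries and the Tweedie fit):

```
  native           bite  23.1 ± 0.93  bout  5.17 ± 0.31  (n=145)
  range_extending  bite  32.3 ± 1.33  bout  5.05 ± 0.26  (n=149)
rate ratios at shoal size ~3:
  range_extending/mono_specific - native/mono_specific   ratio 1.312 (Tukey p 0.028)
```

Range-extenders bite faster on average; at small shoals natives forage at
roughly 1/1.31 ≈ 76% of the range-extenders' rate in this realization
(the generating value is 65%).

The same stages are available as a CLI
(`shoalmix simulate|associate|configure|forage|run`); `shoalmix run
--simulate --seed 7 --out-dir out/` executes everything and writes a
manifest from which the run can be reproduced byte-for-byte.

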