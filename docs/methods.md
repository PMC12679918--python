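# Methods

`strigamet` analyses multi-environment maize hybrid trials run in contrasting
*Striga hermonthica* regimes (artificially infested vs *Striga*-free fields).
This note documents the statistical models, the synthetic-data generator that
drives the test suite, and the numerical and design choices behind each
module.

## Trial model and ANOVA

Trials are resolvable incomplete-block (alpha-lattice) designs: each
environment (location x year x *Striga* treatment) contains `reps_per_env`
complete replicates, and each replicate partitions the entry list into
`blocks_per_rep` blocks of `block_size` plots (default 13 blocks of 12 for
156 entries). The combined analysis of variance decomposes a trait `y` as

    y = mu + E + Rep(E) + Block(E x Rep) + Hybrid + Hybrid x E + error.

Sums of squares are **sequential (Type I)** in that fixed order, computed by
orthogonalizing each term's one-hot indicator block against the span of all
preceding terms (two rounds of block Gram–Schmidt, then an SVD with a
rank tolerance of `1e-8 * sqrt(n)`). On the balanced complete layouts this
pipeline produces, Type I equals Type III and the classical means
decomposition; the sequential sweep additionally handles mildly unbalanced
data (dropped plots or environments) exactly. Layouts in which an entry is
entirely absent from an environment are refused with an explicit error
rather than silently reparameterized.

Hybrids are fixed; environments, replicates and blocks are random. The
F-test denominators follow the corresponding expected-mean-square structure:
Hybrid is tested against Hybrid x E, Hybrid x E and Rep/Block against the
residual, and Environment against Rep(E).

**LS means** come from the additive model (no Hybrid x E term), fit by
minimum-norm least squares; each entry's LS mean is its model prediction
averaged with equal weight over every observed (env, rep, block) cell. On
balanced data this equals the entry's arithmetic mean; under the lattice's
fixed-block adjustment it is the intra-block adjusted mean. Recovery of
inter-block information is deliberately out of scope.

**LSD** is `t(1 - alpha/2, df) * sqrt(2 * MS / n_eff)`. For across-environment
hybrid means the comparison mean square is the Hybrid x E interaction MS
(the same quantity that serves as the hybrid F-test denominator), with
`n_eff` the harmonic-mean number of plots per entry — `reps x environments`
when balanced. Using the residual MS instead would overstate precision
whenever genotype-by-environment variance is non-zero.

Ratings (1–9 scales) and emergence counts are right-skewed; they are
transformed as `log10(x + 1)` before ANOVA (the offset admits zero counts;
the base is configurable). Selection indices operate on **raw-scale** LS
means, since index weights and published summaries are defined on the
measurement scales.

## Selection indices

Across infested environments the *Striga* base index is computed on
standardized (z-scored, sample SD with n−1) entry LS means:

    index = 2*MGY + EPP − (SHD1 + SHD2) − 0.5*(SEC1 + SEC2)

with MGY grain yield (t/ha), EPP ears per plant, SHD the 1–9 host-damage
scores at 8/10 weeks after planting (WAP) and SEC the emerged-*Striga*
counts at the same times. Standardization is across all entries jointly —
hybrids and checks — so checks are directly comparable (configurable by
subsetting the input). Positive index = tolerant/resistant, negative =
susceptible; an exact zero is flagged `boundary` rather than silently
classified. Because each z-vector sums to zero and the index is linear,
indices sum to zero over entries.

Across *Striga*-free environments the rank summation index (RSI) sums each
entry's per-trait ranks over grain yield, ears per plant, plant height, ear
aspect, plant aspect and days to 50 % silking; rank 1 is best per the
trait's orientation, ties receive average ranks (keeps totals comparable),
and the lowest total marks the most superior hybrid. Orientation of plant
height and silking date is genuinely ambiguous in practice (vigor vs
earliness); the registry defaults rank taller plants and earlier silking as
better, and both are overrideable per call.

## Associations

Correlations are pairwise-complete Pearson r on entry-level LS means (one
value per hybrid, the resolution at which such tables are read; plot-level
correlation is possible by passing plot records), with two-sided t tests of
H0: rho = 0 and significance stars at 0.05/0.01/0.001. Cross-regime
prediction fits OLS of a trait in one regime on a trait in the other, in
both directions; simple-regression R² equals the squared pair correlation,
and forward/reverse slopes multiply to r².

Forward stepwise regression of yield on agronomic traits uses SAS-style
entry/stay thresholds, default SLE = SLS = 0.15. At each step the candidate
with the largest partial R² enters if its partial-F p-value is ≤ SLE, then
any included term with stay p > SLS is removed; removals are recorded with
negative partial R² so step increments always sum to the final model R².
Candidates with R² > 0.999 on the included set are skipped as collinear.

## GGE biplots

The genotype x environment yield-mean matrix is environment-centered (no
scaling; "centering = 2, scaling = 0" in biplot parlance) and decomposed by
full SVD. Singular value partitioning is genotype-focused by default
(genotype scores U·S, environment scores V), with symmetric and
environment-focused modes available; the partitioning never changes the
percent variance explained per PC. The average environment axis (AEA) is
the unit vector through the mean of the environment scores in the PC1–PC2
plane only (as in printed biplots, not full-rank space); a genotype's AEA
abscissa approximates mean performance and its perpendicular ordinate the
instability, regardless of sign. The SVD's sign ambiguity is resolved by
requiring the abscissa to correlate positively with genotype marginal
means. Missing cells are refused (no imputation), and an all-equal matrix
yields an explicitly flagged degenerate model. The standard "mean vs
stability" run subsets 8 best + 3 worst hybrids plus the best check,
selected by base index (infested) or RSI (free).

## Synthetic-data generator

The generator exists so every stage is testable with known ground truth; it
emulates the design and the correlation structure of real *Striga* trials,
not any particular dataset. Defaults (chosen once as the study conditions):

| parameter | default | meaning |
|---|---|---|
| `mu_yield` | 4.9 t/ha | mean yield in *Striga*-free plots |
| `var_genotype` | 0.02 (t/ha)² | genetic main-effect variance |
| `var_env` / `var_gxe` | 0.40 / 0.05 | environment and GxE variances |
| `var_rep` / `var_block` / `var_error` | 0.01 / 0.02 / 0.20 | design and residual variances |
| `striga_damage_slope` | 1.1 | damage-score units per susceptibility SD |
| `emergence_mean_tolerant/susceptible` | 10 / 24 | negative-binomial count means |
| `yield_penalty_per_damage` | 0.085 | fractional yield loss per damage unit |
| `nb_dispersion` | 2.0 | gamma shape of the shared count heterogeneity |

Entries carry two latents: a standardized agronomic quality `q` (drives the
genetic yield effect `G = sqrt(var_genotype)·q`, heights, aspect ratings and
ears per plant) and a standardized *Striga* susceptibility `s` (tolerant
class ~ N(−0.4, 0.55²), susceptible ~ N(1.2, 0.55²), default 75 % tolerant,
assigned directly at hybrid level). Damage scores are a rounded, clamped
Gaussian latent `5 + slope·s + shared plot noise` — the simplest ordinal
model with a monotone link to susceptibility — with the 10-WAP score
constrained to at least the 8-WAP score minus one. Emergence counts are
gamma-Poisson (negative binomial) with a plot-shared gamma rate, giving the
strong within-plot 8/10-WAP correlation (≈0.95) seen in field counts.
Infested-plot yield is the linear-model yield times
`1 − penalty·(SHD2 − 1)`, which produces a ~30–35 % mean yield reduction and
a plot-level yield–damage correlation near −0.7; aspect scores load
positively and ears per plant negatively on susceptibility, reproducing the
qualitative sign pattern of infested-trial correlation tables.

`var_genotype` is deliberately small relative to the damage-driven variance,
so that performance in one regime only weakly predicts the other
(cross-regime R² ≈ 0.01–0.03, |slope| ≈ 0.1–0.25 at 150 hybrids) — the
regime-specificity that motivates running separate infested and free
selections in the first place. Blocks are seeded random partitions of the
entry list per replicate, not efficiency-optimized alpha(0,1) designs:
downstream analyses need only the blocking factor. An environment-dropping
switch (the default environment set omits one free location-year) emulates
the common loss of a site without simulating logistics.

What the generator does **not** emulate: spatial field trend within blocks,
measurement error on ratings beyond the latent noise, non-Gaussian yield
residuals, and any parent-level genetic structure (hybrids are exchangeable
given their class). Variance components and heritabilities are free
parameters, not estimates of any particular study; passing tests therefore
demonstrate correctness of the estimators and the qualitative field
structure, not quantitative agreement with any real trial.

## Verification strategy and problem sizes

Exact oracles: balanced-toy ANOVA against a brute-force means
decomposition; GGE singular values on a 3×3 matrix against the
characteristic polynomial of the Gram matrix; base index and RSI on small
printed tables against hand arithmetic; LS means on unbalanced toys against
a sum-contrast OLS fit. Closed-form limits: additive (no-GxE) data give
PC1 = 100 % and zero AEA ordinates; constant traits give all-zero indices;
slope products equal r².

Stochastic suites run at sizes chosen for statistical validity: parameter
recovery pools method-of-moments estimates over 10 full-size trials
(2184 plots each) with the damage penalty off, so yield follows the pure
linear model whose components are being recovered; null calibration of the
hybrid F test uses 200 trials of a scaled-down 20-entry design (p-value
uniformity is exact at any size under the null); stepwise selection is
checked over 100 seeds at n = 150. All random draws use
`numpy.random.default_rng` with explicit seeds; identical seeds give
byte-identical outputs, and every pipeline run writes a JSON manifest from
which it can be reproduced exactly.

## Known limitations

- No REML variance-component estimation or inter-block information
  recovery; the ANOVA is fixed-effect least squares with mixed-model
  F denominators.
- LSD assumes a common comparison MS across all entry pairs; with strong
  imbalance, pairwise standard errors would differ.
- The GGE view is restricted to the PC1–PC2 plane; which-won-where and
  discrimination-vs-representativeness views are not implemented.
- Stepwise regression inherits the usual caveats of sequential selection
  (post-selection p-values are not honest).
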