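# Methods

## Size classes and normalization

Individual dry mass *m* (µg) is assigned to the integer class
*n* = ⌊log₂ *m*⌋, implemented through the float's binary exponent
(`math.frexp`) so exact powers of two land in the class whose lower
bound they equal (16 µg → class 4) without floating-point drift. Class
width is Δₙ = 2ⁿ µg; normalized biomass is NBₙ = Bₙ/2ⁿ, where Bₙ is the
summed dry mass of the class per 0.1 m². Empty classes are absent, not
zero: a zero NB has no logarithm and contributes no regression point.
Normalization is exactly invertible (Σ NBₙ·2ⁿ reproduces total biomass
to round-off), which the tests assert at 10⁻¹² relative error.

## Allometric conversion

All masses are µg dry mass internally; the only unit conversions are at
the allometry boundary (mm, mm³ in; 1 mm³ water-equivalent = 1 mg; one
mg→µg point, `MG_TO_UG`). Biovolume is *V = L·W²·c* with a
dimensionless taxon shape coefficient *c*, except nematodes, which are
treated as cylinders π(W/2)²·L. Wet mass applies a specific gravity of
1.13 to all biovolume-derived masses (meio- and macrofauna alike; the
scope of that factor is genuinely ambiguous in the source protocols, so
it is a single config value). Dry mass is 0.25·WM for meiofauna and
macrofaunal nematodes and a per-taxon DM/WM factor for macrofauna.
Taxa with published direct dimension→mass regressions (crustaceans,
ophiuroids) bypass the biovolume route through `direct_mass_taxa`
entries (WM = b + a·L).

Shape coefficients and DM/WM factors are **not** hard scientific
constants of this package: the shipped tables are documented example
defaults in the published range for these groups, and real analyses
must supply their own. Lookups resolve taxon → genus → family → group
and fail loudly, naming the taxon, when nothing matches.

Fragmented polychaetes get an intact length from a per-taxon OLS of
body length on the width of a designated chaetiger, fitted on at least
five intact specimens; which chaetiger is measured is user
configuration. Fragments without a calibration are excluded with a
warning rather than silently mismeasured. Subsample expansion
multiplies measured count weights by total/measured, conserving counted
abundance exactly; area standardisation multiplies by 1000/area(cm²).

## NBSS fitting and comparison

The spectrum regression is OLS of log₂ NB on the class index. The
y-axis logarithm is base 2 so that axis units match the class axis and
an equal-biomass community has slope exactly −1; the intercept is
evaluated at class 0 (1 µg), uncentred. Cook's distances (default
threshold 4/n) flag influential points, with the lowest and highest
classes called out — the spectrum edges are where undersampling bites.

Sites are compared by ANCOVA: log₂ NB ~ class × site. The interaction
F (df k−1, N−2k) tests slope homogeneity; when slopes are homogeneous
the common-slope refit log₂ NB ~ class + site supplies the pooled
("fixed") slope with its SE and one intercept per site. The fixed-slope
model is deliberately this refit, not a regression constrained to a
literal constant — only a fitted pooled slope has a standard error.
Pairwise intercept contrasts use the studentized-range distribution
with k groups and the refit's residual df; with two groups this reduces
exactly to the two-sided t-test. Station-level intercepts for the
intercept–biomass correlation are refitted with free slopes per
station, and any class-range truncation is applied before *both* the
intercept refit and the total/mean-NB recomputation, since intercepts
are only comparable across stations when the class support is.

## Distance-based statistics

PERMANOVA partitions squared distances (SS_total = Σd²/N; SS_within
summed per group over within-group pairs) into the McArdle–Anderson
pseudo-F. P-values come from seeded label permutations, except that
when the number of distinct label arrangements is ≤ 10⁵ the complete
enumeration is used instead (the p-value is then exact; no
Monte-Carlo asymptotic approximation is attempted). RELATE is the
Spearman correlation of off-diagonal resemblances with row/column
permutation of one matrix; ranks are computed once and permuted with
the labels. Bray–Curtis operates on square-root-transformed biomass
tables, is stored as a dissimilarity in [0, 1], and is reported on the
0–100 similarity scale by convention. DistLM regresses the
Gower-centered distance matrix on z-scored predictors (standardisation
can be disabled); marginal pseudo-F p-values permute the raw
observations (rows/columns of the centered matrix), and forward
selection adds predictors greedily while adjusted
R² = 1 − (1 − R²)(n−1)/(n−m−1) improves. Exactly collinear later
predictors are dropped with a warning. The body-size–temperature models
are gamma GLMs with log link on individual dry masses; convergence
failures are reported as non-estimable rather than raised.

All permutation procedures take an explicit seed; identical seeds give
identical p-values.

## The synthetic community generator

The generator is target-first. For each station it fixes an expected
normalized-biomass curve

&nbsp;&nbsp;log₂ NBₙ = a_s + b·n + δ⊥(n) + ε,&nbsp; ε ~ N(0, σ²)

where (b, a_s) are the configured slope and the station's intercept,
σ (default 0.5) is class-level noise chosen to give fits with R² in the
visually realistic 0.85–0.95 range, and δ⊥ is a fixed *shape profile*:
a meiofaunal mode above the line (Gaussian at class −5.5), a dip at the
smallest classes (the 32 µm mesh limit region), the abundance trough
between faunal components (classes ≈ 2–5) and a macrofaunal mode
(classes ≈ 7–10). The profile is orthogonalised against {1, n} over the
multiset of class indices of a fjord's stations, so by linearity of OLS
the *expected* fitted slope and intercept equal the configured truth
exactly — the bimodal shape lives entirely in the residuals, as it does
in real spectra. Station intercepts a_s are the fjord intercept plus
(optionally) coefficients times standardized chlorophyll *a* and δ¹³C
drawn for that station, plus N(0, 0.25) station noise; that linkage is
what DistLM is expected to recover.

Class biomass splits among components by a logistic share falling from
meiofauna at small classes to macrofauna at large ones, with
macrofaunal nematodes taking a fixed fraction of the non-meiofaunal
share inside classes −6…6. Per class, a few representative masses are
drawn uniform in log₂ within the class bounds and given one common
count weight chosen so the class biomass is met *exactly*; weights are
guaranteed ≥ 1. Dimensions are then back-computed by inverting the
allometry (width from the cube root of biovolume at a taxon aspect
ratio, length = ratio × width), so the conversion chain is exercised
end to end and, in the noiseless configuration, a fitted spectrum
reproduces the configured line to ~10⁻⁹.

Two deliberate departures from a fully idealised design:

* **Station top classes.** The per-station top class cycles through
  (21, 16, 14) within each fjord. A design in which every station
  reaches class 21 would put ~99.9% of dry mass in macrofauna under any
  linear spectrum; with varying tops the macrofaunal share settles at
  0.96–0.99, large organisms are rare and patchy, and class-range
  truncation has the decorrelating effect on intercept–biomass
  correlations that motivates restricting to a common range.
* **Small-class meiofauna feasibility.** At the 10 cm² syringe-core
  area, classes around 3–5 have expected meiofaunal counts below one
  organism per core; their biomass share is carried by grab-sampled
  macrofauna instead so class biomass stays exact. Generated meiofauna
  therefore span classes −11 up to ~0–3 rather than a hard upper limit
  of 5.

The top class of a station is realised only if its target biomass is at
least half the class's minimum organism mass (otherwise the class is
empty for that station); a target between 0.5× and 1× the minimum is
realised as a single organism at the class floor. This truncation is
the one knowingly non-neutral realisation step; its slope effect is
~10⁻⁴ and is covered by the recovery tests' tolerance.

What the generator does **not** emulate: taxonomic turnover along
environmental gradients (taxon pools are fixed weights), within-station
spatial patchiness, counting error, gear selectivity curves, or
season. Passing recovery tests therefore demonstrates correctness of
the estimation chain under the assumed sampling model, not robustness
to those field realities.

## Numerical choices and degenerate inputs

Binning is exact at powers of two (binary-exponent extraction).
Regression through statsmodels OLS; a constant-response fit reports
R² = 1 when residuals vanish. Cook's distances are NaN-guarded for
perfect fits. Permutation p-values use (b+1)/(B+1) for sampled and b/B
for exhaustive null distributions, with a 10⁻¹² tie tolerance on the
statistic. DistLM returns F = ∞ when a predictor set explains the
distance matrix completely. Bray–Curtis refuses all-zero rows;
rank correlations refuse constant inputs; PERMANOVA refuses singleton
groups. Sampled areas must be positive; organism records must carry
either positive dimensions or a positive preset dry mass, and
count weights are ≥ 1 by contract.

## Problem sizes used in the test suite

Stochastic calibrations run at: 200 replicates of the 6 × 3-station
scenario for slope recovery, interaction behaviour and intercept-shift
power; 1000 simulations for PERMANOVA and DistLM type-I error (12 and
14 stations, 199 permutations); 2000 replicates for slope-CI coverage;
200 replicates for the truncation–correlation ordering. These sizes
give Monte-Carlo standard errors comfortably below the asserted
margins while keeping the default test run around three minutes.
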