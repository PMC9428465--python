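# Methods

`thermotrait` implements a trait-to-ecosystem analysis chain for microbial
thermal-gradient experiments: monoculture growth curves are reduced to
temperature-specific growth rates, rates are reduced to thermal-trait
parameters, and community colony counts along the same gradient are reduced
to diversity metrics and inferential statistics that connect the traits to
community structure and ecosystem function. A synthetic-data generator with
known ground truth stands in for raw experimental data and makes every stage
testable for parameter recovery.

## Models

### Logistic growth (per well)

Biomass in a well is modelled as

    N(t) = K / (1 + A e^{-r t}),    A = (K - N0)/N0

with `r` the exponential growth rate (h⁻¹), `K` the carrying capacity and
`N0` the initial biomass (both OD600). The fit minimises squared OD
residuals with `scipy.optimize.least_squares` (trust-region-reflective)
under the parameterisation `(r, K, f)` with `N0 = f·K`, `f ∈ (0, 1)` — this
encodes the constraint `K > N0 > 0` exactly in box bounds, and `r > 0` by
its own bound. One moment-based start (K from the maximum OD, r from the
early log-slope) plus 50 random starts (r uniform in 0.01–3 h⁻¹, K in
0.5–2× the max OD, N0 up to 2× the smallest positive OD) are run and the
lowest-RSS converged solution kept. Tolerances: `ftol = xtol = 1e-12`,
max 400 function evaluations per start.

Before fitting, sample wells are blank-corrected: the mean OD of the
medium-only wells at the same temperature and the nearest blank time point
is subtracted and the result floored at 0. Nearest-time matching tolerates
ragged timestamps between sample and blank schedules.

Quality control: a replicate whose corrected OD never reaches 0.05 is
excluded as non-growing — below that level the "growth" signal is
indistinguishable from baseline drift, and a rate fitted to it would be
noise. (A plateau-based rule — excluding fits whose K exceeds the observed
maximum OD — was considered and rejected: it discards slow-but-real growth
whose plateau falls beyond the observation window, and those mid-range rates
are exactly the ones that anchor the falling limb of the thermal curve.)
Rates are averaged across the technical replicates of each
taxon × temperature group; groups whose replicates are all excluded are
reported with a missing rate.

### Sharpe–Schoolfield thermal performance curve (per taxon)

Growth rate across temperature follows the high-temperature-deactivation
Sharpe–Schoolfield model on the log scale:

    ln r(T) = E_a (1/kT_c − 1/kT) + ln r(T_c) − ln(1 + e^{E_h (1/kT_h − 1/kT)})

with `k = 8.62e-5` eV K⁻¹, reference temperature `T_c = 291.15` K (18 °C,
overridable), activation energy `E_a` (eV), deactivation energy `E_h` (eV)
and half-inactivation temperature `T_h` (K). The inactivation term is
evaluated as `logaddexp(0, x)` so it cannot overflow. The optimum has the
closed form

    T_opt = E_h T_h / (E_h + k T_h ln(E_h/E_a − 1)),

defined only for `E_h > E_a > 0`.

Fitting: non-linear least squares of ln rate against the model from 1000
random uniform starts (E_a 0.05–2 eV, E_h 0.2–10 eV, T_h spanning the assay
range plus 20 K, ln r(T_c) within ±2 log-units of the data range; draws with
E_h ≤ E_a are rejected and redrawn), retaining the converged fit with the
lowest AIC among fits satisfying `E_h > E_a`. AIC is the Gaussian NLS form
`n ln(RSS/n) + 2(p+1)` with the error variance counted as a parameter;
goodness of fit is reported as a quasi-r² (1 − SSres/SStot on the ln-rate
scale). Pairs with non-positive rate are excluded before fitting — the
response is a logarithm, and substituting pseudo-counts would invent data;
at least five usable temperatures are required. Excluded temperatures are
logged and recorded on the fit object, as are the AICs of all valid
converged restarts (so the minimum-AIC retention rule is assertable).

### Diversity metrics

From colony counts per (temperature, replicate): relative abundances
`p_i = n_i/N`, richness `R` (taxa with positive count), Shannon diversity
`H' = −Σ p_i ln p_i` (nats), Pielou evenness `J = H'/ln R` and
rank-abundance curves (descending proportions, ties broken by taxon label).
Natural logs are used in both H' and J so that a perfectly even community
has `J = 1` at any richness. `J` is undefined (NaN) for monocultures —
`ln 1 = 0` makes the ratio genuinely undefined, and treating it as missing
rather than 0 or 1 is why evenness analyses run on fewer records than
richness analyses. The prevalence filter keeps, within each temperature,
only taxa present in **strictly more than** a given fraction (default 25%)
of that temperature's replicate communities; removal is per-temperature and
the operation is idempotent.

### Inferential layer

* **Sequential model ladder** (`polynomial_lrt`): fits `y ~ 1`, `y ~ x`,
  `y ~ x + x²` with raw polynomial terms and descends from the quadratic,
  dropping the highest-order term while the drop is non-significant at
  α = 0.05. Each nested comparison uses the partial F statistic
  `(RSS_red − RSS_full)/(RSS_full/df_resid)` on (1, df_resid) df. The
  asymptotic chi-square form `n ln(RSS_red/RSS_full)` of the same comparison
  was implemented first and rejected: at n ≈ 120 its per-step size is
  ≈ 0.055 rather than 0.05, which drags correct-null selection below 90%;
  the F form is finite-sample exact under Gaussian errors and is what R's
  `anova()` computes for nested linear models. RSS values are floored at
  the rounding-noise scale of an exact fit so that noiseless data cannot
  produce spurious signal from float error.
* **Trait–abundance ANCOVA** (`ancova_trait_abundance`): relative abundance
  regressed on a continuous taxon trait (T_opt, or the TPC-predicted growth
  rate at the assay temperature) with assay temperature as a categorical
  factor, in cell-means coding — one intercept and one trait slope per
  level, the full interaction model. The overall F compares this model with
  the intercept-only null (for 6 levels and n observations: df = (11,
  n − 12)). Levels whose observations carry fewer than two distinct trait
  values get no slope and are flagged inestimable. Pairwise slope contrasts
  between levels use Wald tests with Holm adjustment — a documented stand-in
  for single-step Tukey machinery, which is out of scope.
* **PCA** (`pca_composition`): SVD of the column-centred, unscaled
  relative-abundance matrix (proportions share a scale, so no
  standardisation). Component signs are fixed by making each component's
  largest-magnitude loading positive.
* **PERMANOVA** (`permanova`): the distance matrix is Gower-centred
  (G = −½ J D² J) and partitioned against the design via the projection
  (hat) matrix; pseudo-F = (tr(HG)/df₁)/((tr(G) − tr(HG))/df₂). This form
  reduces to the classical among/within-group decomposition for a one-way
  factor and also supports a continuous predictor (temperature as a
  covariate, df₁ = 1), since published analyses of this kind report either.
  p-values use the add-one estimator `(1 + #{F_perm ≥ F_obs})/(1 + n_perm)`
  over seeded whole-row label permutations (default 999); on small designs
  all distinct label arrangements can be enumerated exactly instead.
  Distances default to Bray–Curtis, `d(u,v) = 1 − 2Σmin(u_i,v_i)/Σ(u_i+v_i)`,
  the conventional choice for compositional data. Pairwise group
  comparisons multiply each raw p by the number of pairs (Bonferroni),
  capped at 1.

## Synthetic data generator

The generator emulates a two-stage experiment on a pool of taxa with
diverse thermal tolerance:

1. **Trait pool** (`gen_taxon_params`): T_opt uniform on 18.7–35.3 °C and
   E_a uniform on 0.23–1.06 eV — the trait ranges of the study system being
   emulated; the deactivation ratio E_h/E_a is uniform on 2–8 (so E_h > E_a
   always) and T_h is back-solved from the closed-form optimum. The
   reference-temperature rate r(18 °C) is uniform on 0.1–0.5 h⁻¹, typical
   heterotroph magnitudes.
2. **Monoculture plates** (`gen_growth_plate`): 9 assay temperatures
   (0–50 °C), 6 technical replicates, OD read every 2 h until 99% of K
   (capped at 240 h — a 10-day plate run), K = 1.0 OD, N0 = 0.01 OD, wells
   sitting on a 0.05-OD medium baseline carried by 4 blank wells per
   temperature. Noise is additive Gaussian on OD (default sd 0.005,
   truncated at 0) — plate-reader noise is approximately additive at low
   OD. No lag phase is simulated.
3. **Community assembly** (`gen_community_counts`): at each of 6 community
   temperatures (10–35 °C), expected proportions are
   `p_i ∝ max(r_i(T), 1e-6)^q` with selection exponent `q` (default 3);
   counts are multinomial draws of 200 colonies per replicate plate,
   20 replicates per temperature. `q` makes selection strength an explicit,
   testable knob: q = 0 is neutral assembly, large q is winner-takes-all.
   The power-law link between growth rate and final abundance is a modelling
   choice of this package — the conceptual assembly model it emulates is
   qualitative and specifies no quantitative mapping.
4. **Ecosystem function** (`gen_community_biomass`): expected day-7 biomass
   at temperature T is `K · mean_i r_i(T)/r_i(T_opt,i)` — a
   niche-complementarity-style summary under which production peaks where
   many taxa perform near their optimum and collapses at thermal extremes —
   plus Gaussian noise (sd 0.05 OD). The transient biomass dynamics over
   the 7 days (growth then logarithmic decline) are deliberately not
   simulated; only the end-point summary used by the function analyses is.

What the generator does **not** emulate: resource competition or other
species interactions (abundances are independent multinomial draws around
fitness-weighted expectations), lag phases, plate position effects,
correlated measurement error, colony-identification error, or taxa lost
before plating. Passing recovery tests therefore demonstrates that the
estimation chain is correct and well-calibrated under its own assumptions —
not that those assumptions hold for any particular real dataset.

## Numerical choices and degenerate inputs

* Temperatures are °C at every file and function boundary; Kelvin appears
  only inside the thermal-model arithmetic (`k` is fixed at the rounded
  8.62e-5 eV K⁻¹ conventional in this literature).
* Logistic fits reject series with < 4 points, < 2 distinct times, or
  constant OD (unidentifiable); TPC fits require ≥ 5 usable temperatures.
* A perfect (zero-RSS) fit yields AIC = −∞ with a warning so that exact
  synthetic data can still be ranked; quasi-r² of a zero-variance response
  is NaN with a warning.
* Zero-variance matrices give a degenerate PCA (zero scores and variance
  fractions) rather than an error; the degeneracy threshold is relative to
  the input scale.
* Bray–Curtis between two all-zero rows is undefined and returned as NaN
  with a warning; PERMANOVA refuses distance matrices containing NaN.
* Rank-abundance ties break by taxon label ascending, making output
  deterministic.
* One global seed drives independent, deterministic per-stage substreams
  (`numpy` `SeedSequence` spawn keys), so each stage is individually
  reproducible and re-running a pipeline bit-reproduces every artifact.

## Problem sizes used in the test suite and acceptance script

Calibration studies use 200 replicate datasets (PERMANOVA type-I error,
model-ladder power), 20 seeded realisations for fit-recovery medians, 200
TPC restarts and 20 logistic restarts per fit, and 199–999 permutations —
sizes at which the Monte-Carlo error of each check is comfortably below the
acceptance margin being tested.

## Known limitations

* The TPC form is the high-deactivation-only Sharpe–Schoolfield variant: no
  low-temperature inactivation term, so behaviour below ~5 °C is
  extrapolated Arrhenius rise.
* Confidence intervals for TPC parameters are asymptotic (Jacobian-based)
  and not currently propagated into downstream analyses.
* The exclusion rule for non-growing wells (OD < 0.05) trades a small
  downward bias in the number of usable temperatures for protection against
  noise-dominated rates; with very low carrying capacities the threshold
  should be lowered accordingly.
* PERMANOVA assumes exchangeability under the null; with strongly unequal
  group dispersions the test confounds location and dispersion effects, as
  all adonis-style tests do.
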