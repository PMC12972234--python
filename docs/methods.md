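# Methods

## Dental-age model

Dental age (DA) follows the Demirjian seven-tooth system: the developmental
stage (A–H, ordinal ranks 1–8) of each left mandibular permanent tooth from
central incisor to second molar is converted to a sex-specific self-weighted
score; the seven scores sum to a global maturity score on a 0–100 scale,
which a second sex-specific table maps to DA in years. Conventions adopted
where the system leaves room:

* **Laterality.** A congenitally missing left tooth is substituted by its
  right homologue; a bilaterally missing tooth yields a MISSING stage
  rating. Records with more than two MISSING positions are rejected rather
  than imputed — with so little signal left, prediction accuracy would
  degrade and severity itself confounds the target.
* **Score → age between knots**: linear interpolation; exact knots return
  the tabulated age. Scores outside the table range are clamped to the
  boundary age with a warning.
* **Chronological age (CA)**: (radiograph date − birth date) / 365.25 days,
  half-up rounded to one decimal. DA is kept at full precision internally.
* **Stage encoding for models**: ordinal integers A=1…H=8, preserving the
  monotone maturation information for tree ensembles.

### Reference tables

The original published score tables are not redistributable, so the package
ships a **synthetic stand-in** (`data/*_synthetic_v1.csv`) built from a
logistic maturation model: per sex, a latent maturity fraction
f(a) = 1/(1+exp(−k(a−a₀))) (k = 0.35, a₀ = 9.0 y for girls; k = 0.33,
a₀ = 9.6 y for boys — girls mature earlier), per-tooth stage-H weights
summing to exactly 100, and shared stage fractions
(0.04, 0.11, 0.21, 0.35, 0.52, 0.70, 0.86, 1.00) of each tooth's full
weight. The score→age table tabulates 100·f(a) on a 0.1-y age grid
(0–17 y) plus a terminal knot at score 100. Loaders validate every
structural invariant (non-negativity, monotonicity in stage, H-sum = 100,
strictly increasing conversion) for bundled and user-supplied tables alike;
all pipeline logic is table-agnostic.

## Pattern-wise random-forest imputation

For every distinct pattern of MISSING stage ratings (size 1 or 2), a
dedicated `RandomForestRegressor` predicts DA from the remaining stages plus
a binary sex indicator. Design choices:

* **Reference set**: all fully staged children with a computed DA, from
  either group; one shared, sex-stratified 80/20 train/test split (seeded)
  is reused by every pattern model to make their metrics comparable.
* **Hyperparameters**: grid over trees ∈ {300, 500, 1000}, features-per-split
  ∈ {2, 3, ⌈p/3⌉}, minimum leaf size ∈ {1, 5}; selection by out-of-bag RMSE
  on the training split only (ties: first grid point). The grid is a config
  knob; time-critical simulation loops use a single-point grid.
* **Guard rails**: at least 50 reference children or the model refuses to
  fit ("cannot impute" rather than a low-quality model); prediction demands
  an exact match between an individual's missing positions and the model's
  pattern; tree-ensemble predictions are inherently bounded by the training
  DA range.
* **Validation**: held-out R², ME, RMSE, MSE, MAE; Bland–Altman bias ±
  1.96·SD limits of agreement; permutation importance (increase in test
  MSE) for every predictor.

## Delay statistics

* **Group comparison** of DA − CA: pooled-variance Student t (Welch as an
  option), 95% CI from the t distribution; also computable from published
  summary statistics alone, and the two routes agree to numerical precision
  on identical data. A Wilcoxon rank-sum option covers non-normal settings.
* **Marked delay**: cutoff = control mean − 2·control SD of DA − CA at full
  precision; group proportions below the cutoff compared by a 2×2 χ² with
  Yates' continuity correction. (Recomputing the cutoff from *rounded*
  published moments can differ from the full-precision value in the last
  digit — e.g. 0.54 − 2·1.07 = −1.60.)
* **Regression**: OLS of DA − CA on agenesis × sex × CA (treatment coding,
  control/female reference levels, matching the sign convention of the group
  delta). Term contributions use a marginality-respecting **Type II ANOVA**
  implemented by nested-model RSS differences: each term is added to the
  model containing all terms that do not include it, and tested against the
  full model's residual mean square. This matches R's `car::Anova` (and
  statsmodels' `anova_lm(typ=2)`, cross-checked in tests). Rank deficiency
  raises an explicit error. Residual diagnostics: Shapiro–Wilk on residuals
  and a residuals-vs-fitted table.
* **Severity**: one-way ANOVA over {control, mild, moderate, oligodontia}
  followed by Tukey HSD; levels with n < 2 are dropped with a warning.
* **Patterns**: Kruskal–Wallis omnibus over TAC pattern groups, Dunn's
  post hoc z-tests with tie correction, Bonferroni-adjusted
  (p_adj = min(1, m·p)); singleton groups participate in the omnibus and are
  flagged pairwise. The second-premolar contrasts ("35", "45", "35+45" vs
  control) have first-class labels; regrouping (e.g. pooling either-side
  unilateral P2) is supported via a configurable mapping.
* **Sample size**: exact two-sided two-sample t-test power via the
  noncentral t. The continuous power-calculator solution for d = 0.413,
  α = 0.05, power 0.90 is n* = 124.17 per group; `n_per_group` returns the
  smallest integer n with power(n) ≥ target, which is **125** here, because
  the discrete power at n = 124 is 0.8996. Both numbers are exposed
  (`n_continuous`, `n_per_group`) since power calculators are often read by
  truncating n*.
* **Agreement**: unweighted Cohen's kappa, κ = (p₀ − p_e)/(1 − p_e), over
  the union of both raters' categories; per-tooth helper for repeat-scoring
  studies.

## Synthetic cohort generator

The generator emulates the world the analysis assumes, with defaults fixed
once to a realistic mid-size orthodontic cohort: n = 626 children, half
with agenesis, 57.5% girls, CA ~ Uniform(6, 15) years recorded to one
decimal.

* **Maturation**: a child's latent DA equals CA minus the injected delay
  (agenesis group only; defaults δ_f = 0.94 y, δ_m = 0.55 y, plus an
  optional extra `severity_gradient` per CMT beyond the first, default 0).
  Each tooth position receives an effective age = latent DA + N(0,
  `stage_noise_sd` = 0.5 y) and is discretised to the *nearest* stage
  implied by the reference tables (midpoints of normalised per-tooth
  contributions), left/right symmetric. Nearest-stage discretisation keeps
  the scoring of a noiseless child unbiased to within one quantisation
  step; the per-tooth noise then creates realistic stage scatter and an
  irreducible DA noise floor of about `stage_noise_sd`/√7 ≈ 0.19 y.
* **Agenesis**: per-tooth probabilities with mandibular second premolars
  (0.26) and maxillary lateral incisors (0.14) dominant and a bilateral
  correlation ρ = 0.3 (homologues share one Bernoulli draw with probability
  ρ); calibrated once so the mean CMT per affected child is ≈ 1.8 and
  bilateral P2 patterns are common enough to exercise the imputation
  models. Affected children always carry ≥ 1 CMT and never more than two
  bilateral mandibular pairs. Bilateral mandibular CMT blank both stage
  ratings.
* **What a green test does and does not establish**: the generator shares
  the scoring model's maturation curve, so recovery tests validate the
  pipeline's internal consistency (scoring inverts generation, imputation
  matches reference DA, the injected group effect is estimated without
  bias) — not the anthropological accuracy of any specific stage table.
  Real radiographic data add inter-rater error, non-uniform age
  distributions, population-specific maturation and secular trends that the
  generator does not model. Delay is injected on the latent dental-age
  scale; tooth-specific differential delays (field effects around the
  agenesis site) are out of scope.

## Numerical conventions and degenerate inputs

* Identical groups: t = 0, p = 1 (zero standard error with zero delta).
* No child below the marked-delay cutoff in either group: χ² = 0, p = 1.
* Kruskal–Wallis requires ≥ 2 groups; Dunn pairs with singleton groups are
  flagged, not dropped.
* `n_per_group` returns 2 when the minimum admissible group size already
  reaches the target power; a zero effect size raises.
* OOB RMSE ignores (rare) unestimated OOB predictions; ≥ 300 trees make
  them practically impossible.
* All randomness flows from explicit integer seeds (NumPy `default_rng`,
  sklearn `random_state`); reruns are bit-identical.

## Known limitations

* The bundled reference tables are synthetic stand-ins; absolute DA values
  are only meaningful once the published (or locally calibrated) tables are
  loaded.
* One shared 80/20 split across pattern models is a choice, not a law;
  per-pattern splits are available by passing `split=None` per pattern.
* The marked-delay cutoff assumes an approximately normal control
  distribution of DA − CA.
* Imputation models refuse patterns of more than two missing ratings;
  severe oligodontia cases therefore carry no DA and are excluded from the
  delay table (counted and reported).
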