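# Methods

## Sampling model and the local null

A plot is a set of `N_s` exchangeable pinpoints (default 300).  Species *i*
occupies a subset of `n_is` pinpoints; presence is binary per (pinpoint,
species), and several species may contact one pinpoint.  The two physical
survey lines are flattened into one index space `[0, N_s)`: the tests use
only counts, never geometry, and the null hypothesis — individuals placed
independently across pinpoints — is exchangeable, so line identity is
irrelevant.

Under that null the co-location count is `n_ijs ~ HG(N_s, n_is, n_js)`.
The one-tailed exact p-values are plain tail sums (`p+ = P(X ≥ n_ijs)`,
`p− = P(X ≤ n_ijs)`), computed by scipy's hypergeometric distribution.  No
mid-p correction is applied: the combination step requires superuniform
(valid) p-values, and mid-p sacrifices validity.  `p+ + p− = 1 + P(X =
n_ijs)` holds identically and is used as a self-check in the tests.

Because the test is discrete, each margin pair induces a finite *support*
of attainable p-values with known null masses.  The support object carries
the three downstream quantities: the minimum achievable p-value (the
detectability bound), the exact moments of `−ln p`, and the null CDF
`F(u) = P(p ≤ u)` used by the discrete FDR procedure.

## Combining evidence across plots

The regional null states independence in *every* plot where the pair
co-occurs; evidence is pooled with `T = Σ_s −ln p_s`.  Two evaluators of
`P(T_null ≥ T_obs)` are provided:

* **Moment-matched gamma** (`gamma2`, the default): a gamma with the exact
  mean and variance of the stratified discrete null.  `gamma3` additionally
  matches skewness with a shifted gamma (`a = 4/γ₁²`, `θ = √(σ²/a)`,
  shift `μ − aθ`).  Strata whose support is `{1}` carry no evidence and are
  dropped before matching — they would only flatten the gamma shape.
* **Exact convolution** (`exact`): the distribution of `T` enumerated over
  the product of the per-stratum supports, with atoms merged at relative
  tolerance 1e-9 and a configurable grid cap (10⁶ atoms); feasible for few
  plots or small supports and used as the authoritative oracle.

The gamma tail is clamped below at the exact probability of the single
most extreme joint outcome (the product of the extreme-point masses), so
the minimum-achievable combined p-value always lower-bounds any observed
combination, even when the gamma tail underflows.  All combined p-values
are additionally floored at 1e-300 to stay in `(0, 1]` in floating point.

The scaling of the statistic (`−ln p` vs `−2 ln p`) is immaterial: moment
matching and the exact convolution are equivariant under a positive scalar.

## Screening

*Detectability pre-filter.*  Per tail, each co-occurring pair's combined
p-value at its per-plot minima is computed with the same method used for
observed data; these minima are BH-adjusted across pairs and only pairs
with adjusted minimum strictly below α (default 0.05) are tested.  The
filter is sound because BH-adjusted values are coordinate-wise monotone in
the p-value vector, and every observable dataset dominates the all-minima
configuration; the validation suite re-verifies this on random margin
configurations.

*Regional calls.*  BH runs separately per tail over the tested pairs of
that tail (mirroring the asymmetric retention the pre-filter produces:
segregation loses rare pairs, aggregation loses saturating ones).  A pair
significant in both tails is labelled `both` — a context-dependent
association.  The pre-filter uses strict `< α`, the calls `≤ α`.

*Plot attribution.*  For each significant pair and tail, a discrete
Benjamini–Hochberg step-up runs over the pair's per-plot p-values.
Candidate thresholds are the union of attainable values across the plots;
the k-th critical constant is the largest attainable `t` with
`Σ_i F_i(t) ≤ kα`.  Superuniformity gives `Σ_i F_i(t) ≤ m·t`, so the
constants dominate the classical `kα/m` and the discrete procedure never
rejects fewer plots than classical BH.  The non-adaptive form is used; the
adaptive variant is out of scope.  The procedure is post-hoc by contract:
the pipeline only attributes plots for regionally significant pairs.

## Network stage

The signed network keeps signs as edge attributes; clustering
(transitivity = 3·triangles / connected triples) and the SBM operate on the
unsigned skeleton.  Connectance is emitted with two denominators — all
co-occurring pairs, and co-occurring pairs among associated species only —
because the two conventions differ by an order of magnitude on sparse
regional networks and published values are ambiguous between them.

Null benchmarks use `G(n, m)` with matched nodes and links, 999 replicates
by default, the add-one empirical rule `p = (1 + #{null ≥ obs})/(R + 1)`
(minimum attainable p = 1/(R+1)), pooled null degrees for the per-species
degree test (all nodes of `G(n, m)` are exchangeable), and BH across
species for hub calls.

The Bernoulli SBM is fitted by mean-field variational EM: damped fixed-point
E-step, closed-form M-step, spectral initialisation (regularised
symmetric-Laplacian embedding + k-means) plus random restarts.  Each
restart index reuses a fixed generator seed, so enlarging the restart set
can only improve the best fit — ICL is monotone in the number of restarts.
K is selected by the integrated completed likelihood of the hard partition:
completed Bernoulli log-likelihood at the MLE minus
`(K(K+1)/4)·log(n(n−1)/2)` for the block probabilities and
`((K−1)/2)·log n` for the mixing proportions.  Blocks are reported in
decreasing mean-degree order and named core / subordinate / peripheral only
when the selected K is 3; within-block connectance of blocks with fewer
than two members is NaN (flagged), never 0/0.

Group-abundance GLMs are quasi-Poisson (log link, Pearson-χ²/df scale),
baseline = plot individual count only, full = + abiotic covariates, with
the deviance-based adjusted R² `1 − (D_res/(n−p))/(D_null/(n−1))` used for
all model comparisons in the package.

## Trait and environment stage

Trait PCA is correlation-matrix PCA (z-scored columns, SVD); constant
columns are an error naming the column.  Pairwise PERMANOVA between block
centroids uses scikit-bio's seeded permutation test with BH across block
pairs; groups with one member are skipped with a warning.

Functional rarity follows the funrar conventions: distances are Euclidean
on z-scored traits rescaled to [0, 1] by the observed maximum;
distinctiveness is the abundance-weighted mean distance to co-occurring
species, `D_is = Σ_{j≠i} d_ij a_js / Σ_{j≠i} a_js`; scarcity is
`S_is = exp(−R_s ln 2 · a_is)` with `R_s` the plot richness, so an
averagely abundant species scores 0.5.  The verbal shorthand "inverse of
relative abundance" is a gloss of this exponential form, not a different
formula.  A species alone in its plot has undefined distinctiveness (NaN).
Group contrasts use two-sided Wilcoxon rank-sum tests (Kruskal–Wallis
globally for ≥ 3 groups).

The association-richness model regresses each plot's count of locally
significant associations (from the plot attribution stage) on the plot's
individual count (always included) plus abiotic covariates and optional
`a:b` interaction terms, quasi-Poisson as above.  Predictor pairs with
|r| > 0.95 raise an error telling the caller to drop one (the pipeline's
default covariate set keeps freezing degree days and drops precipitation,
which tracks it).  Stepwise selection searches both directions from the
full model on adjusted R², with a **minimum improvement margin of 0.01**
per move: a term enters only if it raises adjusted R² by more than the
margin and is dropped whenever removing it costs no more than that.  Plain
adjusted-R² maximisation admits 1-df noise covariates in most null
replicates; the margin restores parsimony (null calibration: abiotic terms
retained in well under half of pure-noise replicates) at the price of
insensitivity to covariates worth less than one R² point.

Hierarchical partitioning is Shapley-value averaging: each predictor's
share is its mean incremental adjusted R² over all orderings of entry,
computed by all-subsets enumeration with level weights (capped at 8
predictors, 2⁸ fits).  The shares telescope exactly to the full-model R²
(the empty model's R² is 0 by construction), which the tests assert at
1e-9.

## Synthetic data: what it emulates, and what not

`generate_survey` draws per-plot occupancy counts from a log-normal
abundance law (default median 18 contacts ≈ 6% of pinpoints, σ_log 0.55 — a
sparse sward), optionally modulated by a Gaussian niche on a 1-D gradient,
then places species uniformly without replacement.  A planted pair (i, j,
θ) places i uniformly and draws j by weighted sampling without replacement
with weight `exp(θ)` on i's pinpoints, realised by the Gumbel top-k trick
(equivalent to sequential weighted sampling); θ = 0 reduces *exactly* to
the uniform null, which the tests verify by chi-square goodness-of-fit
against the hypergeometric.  An optional linear θ(gradient) slope emulates
context-dependent sign switches.  Trait tables are group-wise log-normal
syndromes; block networks are direct Bernoulli draws from a planted Π.
Everything is byte-deterministic under the master seed.

The generator does **not** emulate within-line spatial autocorrelation,
micro-environmental heterogeneity inside a plot, dispersal, or multi-year
dynamics.  Passing tests therefore demonstrate correctness of the
statistics under the exchangeable-pinpoint null and power against
exponential-tilt alternatives — not robustness to micro-habitat confounding,
which in real data can mimic either association sign.

## Validation problem sizes

The simulation suite (`spatassoc.validation`, driven by both
`tests/test_acceptance.py` and `scripts/acceptance.py`) uses the following
desk-scale study conditions, chosen once:

* combination oracle: 200 random configurations, ≤ 3 plots, ≤ 40 pinpoints,
  observed counts drawn from the null; exact vs. full enumeration at 1e-12,
  gamma2 within half a log10 of exact for p ∈ [1e-5, 0.5];
* type-I validity: 10,000 null pairs from independent 3-plot × 8-species
  surveys (3 plots keep the exact convolution authoritative; many small
  surveys keep pairs nearly independent so the binomial MC-SE bound is
  honest);
* FDR: 500 replicates of 12 species / 66 pairs with 6 planted (≈ 10%
  alternatives), 5 plots; a discovery is false when unplanted or
  wrong-signed;
* power: 50 replicates of 20 plots × 20 species, margins ≈ 30/300, θ = ±3;
* pre-filter soundness: 1,000 random margin configurations, both tails;
* SBM: Π = [[0.75, 0.30], [0.30, 0.02]], 30+30 nodes, 20 seeds; ER
  parsimony on matched-density graphs;
* clustering calibration: 200 `G(60, 150)` observations against 199-replicate
  null ensembles;
* GLM recovery: 120 plots, log-link effects pH −0.7, N% +2.5,
  gamma-mixed overdispersion.

## Known limitations

* The gamma combination is an approximation; its worst observed deviation
  from the exact oracle is ≈ 0.5 log10 at single-stratum, highly discrete
  supports.  Use `combine.variant: exact` when plot counts are small.
* Independence across plots is assumed under the global null, as in the
  sampling design; shared regional drivers that survive plot-level
  conditioning would violate it.
* The SBM is binary and degree-naive; strongly heterogeneous degrees inside
  a block can split blocks by degree rather than connectivity profile.
* Stepwise selection with the 0.01 margin will not pick up abiotic effects
  worth less than one adjusted-R² point.
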