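# Methods

## The model

`carlogit` fits a Bayesian hierarchical logistic regression for a binary
outcome observed on women sampled in a two-stage cluster design
(clusters nested in states).  For woman *i* with outcome
*y*<sub>*i*</sub> ∈ {0, 1},

    y_i ~ Bernoulli(p_i)
    logit(p_i) = β0 + z_i'β + f_1(x_i1) + ... + f_p(x_ip) + f_spat(s_i)

where *z*<sub>*i*</sub> collects the dummy-coded categorical and
continuous fixed-effect covariates (including, by default, the survey
sampling weight as one continuous column — the weight enters the mean
structure as a covariate, not the likelihood), each *f*<sub>*l*</sub> is
a piecewise-constant "smooth" effect of a binned nonlinear covariate
(age, community % cut, community % support), and the spatial term for
the woman's state *s*<sub>*i*</sub> decomposes as

    f_spat(s) = u_s + v_s

with **u** a *structured* (spatially correlated) effect and **v** an
*unstructured* (independent) effect.  Four structures are fitted:

| structure  | spatial term | complexity rank |
|------------|--------------|-----------------|
| Base       | none         | 1 |
| IID        | v only       | 2 |
| Besag      | u only       | 3 |
| IID_Besag  | u + v        | 4 |

**u** carries an intrinsic conditional autoregressive (iCAR, Besag)
prior on the state adjacency graph: conditionally,

    u_j | u_-j, tau_s ~ N( mean of neighbours' u,  1 / (d_j * tau_s) )

with *d*<sub>*j*</sub> the neighbour count.  Jointly this is the improper
Gaussian Markov random field with precision τ<sub>s</sub>·L (L the graph
Laplacian), flat along the constant vector.  **v** is i.i.d.
N(0, 1/τ<sub>u</sub>).  Adjacency is binary queen contiguity when built
from polygons (any shared boundary point, including a single corner),
or a synthetic grid/ring/edge-list graph.

### Priors

* intercept β0: improper flat (Gaussian with precision 0);
* fixed effects β: N(0, 1/0.001) each;
* smooth-term levels f_l(bin): i.i.d. N(0, 1/τ_l);
* precisions τ_l, τ_s, τ_u: Gamma(shape 1, rate 5·10⁻⁵), i.e. the
  log-gamma prior on log τ used as the default by common INLA-style
  software.

These are deliberately weak; with the sample sizes involved the
likelihood dominates everything except the spatial precisions.

## Inference: Polya-Gamma Gibbs

The posterior is sampled by a blocked Gibbs sampler using Polya-Gamma
data augmentation.  Given ω_i ~ PG(1, η_i) (η the linear predictor), the
Bernoulli-logit likelihood becomes Gaussian in every linear block, so
(β0, β), each f_l, u and v all have exact multivariate-normal full
conditionals and each precision an exact Gamma full conditional — no
tuning parameters, no rejections in the outer chain.  PG(1, z) variates
are drawn *exactly* with an alternating-series rejection sampler on the
tilted Jacobi density (numba-compiled; validated against the PG
series-representation moments).  The u-block is sampled jointly via a
Cholesky factor of τ_s·L + diag(Σω) (at most a states×states solve).

Numerical and identifiability choices:

* **Sum-to-zero constraint.**  The iCAR prior is flat along constants,
  so after each u-update the mean of u is subtracted and added to β0
  (the likelihood and prior are both invariant under this move, so the
  constrained chain is exact).  Every retained u draw sums to zero to
  floating precision.  Any constant component of a user-supplied initial
  u is dropped at initialisation for the same reason.
* **Smooth-term centring.**  Each f_l is likewise recentred per
  iteration with the mean absorbed into β0.  Because the i.i.d. prior on
  f_l is proper, this amounts to reporting f_l as a sum-to-zero contrast
  (the fitted probabilities are unaffected; only the split of the level
  between β0 and f_l is pinned down).
* **Empty bins** are retained and sampled from their conditional prior,
  so smooth-effect curves are defined over the covariate's full range.
* **Divergence guard.**  |η| > 500 raises an error naming the iteration.
* **Diagnostics.**  Split-R̂ and bulk ESS (via `arviz`) are computed for
  the scalar parameters; R̂ above 1.01 is recorded as a warning on the
  fit, never silently dropped.
* **Determinism.**  All randomness flows from `SamplerConfig.seed`
  through `numpy.random.SeedSequence` (one child stream per chain; the
  PG sampler is reseeded from the chain stream every iteration), so a
  fixed seed gives bit-identical draws; the default run is 4 chains ×
  5,000 iterations with 2,000 burn-in, and the bundled experiments use
  shorter, stated runs because the conjugate blocked sampler has short
  autocorrelation times.
* **Prior-only mode.** With an empty outcome vector the same chain
  samples the proper priors (the flat intercept is held fixed), which is
  used to verify prior recovery.

## Community covariates

The community is the sampling cluster.  From the microdata the package
derives per cluster: % of women cut, % supporting continuation of the
practice, the modal religion and wealth quintile (ties broken by
lexicographic label, for determinism), and the ethnic fractionalisation
index

    EFI = 1 - Σ_k s_k²,

s_k the within-cluster share of ethnic group k (0 for a mono-ethnic
cluster — the single-group limit of the formula — and at most 1 − 1/k).
By default the % cut and % support values attached to a woman *exclude
her own responses* (leave-one-out), so her outcome never appears in its
own predictor; the plain cluster-level aggregate is available with
`leave_one_out=False`.  Nonlinear covariates are binned: age into the
seven 5-year groups 15–19 … 45–49, percentages into ten equal-width
bins over [0, 100], right-open except the last.

## Model comparison and reporting

* **DIC** = mean posterior deviance + p_D, with
  p_D = mean(D) − D(θ̄) evaluated by plugging in the posterior mean of
  the per-observation linear predictor (the plug-in construction).
  Negative p_D is possible for ill-behaved posteriors and is reported
  as-is.
* **Structure selection.**  DIC differences below 2 are treated as ties;
  among structures within 2 of the minimum the lowest complexity rank
  wins.  This rule reproduces the retained structure in the published
  six-column DIC fixture bundled in the tests.
* **Posterior odds ratios** are exp(posterior mean of β) with
  exponentiated 2.5 %/97.5 % quantiles; an effect is "significant" when
  both endpoints fall on the same side of 1.  Reference levels are
  reported as POR 1 without an interval.
* **State prevalence.**  Per retained draw, the predicted state
  prevalence is the survey-weighted mean of p_i over the state's women
  (unweighted mode available); observed prevalence is the weighted mean
  of y_i.  R² is the squared Pearson correlation of observed vs
  predicted state prevalence (a sum-of-squares R² is available via
  `r2_method="ss"`); RMSE/MAE are in percentage points.

## The synthetic-data generator

`simulate_survey` inverts the model: it draws covariates, state effects
u (from the iCAR prior, sampled in the span of the nonzero-eigenvalue
Laplacian eigenvectors, hence exactly sum-zero) and v (i.i.d.), forms η,
and draws y ~ Bernoulli(logit⁻¹ η).  Defaults: a 6×6 rook grid of 36
states (the scale of a Nigeria-like federation of ~37 units), 10
clusters per state, 30 women per cluster (n = 10,800); modest
log-odds effects for residence, education, wealth, marital status,
religion and support for continuation; a rising age profile;
τ_s = τ_u = 4 (state effects with SD ≈ 0.5); weights log-normal with
mean 1 (normalised survey weights are positive and centred near 1);
ethnicity drawn per cluster from a Dirichlet(0.25) mixture over six
groups so that clusters range from near-mono-ethnic to highly mixed and
the EFI covariate has support across its range.  Community covariates
are *recomputed from the simulated outcomes* by the covariates module,
never injected, so the pipeline is exercised end to end.

What the generator does **not** emulate: any real country's ethnic or
religious composition, real DHS/MICS sampling fractions or stratified
weight construction, item nonresponse, within-cluster covariate
correlation beyond ethnicity, or reporting bias in the outcome.  Passing
tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to the ways real survey data
violate them.

## Experiment sizes

The bundled validation experiments use sizes chosen to make Monte-Carlo
error small relative to the tolerances they assert: quadrature
comparisons at n = 200 with 4 × 5,000 iterations; parameter recovery on
the default 6×6 / 10-cluster / 30-woman design over 20 replicate
surveys (1,200 iterations each, the conjugate sampler's autocorrelation
time being a few iterations); DIC discrimination on 3,600-woman surveys
over 10 replicates per scenario.

## Known limitations

* Blocked Gibbs mixes slowly in directions where blocks are strongly
  correlated — chiefly the intercept against cluster-level covariates
  (EFI, modal religion) and the state effects.  Split-R̂ flags this on
  short runs; the per-observation probabilities and prevalence
  predictions are far better identified than those individual
  coefficients.
* The Besag term is unscaled (no Riebler-style scaling of the
  structural variance); τ_s is therefore graph-dependent.
* The weight-as-covariate convention follows the analysis it mirrors; a
  design-based (likelihood-weighted) pseudo-posterior is out of scope.
* No interaction terms between individual and community covariates.
* DIC is the only comparison criterion (no WAIC/LOO).
* Disconnected adjacency graphs are rejected rather than handled
  per-component.
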