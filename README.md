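# carlogit

Bayesian hierarchical spatial logistic regression for small-area survey
prevalence — built for analyses of binary health outcomes (the
motivating application is female genital mutilation status among women
aged 15–49 in two-stage DHS/MICS-style household surveys) where the
question is both *who* is at risk (individual and community covariates)
and *where* (state-level prevalence with uncertainty).

For woman *i* in state *s<sub>i</sub>*,

```
y_i ~ Bernoulli(p_i)
logit(p_i) = β0 + z_i'β + f_1(x_i1) + … + f_p(x_ip) + u_{s_i} + v_{s_i}
```

with dummy-coded fixed effects `z_i'β` (including the survey sampling
weight as a covariate), binned smooth effects `f_l` for nonlinear
covariates (age, community % cut, community % supporting continuation),
a spatially **structured** state effect `u` under an intrinsic CAR
(Besag) prior on the queen-contiguity adjacency graph, and an
**unstructured** i.i.d. state effect `v`.  Four structures — Base (no
spatial term), IID (`v`), Besag (`u`), IID + Besag (`u + v`) — are
compared by DIC with a parsimony rule (differences < 2 are ties, the
simpler structure wins).  Fixed effects are reported as posterior odds
ratios; state-level posterior predicted prevalence is summarised with
means, SDs and 95% intervals and scored against observed prevalence by
R², RMSE and MAE.

Inference is exact-MCMC: a Pólya-Gamma augmented Gibbs sampler with
conjugate updates for every block (no tuning), an in-house exact
PG(1, z) rejection sampler (numba-compiled), sum-to-zero constraints on
the intrinsic term, and split-R̂/ESS diagnostics.  A synthetic
two-stage cluster-survey generator with recorded ground truth supports
end-to-end validation: parameter recovery, DIC structure
discrimination, and quadrature-oracle checks of the sampler.  Community
covariates — % cut, % support, modal religion/wealth, and the ethnic
fractionalisation index `EFI = 1 − Σ_k s_k²` — are computed from
microdata per sampling cluster, with leave-one-out versions so a
woman's outcome never enters her own predictor.

See `docs/methods.md` for the full model, priors, constraints and
design choices.

## Worked example

```python
from carlogit import (SimulationConfig, simulate_survey, ModelSpec,
                      SpatialLogit, SamplerConfig)

sim = SimulationConfig(n_rows=4, n_cols=4, clusters_per_state=8,
                       women_per_cluster=25, seed=42)
microdata, truth = simulate_survey(sim)          # 3,200 women, 16 states

model = SpatialLogit.from_dataframe(
    microdata, ModelSpec(structure="IID", covariate_set="both"),
    graph=sim.resolve_graph())
result = model.fit(SamplerConfig(n_iterations=2000, n_burnin=500,
                                 n_chains=2, seed=7))
print(result.summary())
```

```
Bayesian spatial logistic regression (Polya-Gamma Gibbs)
================================================================
structure: IID (complexity 2)   covariates: both
observations: 3200   states: 16   chains x draws: 2 x 1500
DIC: 3336.5   pD: 40.7   mean deviance: 3295.8
WARNING: split-R-hat above 1.01 for: beta0, beta[efi], beta[main_religion=islam], tau_u
----------------------------------------------------------------
parameter                        mean         sd       2.5%      97.5%
intercept                      -1.634      0.339     -2.318     -1.029
residence=urban                 0.326      0.087      0.155      0.494
education=higher               -0.752      0.150     -1.052     -0.468
...
```

The generator's true log-odds effects here are +0.30 for urban
residence and −0.60 for higher education; both posterior intervals
cover them.  (The run is short — the R̂ warning on a few
weakly identified parameters is the diagnostics doing their job: the
intercept is strongly coupled with the cluster-level covariates and the
state effects, so those chains mix slowly, and their summaries should
be read with that extra uncertainty in mind.)  Reporting hangs off the
results object:

```python
table, national = result.state_prevalence()      # per-state, in percent
print("national: observed {observed_pct:.1f}%  predicted {predicted_pct:.1f}%"
      .format(**national))
print(result.fit_metrics())
print(result.posterior_odds_ratios().head(2))
```

```
national: observed 24.5%  predicted 24.5%
FitMetrics(r2=0.9386044295075261, rmse=1.9331114399272329, mae=1.3596819437071912)
 covariate       level   por  ci_2.5  ci_97.5  significant
 residence rural (ref) 1.000     NaN      NaN        False
 residence       urban 1.386   1.167    1.639         True
```

So the fitted model reproduces state prevalence with R² ≈ 0.94 and an
RMSE under 2 percentage points, and flags urban residence as a
significant risk factor (POR 1.39, interval entirely above 1) —
consistent with the generative truth.

The same pipeline is scriptable from the shell:

```sh
carlogit simulate --seed 1 --out run/          # microdata + adjacency + truth
carlogit profiles --microdata run/microdata.csv --out run/profiles.csv
carlogit compare  --microdata run/microdata.csv --adjacency run/adjacency.txt \
                  --covariate-set both --out run/dic.csv
carlogit run      --seed 1 --out run/full      # everything, one command
```

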