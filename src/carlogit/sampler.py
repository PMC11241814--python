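"""MCMC inference for the hierarchical spatial logistic model.

The posterior is that of a Bernoulli-logit regression with

* an improper flat prior on the intercept,
* N(0, 1/0.001) priors on fixed-effect coefficients,
* i.i.d. N(0, 1/tau_l) priors on the per-bin levels of each smooth
  (nonlinear-covariate) term,
* an intrinsic CAR (Besag) prior on structured state effects u,
* i.i.d. N(0, 1/tau_u) unstructured state effects v,
* Gamma(shape 1, rate 5e-5) hyperpriors on all precisions.

Sampling is by Polya-Gamma augmentation: given latent omega_i ~
PG(1, eta_i), every Gaussian block has a conjugate multivariate-normal
full conditional and every precision a conjugate Gamma full
conditional, so the sampler needs no tuning.  Identifiability of the
intrinsic terms is handled by recentring: u (and each smooth term) is
recentred to mean zero every iteration with the subtracted mean
absorbed into the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from ._polyagamma import sample_pg
from .adjacency import AdjacencyGraph
from .design import DesignData

_ETA_LIMIT = 500.0  # |linear predictor| beyond this is treated as divergence


class SamplerDivergence(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings.  Draws are a pure function of these settings
    plus the design, so a fixed seed gives bit-identical chains."""

    n_iterations: int = 5000
    n_burnin: int = 2000
    thinning: int = 1
    n_chains: int = 4
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.n_chains < 1 or self.thinning < 1:
            raise ValueError("n_chains and thinning must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thinning


@dataclass
class PosteriorFit:
    """Retained draws plus run metadata.

    Array draws have the chain axis flattened to shape
    (n_chains * n_retained, ...); ``chain_shape`` restores it.
    """

    draws: dict
    n_chains: int
    n_retained_per_chain: int
    x_names: list
    states: tuple
    bin_labels: dict
    categorical_levels: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    sampler_config: SamplerConfig | None = None

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_retained_per_chain

    def chain_shape(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape((self.n_chains, self.n_retained_per_chain) + arr.shape[1:])


def icar_full_conditional(u, graph: AdjacencyGraph, j, tau_s: float):
    """Mean and variance of u_j | u_{-j}, tau_s under the intrinsic CAR
    prior: the neighbour average, with variance 1 / (d_j * tau_s)."""
    idx = graph.index_of(j) if j in graph.nodes else int(j)
    nbrs = [graph.index_of(k) for k in graph.neighbours(graph.nodes[idx])]
    if not nbrs:
        raise ValueError(f"node {graph.nodes[idx]!r} has no neighbours; "
                         "the iCAR full conditional is undefined")
    u = np.asarray(u, dtype=float)
    d = len(nbrs)
    return float(u[nbrs].mean()), 1.0 / (d * tau_s)


def _pairwise_penalty(u, graph: AdjacencyGraph) -> float:
    """sum over unordered neighbour pairs of (u_k - u_j)^2 == u' L u."""
    pairs = graph.edge_index_pairs()
    if pairs.size == 0:
        return 0.0
    d = u[pairs[:, 0]] - u[pairs[:, 1]]
    return float(d @ d)


def log_posterior(params: dict, design: DesignData) -> float:
    """Unnormalised log posterior density at ``params``.

    ``params`` keys (all optional except what the spec's structure
    requires): beta0 (float), beta (k,), f (dict cov -> per-bin array),
    u (n_states,), v (n_states,), tau_f (dict cov -> float), tau_s,
    tau_u.  Nonpositive precisions give -inf.
    """
    spec = design.spec
    pri = spec.priors
    beta0 = float(params.get("beta0", 0.0))
    beta = np.asarray(params.get("beta", np.zeros(design.x.shape[1])), dtype=float)
    f = params.get("f", {})
    tau_f = params.get("tau_f", {})

    for name in ("tau_s", "tau_u"):
        if name in params and params[name] <= 0:
            return -np.inf
    if any(t <= 0 for t in tau_f.values()):
        return -np.inf

    eta = beta0 + design.x @ beta
    lp = 0.0
    for cov in spec.nonlinear:
        fl = np.asarray(f[cov], dtype=float)
        tl = float(tau_f[cov])
        eta = eta + fl[design.bin_index[cov]]
        lp += 0.5 * fl.size * np.log(tl) - 0.5 * tl * (fl @ fl)
        lp += np.log(pri.hyper_rate) - pri.hyper_rate * tl  # Gamma(1, rate)
    if spec.has_besag:
        u = np.asarray(params["u"], dtype=float)
        tau_s = float(params["tau_s"])
        eta = eta + u[design.state_index]
        lp += (0.5 * (design.n_states - 1) * np.log(tau_s)
               - 0.5 * tau_s * _pairwise_penalty(u, design.graph))
        lp += np.log(pri.hyper_rate) - pri.hyper_rate * tau_s
    if spec.has_iid:
        v = np.asarray(params["v"], dtype=float)
        tau_u = float(params["tau_u"])
        eta = eta + v[design.state_index]
        lp += 0.5 * v.size * np.log(tau_u) - 0.5 * tau_u * (v @ v)
        lp += np.log(pri.hyper_rate) - pri.hyper_rate * tau_u

    # Bernoulli log-likelihood, stable form
    lp += float(design.y @ eta - np.logaddexp(0.0, eta).sum())
    # Gaussian prior on beta (flat on the intercept: no contribution)
    lp += -0.5 * pri.beta_precision * (beta @ beta)
    if pri.intercept_precision > 0:
        lp += -0.5 * pri.intercept_precision * beta0 ** 2
    return float(lp)


def deviance(y: np.ndarray, eta: np.ndarray) -> float:
    """-2 * Bernoulli log-likelihood at linear predictor eta."""
    return float(2.0 * (np.logaddexp(0.0, eta).sum() - y @ eta))


def _sample_mvn(prec, b, rng):
    """Draw from N(prec^{-1} b, prec^{-1}) via Cholesky."""
    c, low = cho_factor(prec, lower=True)
    mean = cho_solve((c, low), b)
    z = rng.standard_normal(b.size)
    return mean + solve_triangular(c, z, lower=True, trans="T")


def _run_chain(design: DesignData, cfg: SamplerConfig, chain_seed, init=None):
    spec = design.spec
    pri = spec.priors
    y, x = design.y, design.x
    n, k = x.shape
    S = design.n_states
    sidx = design.state_index
    kappa = y - 0.5
    rng = np.random.default_rng(chain_seed)
    prior_only = n == 0

    # blocks present in this structure
    nl = list(spec.nonlinear)
    n_bins = {cov: design.bin_schemes[cov].n_bins for cov in nl}

    # initial state
    init = init or {}
    beta0 = float(init.get("beta0",
                           np.log((y.mean() + 0.01) / (1 - y.mean() + 0.01))
                           if not prior_only else 0.0))
    beta = np.array(init.get("beta", np.zeros(k)), dtype=float)
    f = {cov: np.array(init.get(f"f_{cov}", np.zeros(n_bins[cov])), dtype=float)
         for cov in nl}
    u = np.array(init.get("u", np.zeros(S)), dtype=float)
    v = np.array(init.get("v", np.zeros(S)), dtype=float)
    tau_f = {cov: float(init.get(f"tau_{cov}", 10.0)) for cov in nl}
    tau_s = float(init.get("tau_s", 10.0))
    tau_u = float(init.get("tau_u", 10.0))
    if spec.has_besag and not prior_only:
        # drop any constant component of the initial u: the intrinsic prior
        # is flat along it, so it carries no information and would otherwise
        # leak into the chain through the first linear predictor
        u = u - u.mean()

    if spec.has_besag:
        design.graph.require_connected()
        lap = design.graph.laplacian()
        pairs = design.graph.edge_index_pairs()

    xt1 = np.column_stack([np.ones(n), x])  # intercept + fixed effects
    prior_prec_diag = np.concatenate([[pri.intercept_precision],
                                      np.full(k, pri.beta_precision)])

    n_ret = cfg.n_retained_per_chain
    out = {
        "beta0": np.empty(n_ret), "beta": np.empty((n_ret, k)),
        "tau_s": np.empty(n_ret), "tau_u": np.empty(n_ret),
        "deviance": np.empty(n_ret),
    }
    for cov in nl:
        out[f"f_{cov}"] = np.empty((n_ret, n_bins[cov]))
        out[f"tau_{cov}"] = np.empty(n_ret)
    out["u"] = np.empty((n_ret, S))
    out["v"] = np.empty((n_ret, S))
    # per-draw state / national prevalence aggregates (weighted, unweighted)
    out["prev_state_w"] = np.full((n_ret, S), np.nan)
    out["prev_state_u"] = np.full((n_ret, S), np.nan)
    out["prev_nat_w"] = np.full(n_ret, np.nan)
    out["prev_nat_u"] = np.full(n_ret, np.nan)
    eta_sum = np.zeros(n)
    if not prior_only:
        w = design.weights
        wsum_state = np.bincount(sidx, weights=w, minlength=S)
        nsum_state = np.bincount(sidx, minlength=S).astype(float)
        with np.errstate(invalid="ignore"):
            inv_w_state = np.where(wsum_state > 0, 1.0 / np.where(wsum_state > 0, wsum_state, 1), np.nan)
            inv_n_state = np.where(nsum_state > 0, 1.0 / np.where(nsum_state > 0, nsum_state, 1), np.nan)

    def eta_of():
        e = beta0 + x @ beta
        for cov in nl:
            e = e + f[cov][design.bin_index[cov]]
        if spec.has_besag:
            e = e + u[sidx]
        if spec.has_iid:
            e = e + v[sidx]
        return e

    ret = 0
    for it in range(cfg.n_iterations):
        if prior_only:
            beta = rng.standard_normal(k) / np.sqrt(pri.beta_precision)
            for cov in nl:
                f[cov] = rng.standard_normal(n_bins[cov]) / np.sqrt(tau_f[cov])
                tau_f[cov] = rng.gamma(
                    pri.hyper_shape + 0.5 * n_bins[cov],
                    1.0 / (pri.hyper_rate + 0.5 * (f[cov] @ f[cov])))
            if spec.has_besag:
                from .simulate import sample_icar
                u = sample_icar(design.graph, tau_s, rng)
                tau_s = rng.gamma(
                    pri.hyper_shape + 0.5 * (S - 1),
                    1.0 / (pri.hyper_rate + 0.5 * _pairwise_penalty(u, design.graph)))
            if spec.has_iid:
                v = rng.standard_normal(S) / np.sqrt(tau_u)
                tau_u = rng.gamma(pri.hyper_shape + 0.5 * S,
                                  1.0 / (pri.hyper_rate + 0.5 * (v @ v)))
            eta = np.zeros(0)
        else:
            eta = eta_of()
            if not np.isfinite(eta).all() or np.abs(eta).max() > _ETA_LIMIT:
                raise SamplerDivergence(
                    f"linear predictor diverged at iteration {it}")
            pg_seed = int(rng.integers(0, 2 ** 31))
            omega = sample_pg(eta, pg_seed)

            # --- intercept + fixed effects block
            offset = eta - beta0 - x @ beta
            bvec = xt1.T @ (kappa - omega * offset)
            prec = (xt1 * omega[:, None]).T @ xt1
            prec[np.diag_indices_from(prec)] += prior_prec_diag
            draw = _sample_mvn(prec, bvec, rng)
            beta0, beta = draw[0], draw[1:]
            eta = offset + beta0 + x @ beta

            # --- smooth terms, one diagonal block per nonlinear covariate
            for cov in nl:
                bi = design.bin_index[cov]
                off = eta - f[cov][bi]
                bsum = np.bincount(bi, weights=kappa - omega * off,
                                   minlength=n_bins[cov])
                wsum = np.bincount(bi, weights=omega, minlength=n_bins[cov])
                prec_b = tau_f[cov] + wsum
                f[cov] = bsum / prec_b + rng.standard_normal(n_bins[cov]) / np.sqrt(prec_b)
                m = f[cov].mean()
                f[cov] -= m
                beta0 += m
                eta = off + f[cov][bi] + m
                tau_f[cov] = rng.gamma(
                    pri.hyper_shape + 0.5 * n_bins[cov],
                    1.0 / (pri.hyper_rate + 0.5 * (f[cov] @ f[cov])))

            # --- structured (Besag) state effects
            if spec.has_besag:
                off = eta - u[sidx]
                bs = np.bincount(sidx, weights=kappa - omega * off, minlength=S)
                ws = np.bincount(sidx, weights=omega, minlength=S)
                prec_u = tau_s * lap
                prec_u[np.diag_indices_from(prec_u)] += ws
                u = _sample_mvn(prec_u, bs, rng)
                m = u.mean()
                u -= m
                beta0 += m
                eta = off + u[sidx] + m
                du = u[pairs[:, 0]] - u[pairs[:, 1]]
                tau_s = rng.gamma(pri.hyper_shape + 0.5 * (S - 1),
                                  1.0 / (pri.hyper_rate + 0.5 * (du @ du)))

            # --- unstructured state effects
            if spec.has_iid:
                off = eta - v[sidx]
                bs = np.bincount(sidx, weights=kappa - omega * off, minlength=S)
                ws = np.bincount(sidx, weights=omega, minlength=S)
                prec_v = tau_u + ws
                v = bs / prec_v + rng.standard_normal(S) / np.sqrt(prec_v)
                eta = off + v[sidx]
                tau_u = rng.gamma(pri.hyper_shape + 0.5 * S,
                                  1.0 / (pri.hyper_rate + 0.5 * (v @ v)))

        if it >= cfg.n_burnin and (it - cfg.n_burnin) % cfg.thinning == 0:
            out["beta0"][ret] = beta0
            out["beta"][ret] = beta
            out["u"][ret] = u
            out["v"][ret] = v
            out["tau_s"][ret] = tau_s
            out["tau_u"][ret] = tau_u
            for cov in nl:
                out[f"f_{cov}"][ret] = f[cov]
                out[f"tau_{cov}"][ret] = tau_f[cov]
            if prior_only:
                out["deviance"][ret] = np.nan
            else:
                out["deviance"][ret] = deviance(y, eta)
                eta_sum += eta
                p = 1.0 / (1.0 + np.exp(-eta))
                out["prev_state_w"][ret] = (
                    np.bincount(sidx, weights=w * p, minlength=S) * inv_w_state)
                out["prev_state_u"][ret] = (
                    np.bincount(sidx, weights=p, minlength=S) * inv_n_state)
                out["prev_nat_w"][ret] = (w @ p) / w.sum()
                out["prev_nat_u"][ret] = p.mean()
            ret += 1
    return out, eta_sum / max(ret, 1)


def fit(design: DesignData, cfg: SamplerConfig = SamplerConfig(), init=None) -> PosteriorFit:
    """Run the Gibbs sampler and collect retained draws across chains.

    Returns a PosteriorFit whose draws include, besides the parameters,
    per-draw deviance and the posterior-mean linear predictor (for the
    plug-in deviance used by DIC).  Split-R-hat and effective sample
    sizes are computed for the scalar parameters; values of R-hat above
    the configured threshold are recorded as warnings, not errors.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chains = [_run_chain(design, cfg, s, init=init) for s in seeds]
    draws = {
        key: np.concatenate([c[0][key] for c in chains], axis=0)
        for key in chains[0][0]
    }
    draws["eta_mean"] = np.mean([c[1] for c in chains], axis=0)

    fitres = PosteriorFit(
        draws=draws,
        n_chains=cfg.n_chains,
        n_retained_per_chain=cfg.n_retained_per_chain,
        x_names=list(design.x_names),
        states=design.states,
        bin_labels={cov: design.bin_schemes[cov].labels for cov in design.spec.nonlinear},
        categorical_levels=dict(design.categorical_levels),
        sampler_config=cfg,
    )
    _diagnose(fitres, design)
    return fitres


def _diagnose(fitres: PosteriorFit, design: DesignData):
    import arviz as az

    scalars = {"beta0": fitres.chain_shape("beta0")}
    for j, name in enumerate(fitres.x_names):
        scalars[f"beta[{name}]"] = fitres.chain_shape("beta")[:, :, j]
    if design.spec.has_besag:
        scalars["tau_s"] = fitres.chain_shape("tau_s")
    if design.spec.has_iid:
        scalars["tau_u"] = fitres.chain_shape("tau_u")
    rhat, ess = {}, {}
    for name, arr in scalars.items():
        # split-R-hat needs at least two (split) chains of reasonable length
        rhat[name] = (float(az.rhat(arr))
                      if fitres.n_chains >= 2 and arr.shape[1] >= 4 else np.nan)
        ess[name] = float(az.ess(arr)) if arr.shape[1] >= 4 else np.nan
    fitres.diagnostics = {"rhat": rhat, "ess": ess}
    thr = fitres.sampler_config.rhat_threshold
    bad = [p for p, r in rhat.items() if np.isfinite(r) and r > thr]
    if bad:
        fitres.warnings.append(
            f"split-R-hat above {thr} for: {', '.join(sorted(bad))}")
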