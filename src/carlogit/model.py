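"""Model and Results objects: the package's main user-facing surface.

``SpatialLogit`` is built from woman-level microdata plus a model
specification (and an adjacency graph for the spatial structures);
``fit()`` runs the Gibbs sampler and returns a ``SpatialLogitResults``
carrying the posterior draws, their uncertainties, diagnostics and the
reporting methods (summary table, posterior odds ratios, state-level
predicted prevalence, DIC).  ``compare_structures`` fits the four model
structures on the same data and applies the DIC parsimony rule.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import evaluation
from .adjacency import AdjacencyGraph
from .covariates import community_profiles
from .design import STRUCTURES, DesignData, ModelSpec, build_design
from .sampler import PosteriorFit, SamplerConfig, fit as _fit_mcmc


class SpatialLogit:
    """Bayesian hierarchical logistic model for areal survey prevalence.

    Parameters
    ----------
    design : DesignData
        Assembled numeric design (see :func:`carlogit.design.build_design`).

    Use :meth:`from_dataframe` to go straight from microdata; community
    covariates are derived on the fly when the spec needs them.
    """

    def __init__(self, design: DesignData):
        self.design = design

    @classmethod
    def from_dataframe(
        cls,
        microdata: pd.DataFrame,
        spec: ModelSpec | None = None,
        graph: AdjacencyGraph | None = None,
        leave_one_out: bool = True,
        profiles: pd.DataFrame | None = None,
        woman_covariates: pd.DataFrame | None = None,
    ) -> "SpatialLogit":
        spec = spec or ModelSpec()
        needs_community = spec.covariate_set in ("community", "both") or any(
            c in ("pct_cut", "pct_support") for c in spec.nonlinear
        ) or "efi" in spec.continuous
        if needs_community and profiles is None:
            profiles, woman_covariates = community_profiles(
                microdata, leave_one_out=leave_one_out)
        design = build_design(microdata, spec, profiles=profiles,
                              woman_covariates=woman_covariates, graph=graph)
        return cls(design)

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    def fit(self, sampler_config: SamplerConfig | None = None,
            init: dict | None = None, **kwargs) -> "SpatialLogitResults":
        """Run MCMC; keyword arguments override SamplerConfig fields."""
        cfg = sampler_config or SamplerConfig(**kwargs)
        posterior = _fit_mcmc(self.design, cfg, init=init)
        return SpatialLogitResults(self, posterior)


class SpatialLogitResults:
    """Posterior summaries, diagnostics and reporting for one fit."""

    def __init__(self, model: SpatialLogit, posterior: PosteriorFit):
        self.model = model
        self.posterior = posterior

    @property
    def design(self) -> DesignData:
        return self.model.design

    # -- parameter summaries -------------------------------------------------

    def _scalar_draws(self) -> dict:
        d = self.posterior.draws
        out = {"intercept": d["beta0"]}
        for j, name in enumerate(self.posterior.x_names):
            out[name] = d["beta"][:, j]
        spec = self.design.spec
        for cov in spec.nonlinear:
            for b, lab in enumerate(self.posterior.bin_labels[cov]):
                out[f"f({cov})[{lab}]"] = d[f"f_{cov}"][:, b]
            out[f"tau_{cov}"] = d[f"tau_{cov}"]
        if spec.has_besag:
            out["tau_s"] = d["tau_s"]
        if spec.has_iid:
            out["tau_u"] = d["tau_u"]
        return out

    def params_table(self) -> pd.DataFrame:
        rows = []
        rhat = self.posterior.diagnostics.get("rhat", {})
        for name, draws in self._scalar_draws().items():
            lo, hi = np.quantile(draws, [0.025, 0.975])
            key = {"intercept": "beta0"}.get(name, name)
            rows.append({
                "parameter": name,
                "mean": draws.mean(), "sd": draws.std(),
                "q2.5": lo, "q97.5": hi,
                "rhat": rhat.get(key, rhat.get(f"beta[{name}]", np.nan)),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        spec = self.design.spec
        d = evaluation.dic_of_fit(self.posterior, self.design)
        lines = [
            "Bayesian spatial logistic regression (Polya-Gamma Gibbs)",
            "=" * 64,
            f"structure: {spec.structure} (complexity {spec.complexity})   "
            f"covariates: {spec.covariate_set}",
            f"observations: {self.design.n_obs}   states: {self.design.n_states}   "
            f"chains x draws: {self.posterior.n_chains} x "
            f"{self.posterior.n_retained_per_chain}",
            f"DIC: {d.dic:.1f}   pD: {d.p_d:.1f}   mean deviance: {d.mean_deviance:.1f}",
        ]
        if self.posterior.warnings:
            lines += [f"WARNING: {w}" for w in self.posterior.warnings]
        lines.append("-" * 64)
        tab = self.params_table()
        lines.append(f"{'parameter':<26}{'mean':>11}{'sd':>11}{'2.5%':>11}{'97.5%':>11}")
        for _, r in tab.iterrows():
            lines.append(
                f"{r['parameter']:<26}{r['mean']:>11.3f}{r['sd']:>11.3f}"
                f"{r['q2.5']:>11.3f}{r['q97.5']:>11.3f}")
        return "\n".join(lines)

    # -- reporting ----------------------------------------------------------

    def dic(self) -> evaluation.DICResult:
        return evaluation.dic_of_fit(self.posterior, self.design)

    def posterior_odds_ratios(self) -> pd.DataFrame:
        return evaluation.posterior_odds_ratios(self.posterior)

    def state_prevalence(self, weighted: bool = True):
        return evaluation.state_prevalence(self.posterior, self.design,
                                           weighted=weighted)

    def fit_metrics(self, weighted: bool = True,
                    r2_method: str = "pearson") -> evaluation.FitMetrics:
        table, _ = self.state_prevalence(weighted=weighted)
        return evaluation.fit_metrics(table["observed_pct"],
                                      table["predicted_pct"], r2_method=r2_method)

    def smooth_effect(self, covariate: str) -> pd.DataFrame:
        """Posterior summary of one nonlinear effect over its bins."""
        draws = self.posterior.draws[f"f_{covariate}"]
        lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
        return pd.DataFrame({
            "bin": list(self.posterior.bin_labels[covariate]),
            "mean": draws.mean(axis=0), "sd": draws.std(axis=0),
            "q2.5": lo, "q97.5": hi,
        })

    def plot_observed_vs_predicted(self, ax=None, weighted: bool = True):
        from .plots import observed_vs_predicted
        table, _ = self.state_prevalence(weighted=weighted)
        return observed_vs_predicted(table, ax=ax)

    # -- serialisation ------------------------------------------------------

    def save_draws(self, draws_path, metadata_path=None):
        """Write scalar draws to CSV with a JSON metadata sidecar."""
        pd.DataFrame(self._scalar_draws()).to_csv(draws_path, index=False,
                                                  float_format="%.10g")
        if metadata_path is not None:
            cfg = self.posterior.sampler_config
            meta = {
                "structure": self.design.spec.structure,
                "covariate_set": self.design.spec.covariate_set,
                "n_obs": int(self.design.n_obs),
                "n_states": int(self.design.n_states),
                "sampler": {
                    "n_iterations": cfg.n_iterations, "n_burnin": cfg.n_burnin,
                    "thinning": cfg.thinning, "n_chains": cfg.n_chains,
                    "seed": cfg.seed,
                },
                "diagnostics": self.posterior.diagnostics,
                "warnings": list(self.posterior.warnings),
            }
            with open(metadata_path, "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)


def compare_structures(
    microdata: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    graph: AdjacencyGraph | None = None,
    sampler_config: SamplerConfig | None = None,
    structures=STRUCTURES,
    leave_one_out: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Fit each model structure on the same data and compare by DIC.

    Returns the comparison table (with the parsimony-selected structure
    flagged) and the dict of fitted results keyed by structure name.
    """
    base_spec = base_spec or ModelSpec()
    cfg = sampler_config or SamplerConfig()
    fits = {}
    dics = {}
    profiles = woman_cov = None
    if base_spec.covariate_set in ("community", "both"):
        profiles, woman_cov = community_profiles(
            microdata, leave_one_out=leave_one_out)
    for structure in structures:
        spec = base_spec.with_structure(structure)
        model = SpatialLogit.from_dataframe(
            microdata, spec, graph=graph, leave_one_out=leave_one_out,
            profiles=profiles, woman_covariates=woman_cov)
        res = model.fit(cfg)
        fits[structure] = res
        dics[structure] = res.dic().dic
    table = evaluation.comparison_table(dics)
    return table, fits
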