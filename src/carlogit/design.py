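"""Model specification and design assembly.

A model is a cell of a 4 x 3 grid: one of four structures (Base; Base +
IID state effects; Base + Besag/iCAR state effects; Base + both),
crossed with one of three covariate sets (individual-level,
community-level, or both).  This module turns woman-level microdata plus
community profiles into the numeric design a sampler consumes: dummy
coding with explicit reference levels, bin indices for the nonlinear
covariates, the state index, and the survey weight as an extra
fixed-effect column (the analysis treats the design weight as a
covariate, not as a likelihood weight).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .adjacency import AdjacencyGraph
from .covariates import DEFAULT_BINS, BinningScheme, discretise

STRUCTURES = ("Base", "IID", "Besag", "IID_Besag")

#: parsimony rank used for DIC tie-breaking (1 = simplest)
COMPLEXITY = {"Base": 1, "IID": 2, "Besag": 3, "IID_Besag": 4}


@dataclass(frozen=True)
class PriorSettings:
    """Gaussian priors for the fixed effects; Gamma hyperpriors for the
    precisions of the smooth, structured and unstructured terms.

    The intercept prior is improper flat (precision 0); fixed effects
    are N(0, 1/0.001); every precision has a Gamma(shape 1, rate 5e-5)
    hyperprior.
    """

    intercept_precision: float = 0.0
    beta_precision: float = 0.001
    hyper_shape: float = 1.0
    hyper_rate: float = 5e-5


# categorical covariates of the synthetic schema with their reference levels
_INDIVIDUAL_CATEGORICAL = {
    "residence": "rural",
    "education": "none",
    "wealth_quintile": "poorest",
    "marital_status": "married",
    "ethnicity": None,  # reference = most frequent level (deterministic)
    "religion": "christian",
    "support_continuation": "no",
}
_COMMUNITY_CATEGORICAL = {
    "main_religion": "christian",
    "main_wealth": "poorest",
}

COVARIATE_SETS = {
    "individual": {
        "categorical": dict(_INDIVIDUAL_CATEGORICAL),
        "continuous": [],
        "nonlinear": ["age_years"],
    },
    "community": {
        "categorical": dict(_COMMUNITY_CATEGORICAL),
        "continuous": ["efi"],
        "nonlinear": ["pct_cut", "pct_support"],
    },
    "both": {
        "categorical": {
            "residence": "rural",
            "education": "none",
            "wealth_quintile": "poorest",
            "marital_status": "married",
            "main_religion": "christian",
        },
        "continuous": ["efi"],
        "nonlinear": ["age_years", "pct_cut", "pct_support"],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """One model configuration: structure x covariate set x priors x bins."""

    structure: str = "IID"
    covariate_set: str = "both"
    categorical: dict = None
    continuous: tuple = None
    nonlinear: tuple = None
    binning: dict = field(default_factory=lambda: dict(DEFAULT_BINS))
    include_weight_covariate: bool = True
    priors: PriorSettings = PriorSettings()

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        preset = COVARIATE_SETS.get(self.covariate_set)
        if preset is None and (self.categorical is None or self.nonlinear is None):
            raise ValueError(
                f"unknown covariate set {self.covariate_set!r} and no explicit lists"
            )
        if self.categorical is None:
            object.__setattr__(self, "categorical", dict(preset["categorical"]))
        if self.continuous is None:
            object.__setattr__(self, "continuous", tuple(preset["continuous"]))
        else:
            object.__setattr__(self, "continuous", tuple(self.continuous))
        if self.nonlinear is None:
            object.__setattr__(self, "nonlinear", tuple(preset["nonlinear"]))
        else:
            object.__setattr__(self, "nonlinear", tuple(self.nonlinear))
        for cov in self.nonlinear:
            if cov not in self.binning:
                raise ValueError(f"no binning scheme for nonlinear covariate {cov!r}")

    @property
    def complexity(self) -> int:
        return COMPLEXITY[self.structure]

    @property
    def has_besag(self) -> bool:
        return self.structure in ("Besag", "IID_Besag")

    @property
    def has_iid(self) -> bool:
        return self.structure in ("IID", "IID_Besag")

    def with_structure(self, structure: str) -> "ModelSpec":
        return replace(self, structure=structure)


def enumerate_model_specs(**overrides) -> list[ModelSpec]:
    """The full 4-structure x 3-covariate-set grid (12 configurations)."""
    return [
        ModelSpec(structure=s, covariate_set=c, **overrides)
        for c in ("individual", "community", "both")
        for s in STRUCTURES
    ]


@dataclass
class DesignData:
    """Numeric design for one model fit.

    ``x`` excludes the intercept (handled by the sampler) and excludes
    reference-level columns; ``bin_index`` maps each nonlinear covariate
    to a per-row bin index into its scheme.
    """

    y: np.ndarray
    x: np.ndarray
    x_names: list
    bin_index: dict
    bin_schemes: dict
    state_index: np.ndarray
    states: tuple
    graph: AdjacencyGraph | None
    weights: np.ndarray
    cluster_id: np.ndarray
    n_dropped: int
    categorical_levels: dict      # covariate -> (reference, ordered non-ref levels)
    spec: ModelSpec

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_states(self) -> int:
        return len(self.states)

    def decode_categoricals(self) -> pd.DataFrame:
        """Invert the dummy coding back to category labels (round-trip)."""
        out = {}
        for cov, (ref, levels) in self.categorical_levels.items():
            lab = np.full(self.n_obs, ref, dtype=object)
            for lev in levels:
                col = self.x[:, self.x_names.index(f"{cov}={lev}")]
                lab[col == 1.0] = lev
            out[cov] = lab
        return pd.DataFrame(out)


def _merge_community(microdata, profiles, woman_covariates):
    md = microdata.merge(
        profiles[["cluster_id", "efi", "main_religion", "main_wealth"]],
        on="cluster_id", how="left", validate="many_to_one",
    )
    if woman_covariates is not None:
        md = md.merge(woman_covariates, on="woman_id", how="left",
                      validate="one_to_one", suffixes=("", "_w"))
    else:
        md = md.merge(profiles[["cluster_id", "pct_cut", "pct_support"]],
                      on="cluster_id", how="left", validate="many_to_one")
    return md


def build_design(
    microdata: pd.DataFrame,
    spec: ModelSpec,
    profiles: pd.DataFrame | None = None,
    woman_covariates: pd.DataFrame | None = None,
    graph: AdjacencyGraph | None = None,
) -> DesignData:
    """Assemble the numeric design for one model configuration.

    Parameters
    ----------
    microdata : woman-level table (see the microdata CSV schema).
    spec : the model configuration.
    profiles : per-cluster community profiles; required when the spec
        uses community covariates.
    woman_covariates : optional per-woman pct_cut / pct_support values
        (leave-one-out); falls back to the cluster-level values.
    graph : state adjacency; required for Besag structures.  When given,
        its node set fixes the state order; microdata states must be a
        subset.
    """
    needs_community = bool(
        set(spec.categorical) & set(_COMMUNITY_CATEGORICAL)
        or "efi" in spec.continuous
        or set(spec.nonlinear) & {"pct_cut", "pct_support"}
    )
    if needs_community and profiles is None:
        raise ValueError("this covariate set requires community profiles")
    md = (_merge_community(microdata, profiles, woman_covariates)
          if needs_community else microdata.copy())

    n_dropped = int(md["fgm_status"].isna().sum())
    md = md[md["fgm_status"].notna()].reset_index(drop=True)

    if spec.has_besag and graph is None:
        raise ValueError("Besag structures require an adjacency graph")
    if graph is not None:
        states = tuple(graph.nodes)
        unknown = set(md["state_id"]) - set(states)
        if unknown:
            raise ValueError(f"state(s) {sorted(map(str, unknown))} not in adjacency graph")
    else:
        states = tuple(sorted(md["state_id"].unique(), key=str))
    state_pos = {s: i for i, s in enumerate(states)}
    state_index = md["state_id"].map(state_pos).to_numpy(dtype=int)

    # dummy coding with explicit reference levels
    columns, names = [], []
    categorical_levels = {}
    for cov, ref in spec.categorical.items():
        vals = md[cov].astype(str)
        counts = vals.value_counts()
        present = sorted(counts.index)
        if ref is None:
            top = counts[counts == counts.max()]
            ref = sorted(top.index)[0]
        elif ref not in present:
            raise ValueError(f"reference level {ref!r} absent from covariate {cov!r}")
        levels = [lev for lev in present if lev != ref]
        categorical_levels[cov] = (ref, tuple(levels))
        for lev in levels:
            columns.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{cov}={lev}")
    for cov in spec.continuous:
        columns.append(md[cov].to_numpy(dtype=float))
        names.append(cov)
    if spec.include_weight_covariate:
        columns.append(md["weight"].to_numpy(dtype=float))
        names.append("weight")

    x = (np.column_stack(columns) if columns
         else np.empty((len(md), 0)))
    if np.isnan(x).any():
        bad = [names[j] for j in np.flatnonzero(np.isnan(x).any(axis=0))]
        raise ValueError(f"missing values in design columns {bad}")

    bin_index = {
        cov: discretise(md[cov].to_numpy(dtype=float), spec.binning[cov])
        for cov in spec.nonlinear
    }
    return DesignData(
        y=md["fgm_status"].to_numpy(dtype=float),
        x=x,
        x_names=names,
        bin_index=bin_index,
        bin_schemes={cov: spec.binning[cov] for cov in spec.nonlinear},
        state_index=state_index,
        states=states,
        graph=graph,
        weights=md["weight"].to_numpy(dtype=float),
        cluster_id=md["cluster_id"].to_numpy(),
        n_dropped=n_dropped,
        categorical_levels=categorical_levels,
        spec=spec,
    )
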