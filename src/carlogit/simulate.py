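"""Synthetic two-stage cluster survey generator with known ground truth.

Emulates the essential structure of a DHS/MICS-style women's survey:
clusters (primary sampling units) nested in states, women nested in
clusters, categorical individual covariates, a spatially structured
(iCAR) plus an independent state effect, and Bernoulli outcomes from the
logistic model the package fits.  Because every parameter of the
generative model is recorded, the generator supports exact
parameter-recovery and model-selection experiments.

The generator makes no attempt to match any real country's ethnic or
religious composition or sampling fractions; categories are generic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjacency import AdjacencyGraph, grid_adjacency
from .covariates import DEFAULT_BINS, BinningScheme, discretise

MICRODATA_COLUMNS = [
    "woman_id", "state_id", "cluster_id", "fgm_status", "age_years",
    "residence", "education", "wealth_quintile", "marital_status",
    "ethnicity", "religion", "support_continuation", "weight",
]

# Default covariate distributions: plausible for a West-African women's
# survey without mirroring any real one.
DEFAULT_FREQUENCIES = {
    "residence": {"rural": 0.60, "urban": 0.40},
    "education": {"none": 0.35, "primary": 0.20, "secondary": 0.30, "higher": 0.15},
    "wealth_quintile": {
        "poorest": 0.20, "poorer": 0.20, "middle": 0.20, "richer": 0.20,
        "richest": 0.20,
    },
    "marital_status": {"married": 0.70, "formerly": 0.10, "never": 0.20},
    "religion": {"christian": 0.50, "islam": 0.45, "traditional": 0.05},
    "support_continuation": {"no": 0.75, "yes": 0.25},
}

DEFAULT_ETHNIC_GROUPS = tuple(f"group_{c}" for c in "abcdef")

# Modest default effect sizes on the log-odds scale.
DEFAULT_FIXED_EFFECTS = {
    "residence": {"urban": 0.30},
    "education": {"primary": 0.10, "secondary": -0.30, "higher": -0.60},
    "wealth_quintile": {"richer": -0.15, "richest": -0.25},
    "marital_status": {"formerly": 0.30, "never": -0.40},
    "religion": {"islam": 0.10, "traditional": 0.20},
    "support_continuation": {"yes": 1.00},
}

# Age effect per 5-year bin (centred): risk rises with age.
DEFAULT_SMOOTH_EFFECTS = {
    "age_years": (-0.60, -0.35, -0.15, 0.00, 0.20, 0.40, 0.50),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic survey draw.

    The topology defaults to a 6x6 rook grid of 36 states, the scale of
    a Nigeria-like federation, with 10 clusters per state and 30 women
    per cluster.
    """

    n_rows: int = 6
    n_cols: int = 6
    graph: AdjacencyGraph | None = None
    clusters_per_state: int = 10
    women_per_cluster: int = 30
    true_intercept: float = -1.5
    true_fixed_effects: dict = field(default_factory=lambda: dict(DEFAULT_FIXED_EFFECTS))
    true_smooth_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_SMOOTH_EFFECTS)
    )
    tau_s: float = 4.0
    tau_u: float = 4.0
    spatial_structure: str = "IID_Besag"  # which effects enter the truth
    covariate_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCIES)
    )
    ethnic_groups: tuple = DEFAULT_ETHNIC_GROUPS
    ethnicity_concentration: float = 0.25
    weight_sigma: float = 0.4
    binning: dict = field(default_factory=lambda: dict(DEFAULT_BINS))
    seed: int = 0

    def __post_init__(self):
        for cov, freqs in self.covariate_frequencies.items():
            p = np.array(list(freqs.values()), dtype=float)
            if (p < 0).any() or (p > 1).any() or abs(p.sum() - 1) > 1e-9:
                raise ValueError(f"frequencies for {cov!r} must be a distribution")
        if self.tau_s <= 0 or self.tau_u <= 0:
            raise ValueError("tau_s and tau_u must be positive")
        if self.spatial_structure not in {"Base", "IID", "Besag", "IID_Besag"}:
            raise ValueError(f"unknown spatial structure {self.spatial_structure!r}")
        g = self.resolve_graph()
        if g.n_nodes * self.clusters_per_state < 2:
            raise ValueError("need at least 2 clusters in total")

    def resolve_graph(self) -> AdjacencyGraph:
        if self.graph is not None:
            return self.graph
        return grid_adjacency(self.n_rows, self.n_cols)


@dataclass(frozen=True)
class GroundTruth:
    """Realised latent state of one simulation, for recovery testing."""

    u: np.ndarray          # structured state effects, sum-to-zero
    v: np.ndarray          # unstructured state effects
    intercept: float
    fixed_effects: dict
    smooth_effects: dict
    tau_s: float
    tau_u: float
    p: np.ndarray          # per-woman true Bernoulli probability
    states: tuple

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state_id": list(self.states), "u_true": self.u, "v_true": self.v}
        )


def sample_icar(graph: AdjacencyGraph, tau_s: float, seed) -> np.ndarray:
    """Draw state effects from the intrinsic CAR (Besag) prior.

    The intrinsic prior is improper (flat along the constant vector);
    the draw is taken in the span of the graph-Laplacian eigenvectors
    with nonzero eigenvalue, i.e. restricted to the sum-to-zero
    subspace, each direction scaled by 1/sqrt(tau_s * eigenvalue).

    ``seed`` may be an int or a numpy Generator.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    graph.require_connected("iCAR sampling")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam, vec = np.linalg.eigh(graph.laplacian())
    if (lam < 1e-9).sum() != 1:
        raise ValueError("Laplacian rank deficiency exceeds 1 (disconnected graph)")
    lam, vec = lam[1:], vec[:, 1:]
    z = rng.standard_normal(lam.size)
    u = vec @ (z / np.sqrt(tau_s * lam))
    return u - u.mean()  # exact sum-to-zero despite floating error


def _draw_categorical(rng, freqs: dict, n: int) -> np.ndarray:
    levels = np.array(list(freqs), dtype=object)
    p = np.array(list(freqs.values()), dtype=float)
    return levels[rng.choice(len(levels), size=n, p=p)]


def simulate_survey(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one synthetic survey: microdata table plus ground truth.

    The linear predictor for woman i is
    ``b0 + z_i' b + f_age(age_i) + u[state_i] + v[state_i]``
    with u and/or v zeroed out according to ``spatial_structure``;
    y_i ~ Bernoulli(inverse-logit(eta_i)).  Output is a pure function of
    the config (identical seed, identical table).
    """
    graph = config.resolve_graph()
    rng = np.random.default_rng(config.seed)
    n_states = graph.n_nodes
    n_clusters = n_states * config.clusters_per_state
    n = n_clusters * config.women_per_cluster

    # state / cluster structure
    state_idx = np.repeat(np.arange(n_states),
                          config.clusters_per_state * config.women_per_cluster)
    cluster_idx = np.repeat(np.arange(n_clusters), config.women_per_cluster)

    # latent state effects
    use_u = config.spatial_structure in {"Besag", "IID_Besag"}
    use_v = config.spatial_structure in {"IID", "IID_Besag"}
    u = sample_icar(graph, config.tau_s, rng) if use_u else np.zeros(n_states)
    v = (rng.standard_normal(n_states) / np.sqrt(config.tau_u)
         if use_v else np.zeros(n_states))

    # individual covariates
    cols = {}
    eta = np.full(n, config.true_intercept)
    for cov, freqs in config.covariate_frequencies.items():
        draw = _draw_categorical(rng, freqs, n)
        cols[cov] = draw
        for level, coef in config.true_fixed_effects.get(cov, {}).items():
            eta += coef * (draw == level)

    # per-cluster ethnicity mixtures so the EFI has support across clusters
    alpha = np.full(len(config.ethnic_groups), config.ethnicity_concentration)
    theta = rng.dirichlet(alpha, size=n_clusters)
    eth_levels = np.array(config.ethnic_groups, dtype=object)
    eth = np.empty(n, dtype=object)
    for c in range(n_clusters):
        rows = slice(c * config.women_per_cluster, (c + 1) * config.women_per_cluster)
        eth[rows] = eth_levels[rng.choice(len(eth_levels),
                                          size=config.women_per_cluster, p=theta[c])]
    cols["ethnicity"] = eth

    # age and its smooth (binned) effect
    age = rng.integers(15, 50, size=n)
    cols["age_years"] = age
    for cov, effects in config.true_smooth_effects.items():
        scheme: BinningScheme = config.binning[cov]
        effects = np.asarray(effects, dtype=float)
        if effects.size != scheme.n_bins:
            raise ValueError(f"smooth effects for {cov!r} must have one value per bin")
        eta += effects[discretise(cols[cov], scheme)]

    eta += u[state_idx] + v[state_idx]
    p = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, p)

    # positive sampling weights, log-normal with mean 1
    sig = config.weight_sigma
    weight = rng.lognormal(mean=-0.5 * sig * sig, sigma=sig, size=n)

    microdata = pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "state_id": np.asarray(graph.nodes, dtype=object)[state_idx],
            "cluster_id": cluster_idx,
            "fgm_status": y,
            "age_years": age,
            "residence": cols["residence"],
            "education": cols["education"],
            "wealth_quintile": cols["wealth_quintile"],
            "marital_status": cols["marital_status"],
            "ethnicity": cols["ethnicity"],
            "religion": cols["religion"],
            "support_continuation": cols["support_continuation"],
            "weight": weight,
        }
    )
    truth = GroundTruth(
        u=u, v=v,
        intercept=config.true_intercept,
        fixed_effects=config.true_fixed_effects,
        smooth_effects=config.true_smooth_effects,
        tau_s=config.tau_s, tau_u=config.tau_u,
        p=p, states=tuple(graph.nodes),
    )
    return microdata, truth
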