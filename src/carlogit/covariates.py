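"""Community-level covariate construction.

The community is the survey sampling cluster.  From woman-level
microdata this module derives, per cluster: the ethnic fractionalisation
index (EFI), the percentage of women cut, the percentage supporting
continuation of the practice, and the modal religion and wealth
quintile.  It also provides the binning used by the nonlinear (smooth)
terms of the regression model.

EFI = 1 - sum_k s_k^2, with s_k the within-cluster proportion of ethnic
group k: 0 in a mono-ethnic cluster, approaching 1 - 1/n for n equally
sized groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def efi(group_proportions) -> float:
    """Ethnic fractionalisation index of a community.

    Parameters
    ----------
    group_proportions : sequence of float
        Proportions of each ethnic group; nonnegative, summing to 1.
        A single group (mono-ethnic community) gives 0.

    Returns
    -------
    float in [0, 1 - 1/n_groups].
    """
    s = np.asarray(group_proportions, dtype=float)
    if (s < 0).any():
        raise ValueError("group proportions must be nonnegative")
    total = s.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"group proportions sum to {total}, expected 1")
    return float(1.0 - (s ** 2).sum())


@dataclass(frozen=True)
class BinningScheme:
    """Ordered bin edges and labels for one nonlinear covariate.

    Bins are right-open [e_k, e_{k+1}) except the last, which is closed
    so the covariate's maximum maps to the top bin.
    """

    edges: tuple
    labels: tuple

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or not (np.diff(e) > 0).all():
            raise ValueError("bin edges must be strictly increasing, >= 2 edges")
        if len(self.labels) != len(e) - 1:
            raise ValueError("need one label per bin")

    @property
    def n_bins(self) -> int:
        return len(self.labels)

    @classmethod
    def equal_width(cls, low, high, n_bins, fmt="{lo:g}-{hi:g}"):
        edges = np.linspace(low, high, n_bins + 1)
        labels = tuple(fmt.format(lo=lo, hi=hi) for lo, hi in zip(edges[:-1], edges[1:]))
        return cls(edges=tuple(edges), labels=labels)


def discretise(values, scheme: BinningScheme) -> np.ndarray:
    """Map each value to its bin index under ``scheme``.

    Out-of-range values raise, naming the first offender.
    """
    v = np.asarray(values, dtype=float)
    edges = np.asarray(scheme.edges)
    bad = (v < edges[0]) | (v > edges[-1])
    if bad.any():
        raise ValueError(
            f"value {v[bad][0]!r} outside binning range [{edges[0]}, {edges[-1]}]"
        )
    idx = np.digitize(v, edges, right=False) - 1
    # top edge belongs to the last (closed) bin
    idx[v == edges[-1]] = scheme.n_bins - 1
    return idx


# default schemes: 5-year age groups over the 15-49 survey age range,
# decile bins for the community percentages
DEFAULT_BINS = {
    "age_years": BinningScheme(
        edges=(15, 20, 25, 30, 35, 40, 45, 50),
        labels=("15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49"),
    ),
    "pct_cut": BinningScheme.equal_width(0, 100, 10),
    "pct_support": BinningScheme.equal_width(0, 100, 10),
}


def _mode_lexicographic(series: pd.Series):
    # most frequent level; ties broken by lexicographic label order
    counts = series.value_counts()
    top = counts[counts == counts.max()]
    return sorted(top.index.astype(str))[0]


def community_profiles(
    microdata: pd.DataFrame, leave_one_out: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster community profiles and per-woman community covariates.

    Parameters
    ----------
    microdata : DataFrame
        Woman-level table with at least cluster_id, fgm_status,
        ethnicity, religion, wealth_quintile, support_continuation.
    leave_one_out : bool
        When True (default) a woman's own outcome and support response
        are excluded from the pct_cut / pct_support values attached to
        her row, so her outcome never appears in its own predictor.
        Requires every cluster to have >= 2 women.

    Returns
    -------
    (profiles, woman_covariates)
        ``profiles``: one row per cluster (cluster_id, efi, pct_cut,
        pct_support, main_religion, main_wealth, n_women) — always the
        all-women aggregates.
        ``woman_covariates``: one row per woman (woman_id, pct_cut,
        pct_support), leave-one-out when requested.
    """
    md = microdata
    if md["cluster_id"].isna().any():
        raise ValueError("every woman must have a cluster_id")
    grouped = md.groupby("cluster_id", sort=True)

    sizes = grouped.size()
    if leave_one_out and (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(
            f"leave-one-out requires >= 2 women per cluster; singleton cluster(s) {bad}"
        )

    rows = []
    for cid, grp in grouped:
        props = grp["ethnicity"].value_counts(normalize=True).to_numpy()
        support = (grp["support_continuation"].astype(str) == "yes").mean()
        rows.append(
            {
                "cluster_id": cid,
                "efi": efi(props),
                "pct_cut": 100.0 * grp["fgm_status"].mean(),
                "pct_support": 100.0 * support,
                "main_religion": _mode_lexicographic(grp["religion"]),
                "main_wealth": _mode_lexicographic(grp["wealth_quintile"]),
                "n_women": len(grp),
            }
        )
    profiles = pd.DataFrame(rows)

    # per-woman values, optionally excluding the index woman
    n_c = grouped["fgm_status"].transform("size").to_numpy()
    cut_sum = grouped["fgm_status"].transform("sum").to_numpy()
    sup = (md["support_continuation"].astype(str) == "yes").astype(float)
    sup_sum = sup.groupby(md["cluster_id"]).transform("sum").to_numpy()
    if leave_one_out:
        pct_cut = 100.0 * (cut_sum - md["fgm_status"].to_numpy()) / (n_c - 1)
        pct_support = 100.0 * (sup_sum - sup.to_numpy()) / (n_c - 1)
    else:
        pct_cut = 100.0 * cut_sum / n_c
        pct_support = 100.0 * sup_sum / n_c
    woman_cov = pd.DataFrame(
        {
            "woman_id": md["woman_id"].to_numpy(),
            "pct_cut": pct_cut,
            "pct_support": pct_support,
        }
    )
    return profiles, woman_cov
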