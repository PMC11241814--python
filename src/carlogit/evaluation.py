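"""Model comparison and reporting.

DIC with the parsimony rule (differences under 2 are ties, resolved in
favour of the simpler structure), posterior odds ratios with a
same-side-of-1 significance flag, state-level posterior predicted
prevalence with uncertainty, and R-squared / RMSE / MAE of predicted
against observed state prevalence.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .design import COMPLEXITY, DesignData
from .sampler import PosteriorFit, deviance


class DICResult(NamedTuple):
    dic: float
    p_d: float
    mean_deviance: float


def dic(per_draw_deviance, deviance_at_posterior_mean: float) -> DICResult:
    """Deviance information criterion.

    p_D = mean(D) - D(theta-bar) with the plug-in deviance evaluated at
    the posterior mean of the per-observation linear predictor;
    DIC = mean(D) + p_D.  A negative p_D is possible for strongly
    non-normal posteriors and is returned as-is (callers may flag it).
    """
    d = np.asarray(per_draw_deviance, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 deviance draws")
    if not np.isfinite(d).all() or not np.isfinite(deviance_at_posterior_mean):
        raise ValueError("non-finite deviance values")
    mean_d = float(d.mean())
    p_d = mean_d - float(deviance_at_posterior_mean)
    return DICResult(dic=mean_d + p_d, p_d=p_d, mean_deviance=mean_d)


def dic_of_fit(fit: PosteriorFit, design: DesignData) -> DICResult:
    """DIC of a fitted model, plug-in at the posterior-mean predictor."""
    d_bar = deviance(design.y, fit.draws["eta_mean"])
    return dic(fit.draws["deviance"], d_bar)


def select_structure(dic_by_structure: dict, complexity: dict = COMPLEXITY) -> str:
    """Pick the structure by DIC with the parsimony tie-break.

    Among structures whose DIC is within 2 of the minimum (differences
    below 2 are not meaningful), return the one with the lowest
    complexity rank.
    """
    vals = {k: float(v) for k, v in dic_by_structure.items()}
    if not all(np.isfinite(v) for v in vals.values()):
        raise ValueError("all DIC values must be finite")
    best = min(vals.values())
    candidates = [k for k, v in vals.items() if v < best + 2.0]
    return min(candidates, key=lambda k: complexity[k])


def comparison_table(dic_by_structure: dict,
                     complexity: dict = COMPLEXITY) -> pd.DataFrame:
    """DIC comparison across structures with the selected row flagged."""
    selected = select_structure(dic_by_structure, complexity)
    rows = [
        {"structure": k, "dic": float(v), "complexity": complexity[k],
         "selected": k == selected}
        for k, v in dic_by_structure.items()
    ]
    return pd.DataFrame(rows).sort_values("complexity").reset_index(drop=True)


def posterior_odds_ratios(fit: PosteriorFit) -> pd.DataFrame:
    """Exponentiated fixed effects with 95% credible intervals.

    POR is exp(posterior mean of the coefficient); the interval is the
    exponentiated 2.5%/97.5% posterior quantiles.  An effect is flagged
    significant when both interval endpoints lie on the same side of 1.
    Reference levels of categorical covariates are included as POR 1
    rows without an interval.
    """
    beta = fit.draws["beta"]
    por = {}
    for j, name in enumerate(fit.x_names):
        b = beta[:, j]
        lo, hi = np.quantile(b, [0.025, 0.975])
        por[name] = (float(np.exp(b.mean())), float(np.exp(lo)), float(np.exp(hi)))

    rows = []
    consumed = set()
    for cov, (ref, levels) in fit.categorical_levels.items():
        rows.append({"covariate": cov, "level": f"{ref} (ref)", "por": 1.0,
                     "ci_2.5": np.nan, "ci_97.5": np.nan, "significant": False})
        for lev in levels:
            name = f"{cov}={lev}"
            p, lo, hi = por[name]
            consumed.add(name)
            rows.append({"covariate": cov, "level": lev, "por": p,
                         "ci_2.5": lo, "ci_97.5": hi,
                         "significant": bool((lo > 1 and hi > 1) or (lo < 1 and hi < 1))})
    for name in fit.x_names:
        if name in consumed:
            continue
        p, lo, hi = por[name]
        rows.append({"covariate": name, "level": "", "por": p,
                     "ci_2.5": lo, "ci_97.5": hi,
                     "significant": bool((lo > 1 and hi > 1) or (lo < 1 and hi < 1))})
    return pd.DataFrame(rows)


def state_prevalence(fit: PosteriorFit, design: DesignData,
                     weighted: bool = True) -> tuple[pd.DataFrame, dict]:
    """Observed and posterior predicted prevalence per state, in percent.

    Per posterior draw, the predicted state prevalence is the (survey-
    weighted by default) mean of the fitted probabilities p_i over the
    state's women; the table reports the posterior mean, SD and
    2.5%/97.5% quantiles across draws next to the observed (weighted)
    prevalence.  States with no sampled women are excluded and listed in
    the summary.  The national summary aggregates over all women.
    """
    key = "prev_state_w" if weighted else "prev_state_u"
    prev = fit.draws[key] * 100.0
    S = len(fit.states)
    sidx = design.state_index
    w = design.weights if weighted else np.ones_like(design.weights)
    wsum = np.bincount(sidx, weights=w, minlength=S)
    ysum = np.bincount(sidx, weights=w * design.y, minlength=S)
    sampled = wsum > 0
    with np.errstate(invalid="ignore"):
        observed = np.where(sampled, ysum / np.where(sampled, wsum, 1.0), np.nan) * 100

    q = np.nanquantile(prev, [0.025, 0.975], axis=0)
    table = pd.DataFrame(
        {
            "state_id": list(fit.states),
            "observed_pct": observed,
            "predicted_pct": np.nanmean(prev, axis=0),
            "predicted_sd": np.nanstd(prev, axis=0),
            "q2.5_pct": q[0],
            "q97.5_pct": q[1],
        }
    )
    excluded = [fit.states[i] for i in np.flatnonzero(~sampled)]
    table = table[sampled].reset_index(drop=True)

    nat_key = "prev_nat_w" if weighted else "prev_nat_u"
    nat = fit.draws[nat_key] * 100.0
    national = {
        "observed_pct": float((w @ design.y) / w.sum() * 100.0),
        "predicted_pct": float(nat.mean()),
        "predicted_sd": float(nat.std()),
        "weighted": weighted,
        "excluded_states": excluded,
    }
    return table, national


class FitMetrics(NamedTuple):
    r2: float
    rmse: float
    mae: float


def fit_metrics(observed_by_state, predicted_by_state,
                r2_method: str = "pearson") -> FitMetrics:
    """R-squared, RMSE and MAE of predicted vs observed state prevalence.

    R-squared is the squared Pearson correlation by default
    (``r2_method='ss'`` gives the sum-of-squares definition instead);
    RMSE and MAE are in the units of the inputs (percentage points when
    prevalences are given in percent).  Zero variance in either vector
    makes the correlation R-squared undefined (returned as NaN).
    """
    obs = np.asarray(observed_by_state, dtype=float)
    pred = np.asarray(predicted_by_state, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("need equal-length vectors of >= 2 states")
    err = pred - obs
    rmse = float(np.sqrt((err ** 2).mean()))
    mae = float(np.abs(err).mean())
    if r2_method == "pearson":
        if obs.std() == 0 or pred.std() == 0:
            r2 = float("nan")
        else:
            r2 = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    elif r2_method == "ss":
        sst = ((obs - obs.mean()) ** 2).sum()
        r2 = float("nan") if sst == 0 else float(1.0 - (err ** 2).sum() / sst)
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return FitMetrics(r2=r2, rmse=rmse, mae=mae)


def prevalence_difference(table_a: pd.DataFrame, table_b: pd.DataFrame,
                          column: str = "predicted_pct") -> pd.DataFrame:
    """Per-state change B - A in percentage points.

    Positive values mean the prevalence in ``table_b`` (the later
    period) exceeds that in ``table_a``.  The two tables must cover the
    same states.
    """
    sa, sb = set(table_a["state_id"]), set(table_b["state_id"])
    if sa != sb:
        raise ValueError(
            f"state sets differ; symmetric difference: {sorted(map(str, sa ^ sb))}")
    a = table_a.set_index("state_id")[column]
    b = table_b.set_index("state_id")[column]
    diff = (b - a).reindex(sorted(sa, key=str))
    return pd.DataFrame({"state_id": diff.index, "difference_pct": diff.to_numpy()})
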