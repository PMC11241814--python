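"""Quick-look plots (observed vs predicted state prevalence scatter)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402


def observed_vs_predicted(state_table, ax=None):
    """Scatter of predicted vs observed state prevalence with a 1:1 line."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    obs = state_table["observed_pct"]
    pred = state_table["predicted_pct"]
    ax.scatter(obs, pred, s=25, alpha=0.8, edgecolor="k", linewidth=0.4)
    lim = (0, max(float(obs.max()), float(pred.max())) * 1.05 + 1)
    ax.plot(lim, lim, color="grey", linestyle="--", linewidth=1, label="1:1")
    ax.set_xlim(lim)
    ax.set_ylim(lim)
    ax.set_xlabel("observed prevalence (%)")
    ax.set_ylabel("posterior predicted prevalence (%)")
    ax.legend(frameon=False)
    return ax


def smooth_effect(effect_table, covariate, ax=None):
    """Posterior mean and 95% band of one binned nonlinear effect."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = range(len(effect_table))
    ax.fill_between(x, effect_table["q2.5"], effect_table["q97.5"],
                    alpha=0.25, label="95% CrI")
    ax.plot(x, effect_table["mean"], marker="o", label="posterior mean")
    ax.axhline(0, color="grey", linewidth=0.8)
    ax.set_xticks(list(x), effect_table["bin"], rotation=45)
    ax.set_xlabel(covariate)
    ax.set_ylabel("effect (log-odds)")
    ax.legend(frameon=False)
    return ax
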