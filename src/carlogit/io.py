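"""File formats, run configuration, provenance, and the end-to-end pipeline.

All tabular formats are plain CSV with headers.  The microdata schema
is the package's documented interchange format for woman-level survey
records; unknown extra columns are preserved on read but ignored by the
model.  Every pipeline run writes a provenance record (config hash,
seed, package version) sufficient to reproduce its outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjacency import read_edge_list, write_edge_list
from .covariates import community_profiles
from .design import ModelSpec
from .model import SpatialLogit, compare_structures
from .sampler import SamplerConfig
from .simulate import MICRODATA_COLUMNS, SimulationConfig, simulate_survey

_FLOAT_FMT = "%.10g"

REQUIRED_COLUMNS = list(MICRODATA_COLUMNS)


def write_microdata(microdata: pd.DataFrame, path):
    microdata.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_microdata(path) -> pd.DataFrame:
    """Read and validate a microdata CSV.

    Raises on missing required columns; reports malformed rows (bad
    outcome codes, non-positive weights, out-of-range ages) with their
    line numbers.
    """
    md = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    bad = []
    status_ok = md["fgm_status"].isin([0, 1]) | md["fgm_status"].isna()
    weight_ok = md["weight"] > 0
    for mask, reason in [(~status_ok, "fgm_status not in {0,1}"),
                         (~weight_ok, "non-positive weight")]:
        for i in np.flatnonzero(mask.to_numpy())[:5]:
            bad.append(f"line {i + 2}: {reason}")  # +2: header + 1-based
    if bad:
        raise ValueError("malformed microdata rows:\n" + "\n".join(bad))
    if md["woman_id"].duplicated().any():
        raise ValueError("duplicate woman_id values")
    return md


@dataclass
class RunConfig:
    """One end-to-end analysis run, fully serialisable for provenance."""

    seed: int = 0
    # simulation (used when no microdata path is given)
    n_rows: int = 6
    n_cols: int = 6
    clusters_per_state: int = 10
    women_per_cluster: int = 30
    # model
    covariate_set: str = "both"
    structures: tuple = ("Base", "IID", "Besag", "IID_Besag")
    leave_one_out: bool = True
    include_weight_covariate: bool = True
    weighted_aggregation: bool = True
    # sampler
    n_iterations: int = 3000
    n_burnin: int = 1000
    thinning: int = 1
    n_chains: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "structures" in raw:
            raw["structures"] = tuple(raw["structures"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["structures"] = list(d["structures"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            n_iterations=self.n_iterations, n_burnin=self.n_burnin,
            thinning=self.thinning, n_chains=self.n_chains, seed=self.seed)


def run_pipeline(config: RunConfig, out_dir, microdata=None, graph=None) -> dict:
    """simulate -> profiles -> fit all structures -> compare -> report.

    When ``microdata`` is None a synthetic survey is generated from the
    config.  Writes all outputs (CSV tables, run report, provenance
    record) under ``out_dir`` and returns them in memory.  Outputs are a
    pure function of the config and inputs: a repeated run is
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if microdata is None:
        sim = SimulationConfig(
            n_rows=config.n_rows, n_cols=config.n_cols,
            clusters_per_state=config.clusters_per_state,
            women_per_cluster=config.women_per_cluster,
            seed=config.seed,
        )
        graph = sim.resolve_graph()
        microdata, truth = simulate_survey(sim)
        write_microdata(microdata, out / "microdata.csv")
        truth.as_frame().to_csv(out / "ground_truth_states.csv", index=False,
                                float_format=_FLOAT_FMT)
        write_edge_list(graph, out / "adjacency.txt")
    elif graph is None:
        raise ValueError("an adjacency graph is required with external microdata")

    profiles, woman_cov = community_profiles(
        microdata, leave_one_out=config.leave_one_out)
    profiles.to_csv(out / "community_profiles.csv", index=False,
                    float_format=_FLOAT_FMT)

    spec = ModelSpec(covariate_set=config.covariate_set,
                     include_weight_covariate=config.include_weight_covariate)
    table, fits = compare_structures(
        microdata, spec, graph=graph,
        sampler_config=config.sampler_config(),
        structures=config.structures,
        leave_one_out=config.leave_one_out)
    table.to_csv(out / "dic_comparison.csv", index=False, float_format=_FLOAT_FMT)

    selected = table.loc[table["selected"], "structure"].iloc[0]
    best = fits[selected]
    por = best.posterior_odds_ratios()
    por.to_csv(out / "posterior_odds_ratios.csv", index=False,
               float_format=_FLOAT_FMT)
    prev, national = best.state_prevalence(weighted=config.weighted_aggregation)
    prev.to_csv(out / "state_prevalence.csv", index=False, float_format=_FLOAT_FMT)
    metrics = best.fit_metrics(weighted=config.weighted_aggregation)
    best.save_draws(out / "draws.csv", out / "draws_metadata.json")

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    report = _run_report(config, table, selected, best, metrics, national)
    (out / "report.txt").write_text(report)
    return {
        "microdata": microdata, "profiles": profiles, "comparison": table,
        "selected": selected, "fits": fits, "por": por,
        "state_prevalence": prev, "national": national, "metrics": metrics,
        "report": report,
    }


def _run_report(config, table, selected, best, metrics, national) -> str:
    lines = [
        "carlogit run report",
        "===================",
        f"config hash: {config.config_hash()}   seed: {config.seed}   "
        f"version: {__version__}",
        "",
        "DIC comparison (parsimony rule: differences < 2 are ties,",
        "resolved in favour of the simpler structure):",
    ]
    for _, r in table.iterrows():
        mark = " <- selected" if r["selected"] else ""
        lines.append(f"  {r['structure']:<10} DIC {r['dic']:10.1f} "
                     f"(complexity {r['complexity']}){mark}")
    lines += [
        "",
        f"selected structure: {selected}",
        f"national prevalence: observed {national['observed_pct']:.1f}%  "
        f"predicted {national['predicted_pct']:.1f}% "
        f"(SD {national['predicted_sd']:.1f})"
        f" [{'weighted' if national['weighted'] else 'unweighted'}]",
        f"state-level fit: R2 {metrics.r2:.3f}  RMSE {metrics.rmse:.1f}  "
        f"MAE {metrics.mae:.1f} (percentage points)",
    ]
    if best.posterior.warnings:
        lines += [""] + [f"WARNING: {w}" for w in best.posterior.warnings]
    return "\n".join(lines) + "\n"
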