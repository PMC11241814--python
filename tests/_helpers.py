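import numpy as np
import pandas as pd


def toy_microdata(n=40, n_clusters=4, seed=0, p=0.4):
    """Minimal schema-complete microdata frame for design/profile tests."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "woman_id": np.arange(n),
        "state_id": rng.integers(0, 2, n),
        "cluster_id": rng.integers(0, n_clusters, n),
        "fgm_status": rng.binomial(1, p, n),
        "age_years": rng.integers(15, 50, n),
        "residence": rng.choice(["rural", "urban"], n),
        "education": rng.choice(["none", "primary", "secondary", "higher"], n),
        "wealth_quintile": rng.choice(
            ["poorest", "poorer", "middle", "richer", "richest"], n),
        "marital_status": rng.choice(["married", "formerly", "never"], n),
        "ethnicity": rng.choice(["group_a", "group_b", "group_c"], n),
        "religion": rng.choice(["christian", "islam"], n),
        "support_continuation": rng.choice(["no", "yes"], n),
        "weight": rng.lognormal(0, 0.3, n),
    })
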