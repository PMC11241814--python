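import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_survey():
    """A small synthetic survey on a 3x3 state grid (session-cached)."""
    from carlogit import SimulationConfig, simulate_survey

    cfg = SimulationConfig(n_rows=3, n_cols=3, clusters_per_state=4,
                           women_per_cluster=20, seed=202)
    md, truth = simulate_survey(cfg)
    return cfg, md, truth
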