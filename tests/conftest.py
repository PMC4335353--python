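import numpy as np
import pytest

from epifootprint import pipeline_cli as pc
from epifootprint import synthetic_data as syn


@pytest.fixture(scope="session")
def default_sim():
    """Default-preset simulation shared across tests (3 clusters x 4 samples,
    2 replicates, effect 2.0, noise 0.25, seed 7)."""
    cfg = syn.SimulationConfig()
    tracks, regions, truth = syn.simulate_epigenomes(cfg)
    return cfg, tracks, regions, truth


@pytest.fixture(scope="session")
def region_mean_cache(default_sim):
    """Per-(sample, replicate, mark, roi) region-mean vectors for the default
    simulation."""
    _, tracks, regions, _ = default_sim
    return pc._region_means(tracks, regions)


@pytest.fixture(scope="session")
def confirm_result(default_sim, region_mean_cache):
    """Full confirmation-score run (50 rounds x 40 combinations) on the
    default simulation."""
    cfg, _, regions, _ = default_sim
    manifest = {s: ["rep1", "rep2"] for s in cfg.sample_ids()}
    return pc.run_confirm(region_mean_cache, regions, manifest, 50, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
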