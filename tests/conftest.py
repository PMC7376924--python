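import numpy as np
import pytest

from panclean import CleanConfig, SimConfig, build_pangenome, simulate_pangenome


@pytest.fixture(scope="session")
def small_sim():
    """A small clean simulated pangenome shared across tests."""
    cfg = SimConfig(n_genomes=8, n_core_genes=40, gain_rate=8.0, loss_rate=0.5, seed=3)
    sim, truth = simulate_pangenome(cfg)
    return cfg, sim, truth


@pytest.fixture(scope="session")
def small_graph(small_sim):
    cfg, sim, truth = small_sim
    g = build_pangenome(
        sim.records(), sim.contig_map(), CleanConfig(mode="moderate"),
        genomes=list(truth.matrix.index),
    )
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
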