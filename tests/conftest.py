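import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from fibergel.macro_model import SimulationConfig, run_compaction
from fibergel.rve_network import NetworkMaterial


@pytest.fixture(scope="session")
def material():
    return NetworkMaterial()


@pytest.fixture(scope="session")
def small_compaction():
    """One small Fixed-case compaction run shared by post-processing tests."""
    cfg = SimulationConfig(
        nx=6, ny=6, nz=1, patch_origins=[(1, 4), (4, 4), (2, 1)], patch_size=1,
        target_fibers=40, n_increments=2, total_shortening=0.10,
        bc_case="fixed", seed=0,
    )
    return run_compaction(cfg)


def random_truss(seed, n_nodes=14, tension=0.05):
    """Small random cross-linked truss with all-around boundary support.

    Nodes in the unit cube; the outermost nodes are boundary, interior nodes
    are connected to several neighbours; reference lengths are set slightly
    short so the assembly is tension-dominated (stable equilibria).
    """
    from fibergel.rve_network import FiberNetwork

    rng = np.random.default_rng(seed)
    pos = rng.uniform(0.05, 0.95, size=(n_nodes, 3))
    center_dist = np.linalg.norm(pos - 0.5, axis=1)
    boundary = center_dist >= np.median(center_dist)
    fibers = set()
    for i in range(n_nodes):
        d = np.linalg.norm(pos - pos[i], axis=1)
        d[i] = np.inf
        for j in np.argsort(d)[:4]:
            fibers.add((min(i, int(j)), max(i, int(j))))
    fibers = np.array(sorted(fibers))
    lengths = np.linalg.norm(pos[fibers[:, 1]] - pos[fibers[:, 0]], axis=1)
    return FiberNetwork(
        node_positions=pos,
        fibers=fibers,
        ref_lengths=lengths * (1.0 - tension),
        boundary=boundary,
        volume=1.0,
        seed=seed,
    )
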