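import numpy as np
import pytest

from branchgrm import SimulationConfig, TreeSequence, simulate_coalescent_ts


@pytest.fixture
def two_sample_ts() -> TreeSequence:
    """Two samples at time 0 coalescing at a root at time 1, span 1."""
    return TreeSequence(
        sequence_length=1.0,
        node_time=[0.0, 0.0, 1.0],
        node_is_sample=[1, 1, 0],
        edge_left=[0.0, 0.0],
        edge_right=[1.0, 1.0],
        edge_parent=[2, 2],
        edge_child=[0, 1],
    )


@pytest.fixture
def caterpillar_ts() -> TreeSequence:
    """Samples a, b, c at time 0; (a, b) coalesce at t=1, +c at t=2."""
    return TreeSequence(
        sequence_length=1.0,
        node_time=[0.0, 0.0, 0.0, 1.0, 2.0],
        node_is_sample=[1, 1, 1, 0, 0],
        edge_left=[0.0] * 4,
        edge_right=[1.0] * 4,
        edge_parent=[3, 3, 4, 4],
        edge_child=[0, 1, 3, 2],
    )


def make_random_ts(seed, n=None, rho=None, n_max=32, **kwargs) -> TreeSequence:
    """A coalescent-with-recombination tree sequence at desk scale."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(4, n_max + 1))
    if rho is None:
        rho = float(rng.uniform(0.5, 4.0))
    cfg = SimulationConfig(
        n_samples=n,
        sequence_length=1.0,
        effective_size=1.0,
        recombination_rate=rho,
        seed=int(rng.integers(2**31)),
        **kwargs,
    )
    return simulate_coalescent_ts(cfg)


@pytest.fixture(scope="session")
def random_ts_batch():
    """A reusable batch of simulated tree sequences for oracle tests."""
    return [make_random_ts(seed) for seed in range(20)]


def brute_force_parent_maps(ts: TreeSequence):
    """Independent per-interval forest reconstruction straight from the
    raw edge table (no sweep): for each breakpoint interval, the parent of
    a node is the parent of the unique edge covering the interval's
    midpoint."""
    bp = ts.breakpoints
    maps = []
    for left, right in zip(bp[:-1], bp[1:]):
        mid = 0.5 * (left + right)
        parent = np.full(ts.num_nodes, -1, dtype=np.int64)
        cover = (ts.edge_left <= mid) & (mid < ts.edge_right)
        parent[ts.edge_child[cover]] = ts.edge_parent[cover]
        maps.append(((float(left), float(right)), parent))
    return maps
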