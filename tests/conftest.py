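import numpy as np
import pytest

from fcpipe.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-region three-group cohort with planted effects, shared read-only."""
    cfg = SimulationConfig(
        n_regions=30,
        group_sizes={"HC": 16, "nonOHE": 10, "OHE": 8},
        delta_z=0.8,
        n_disrupted_edges=6,
        n_pmn_edges=6,
        seed=42,
    )
    return simulate_cohort(cfg)


def dfs_components(pairs, n_nodes):
    """Brute-force depth-first-search component oracle on an edge list.

    Returns a list of frozensets of edges (as (i, j) tuples), one per
    connected component, independent of the union-find implementation
    under test.
    """
    adj = {}
    for i, j in pairs:
        adj.setdefault(int(i), set()).add(int(j))
        adj.setdefault(int(j), set()).add(int(i))
    seen = set()
    comps = []
    for start in adj:
        if start in seen:
            continue
        stack, nodes = [start], set()
        while stack:
            u = stack.pop()
            if u in nodes:
                continue
            nodes.add(u)
            stack.extend(adj[u] - nodes)
        seen |= nodes
        comp_edges = frozenset(
            (min(int(i), int(j)), max(int(i), int(j)))
            for i, j in pairs
            if int(i) in nodes
        )
        comps.append(comp_edges)
    return comps
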