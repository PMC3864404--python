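import numpy as np
import pytest

from clonaltapestry.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition simulated data set shared across tests."""
    return simulate_all(SimulationConfig(random_seed=11))


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random unrooted binary tree with positive branch lengths.

    Built by attaching each new leaf to a uniformly chosen edge; returns
    (labels, path-distance matrix).  Path distances are computed directly on
    the edge graph, independent of any tree-reconstruction code.
    """
    import collections

    labels = [f"L{i}" for i in range(n)]
    edges: dict[frozenset, float] = {}
    for l in labels[:3]:
        edges[frozenset((l, "I0"))] = float(rng.uniform(0.5, 2.0))
    for i, leaf in enumerate(labels[3:], 1):
        e = list(edges)[int(rng.integers(len(edges)))]
        a, b = tuple(e)
        length = edges.pop(e)
        mid = f"I{i}"
        split = float(rng.uniform(0.2, 0.8)) * length
        edges[frozenset((a, mid))] = split
        edges[frozenset((b, mid))] = length - split
        edges[frozenset((leaf, mid))] = float(rng.uniform(0.5, 2.0))

    adj = collections.defaultdict(list)
    for e, length in edges.items():
        a, b = tuple(e)
        adj[a].append((b, length))
        adj[b].append((a, length))
    D = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, length in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + length
                    stack.append(v)
        for j, dst in enumerate(labels):
            D[i, j] = dist[dst]
    np.fill_diagonal(D, 0.0)
    return labels, D
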