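import numpy as np
import pytest

import graynet as gn


@pytest.fixture
def k4():
    return gn.shared_node_modules(1, 4, 0)[0]


@pytest.fixture
def two_k4():
    """Two disjoint 4-cliques (8 nodes, 12 edges)."""
    g, modules = gn.planted_module_graph([4, 4], 1.0, 0.0, seed=0)
    assert g.m == 12
    return g, modules


@pytest.fixture
def shared_clique():
    """Two 4-cliques sharing 2 nodes (6 nodes, 11 edges)."""
    g, modules = gn.shared_node_modules(2, 4, 2)
    return g, modules


def bfs_components(A):
    """Independent breadth-first-search component oracle."""
    n = A.shape[0]
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            u = queue.pop()
            comp.add(u)
            for v in np.flatnonzero(A[u]):
                if not seen[v]:
                    seen[v] = True
                    queue.append(int(v))
        comps.append(comp)
    return comps
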