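import numpy as np
import pytest

from flavoscreen import load_candidates, load_reference_dataset
from flavoscreen.descriptors_2d import Atom, MolecularGraph
from scipy.sparse.csgraph import shortest_path


@pytest.fixture(scope="session")
def reference():
    return load_reference_dataset()


@pytest.fixture(scope="session")
def candidates():
    return load_candidates()


def make_graph(n, edges, weights=None, elements=None, orders=None):
    """Build a MolecularGraph directly from an edge list (test helper).

    ``weights`` feeds both mass and vdW-volume channels so autocorrelation
    oracles can use arbitrary values.
    """
    weights = list(weights) if weights is not None else [1.0] * n
    elements = list(elements) if elements is not None else ["C"] * n
    orders = list(orders) if orders is not None else [1.0] * len(edges)
    degree = [0] * n
    for i, j in edges:
        degree[i] += 1
        degree[j] += 1
    atoms = [
        Atom(
            element=elements[i],
            period=2,
            degree=degree[i],
            delta_v=max(4 - degree[i], 1),
            mass=float(weights[i]),
            vdw_volume=float(weights[i]),
            n_h=max(4 - degree[i], 0),
        )
        for i in range(n)
    ]
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    dist = shortest_path(adj, unweighted=True, directed=False) if n else np.zeros((0, 0))
    bonds = [(i, j, orders[k]) for k, (i, j) in enumerate(edges)]
    return MolecularGraph(atoms=atoms, bonds=bonds, dist=dist)


def random_graph(rng, n_min=3, n_max=12):
    """A random connected simple graph: spanning tree plus extra edges."""
    n = int(rng.integers(n_min, n_max + 1))
    edges = set()
    for i in range(1, n):
        edges.add(tuple(sorted((int(rng.integers(0, i)), i))))
    extra = int(rng.integers(0, n))
    for _ in range(extra):
        i, j = rng.choice(n, size=2, replace=False)
        edges.add(tuple(sorted((int(i), int(j)))))
    weights = rng.uniform(1.0, 30.0, size=n)
    elements = [str(e) for e in rng.choice(["C", "N", "O"], size=n)]
    return make_graph(n, sorted(edges), weights=weights, elements=elements)
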