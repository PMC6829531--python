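"""Independent oracles used by the tests.

These deliberately avoid the library's own code paths: exhaustive
simple-path enumeration instead of the weighted shortest-path search,
and a literal step-up implementation of the Benjamini-Hochberg
procedure instead of the statsmodels call.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np


def serial_key(nodes):
    return tuple((1, n) if isinstance(n, str) else (0, n) for n in nodes)


def brute_force_best_path(g: nx.Graph, source, target):
    """Maximum-product path by exhaustive enumeration of all simple paths.

    Returns (coupling, node list); (0.0, None) when disconnected. Ties
    are broken by fewer steps, then smallest atom-serial sequence, the
    same contract the search is specified to obey.
    """
    best_T, best_nodes = 0.0, None
    for nodes in nx.all_simple_paths(g, source, target):
        T = 1.0
        for u, v in zip(nodes, nodes[1:]):
            T *= g[u][v]["epsilon"]
        if best_nodes is None or T > best_T * (1 + 1e-12):
            best_T, best_nodes = T, nodes
        elif abs(T - best_T) <= 1e-12 * best_T:
            if (len(nodes), serial_key(nodes)) < (len(best_nodes), serial_key(best_nodes)):
                best_nodes = nodes
    return best_T, best_nodes


def brute_force_top_k(g: nx.Graph, source, target, k: int):
    """Top-k maximum-product simple paths by exhaustive enumeration."""
    scored = []
    for nodes in nx.all_simple_paths(g, source, target):
        T = 1.0
        for u, v in zip(nodes, nodes[1:]):
            T *= g[u][v]["epsilon"]
        scored.append((T, nodes))
    scored.sort(key=lambda x: (-x[0], len(x[1]), serial_key(x[1])))
    return scored[:k]


def brute_force_bh(pvals):
    """Benjamini-Hochberg step-up q-values, written out literally."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = math.inf
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


def brute_force_covalent(atoms, radii, tol=0.45, floor=0.4):
    """Literal sweep of the covalent-bond criterion over all atom pairs."""
    pairs = {}
    for i, ai in enumerate(atoms):
        for aj in atoms[i + 1 :]:
            d = math.dist(ai.coords, aj.coords)
            if floor < d <= radii[ai.element] + radii[aj.element] + tol:
                pairs[frozenset((ai.serial, aj.serial))] = d
    return pairs


def random_coupling_graph(rng: np.random.Generator, step_decay, n_nodes=None,
                          edge_prob=0.35):
    """Random connected graph with mixed step kinds for oracle testing."""
    if n_nodes is None:
        n_nodes = int(rng.integers(4, 13))
    while True:
        g = nx.Graph()
        nodes = ["donor", "acceptor"] + list(range(1, n_nodes - 1))
        g.add_nodes_from(nodes)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1 :]:
                if rng.uniform() < edge_prob:
                    kind = rng.choice(["covalent", "hbond", "space"])
                    dist = {
                        "covalent": float(rng.uniform(1.2, 1.8)),
                        "hbond": float(rng.uniform(2.4, 3.5)),
                        "space": float(rng.uniform(1.5, 6.0)),
                    }[kind]
                    eps = step_decay(kind, dist)
                    g.add_edge(u, v, kind=kind, distance=dist, epsilon=eps,
                               weight=-math.log(eps), atoms=(u, v))
        if nx.is_connected(g):
            return g
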