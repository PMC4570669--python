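"""Shared fixtures and independent brute-force oracles.

The oracle implementations here deliberately avoid the package's own
algorithms: distances come from exhaustive simple-path enumeration,
betweenness/closeness from direct counting over enumerated shortest paths,
and modularity maxima from enumeration over all partitions.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from foldbridges.synthetic import SyntheticSpec, generate

REL_TOL = 1e-9


@pytest.fixture(scope="session")
def default_bundle():
    """One deterministic bundle at the reference study conditions."""
    return generate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A small bundle for fast end-to-end style tests."""
    return generate(SyntheticSpec(seed=5, folds_per_class=8))


# ---------------------------------------------------------------------------
# brute-force graph oracles


def brute_all_pairs(G: nx.Graph) -> dict:
    """Distances and shortest-path lists by exhaustive simple-path enumeration."""
    out = {}
    for s in G.nodes:
        for t in G.nodes:
            if s == t:
                out[(s, t)] = (0.0, [[s]])
                continue
            best = math.inf
            paths = []
            for path in nx.all_simple_paths(G, s, t):
                length = sum(
                    1.0 / G[u][v]["weight"] for u, v in zip(path, path[1:])
                )
                if length < best and not math.isclose(length, best, rel_tol=REL_TOL):
                    best = length
                    paths = [path]
                elif math.isclose(length, best, rel_tol=REL_TOL):
                    paths.append(path)
            out[(s, t)] = (best, paths)
    return out


def brute_centralities(G: nx.Graph) -> dict:
    """Degree, closeness and betweenness from the enumerated shortest paths."""
    ap = brute_all_pairs(G)
    degree = {n: sum(d["weight"] for d in G[n].values()) for n in G.nodes}
    closeness = {
        n: sum(
            1.0 / ap[(n, m)][0]
            for m in G.nodes
            if m != n and math.isfinite(ap[(n, m)][0]) and ap[(n, m)][0] > 0
        )
        for n in G.nodes
    }
    betweenness = dict.fromkeys(G.nodes, 0.0)
    for j, k in itertools.combinations(G.nodes, 2):
        dist, paths = ap[(j, k)]
        if not math.isfinite(dist) or not paths:
            continue
        sigma = len(paths)
        for i in G.nodes:
            if i in (j, k):
                continue
            through = sum(1 for p in paths if i in p)
            betweenness[i] += through / sigma
    return {"degree": degree, "closeness": closeness, "betweenness": betweenness}


def exhaustive_best_partition(G: nx.Graph):
    """Maximum-modularity partition by enumeration over all set partitions."""
    nodes = list(G.nodes)
    best_q, best_parts = -math.inf, None
    for labels in _set_partitions(len(nodes)):
        groups: dict[int, set] = {}
        for node, lab in zip(nodes, labels):
            groups.setdefault(lab, set()).add(node)
        q = nx.community.modularity(G, list(groups.values()), weight="weight")
        if q > best_q:
            best_q, best_parts = q, [frozenset(g) for g in groups.values()]
    return best_q, best_parts


def _set_partitions(n: int):
    """Restricted-growth strings enumerating all partitions of n items."""
    labels = [0] * n

    def rec(i: int, maximum: int):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(maximum + 2):
            labels[i] = lab
            yield from rec(i + 1, max(maximum, lab))

    yield from rec(1, 0) if n > 1 else iter([(0,) * n])


def random_weighted_graph(rng: np.random.Generator, n_max: int = 8) -> nx.Graph:
    """Random connected-ish weighted graph with <= n_max nodes."""
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.3, 0.9))
    G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    for u, v in G.edges:
        G[u][v]["weight"] = float(rng.uniform(0.1, 3.0))
    return G
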