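"""Weighted network analysis: paths, centralities, communities, statistics.

Distances follow the reciprocal-weight convention for weighted networks:
the length of a path is the sum of 1/w over its edges, minimised with
Dijkstra's algorithm, so strong bridges (large weights) are short steps.
Centralities are the weighted generalisations of degree, closeness and
betweenness:

    C_D(i) = sum_j w_ij
    C_C(i) = sum_{j != i, same component} 1 / d(i, j)
    C_B(i) = sum_{j, k != i} sigma_jk(i) / sigma_jk

with closeness and betweenness computed within each connected component.
Shortest-path counts for betweenness treat path lengths equal within a
relative tolerance of 1e-9, since lengths are floating-point sums of
reciprocals and exact ties would otherwise be split by rounding noise.

Communities are detected with the Louvain method on edge weights, with
multiple seeded restarts keeping the maximum-modularity partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from heapq import heappop, heappush
from collections.abc import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

REL_TOL = 1e-9
MEASURES = ("degree", "closeness", "betweenness")


def _check_weights(G: nx.Graph) -> None:
    for u, v, d in G.edges(data=True):
        w = d.get("weight")
        if w is None or w <= 0:
            raise ValueError(f"edge ({u}, {v}) has nonpositive or missing weight")


def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=REL_TOL, abs_tol=0.0)


def _dijkstra(G: nx.Graph, source) -> tuple[dict, dict, dict, list]:
    """Single-source Dijkstra under reciprocal-weight lengths.

    Returns distances, shortest-path counts (sigma), predecessor lists and
    the settled order.  Ties in path length within REL_TOL are counted as
    equally short.
    """
    dist: dict = {}
    sigma: dict = {source: 1.0}
    preds: dict = {source: []}
    order: list = []
    seen = {source: 0.0}
    heap = [(0.0, 0, source)]
    tiebreak = 1
    while heap:
        d, _, u = heappop(heap)
        if u in dist:
            continue
        dist[u] = d
        order.append(u)
        for v, edata in G[u].items():
            length = 1.0 / edata["weight"]
            alt = d + length
            if v in dist:
                if _close(alt, dist[v]) and u not in preds[v]:
                    # equal-length path into an already-settled node
                    sigma[v] += sigma[u]
                    preds[v].append(u)
                continue
            if v not in seen or alt < seen[v] and not _close(alt, seen[v]):
                seen[v] = alt
                sigma[v] = sigma[u]
                preds[v] = [u]
                heappush(heap, (alt, tiebreak, v))
                tiebreak += 1
            elif _close(alt, seen[v]):
                sigma[v] += sigma[u]
                preds[v].append(u)
    return dist, sigma, preds, order


def shortest_paths(G: nx.Graph) -> dict:
    """All-pairs distances d(i,j) = min over paths of sum(1/w); inf across components."""
    _check_weights(G)
    out: dict = {}
    for source in G.nodes:
        dist, _, _, _ = _dijkstra(G, source)
        out[source] = {v: dist.get(v, math.inf) for v in G.nodes}
    return out


def centralities(G: nx.Graph) -> pd.DataFrame:
    """Weighted degree, closeness and betweenness per node.

    Returns a frame with columns ``node, component, degree, closeness,
    betweenness``.  Components are numbered; closeness and betweenness only
    aggregate over a node's own component.  Betweenness sums over unordered
    pairs (j, k).
    """
    _check_weights(G)
    comp_of = {}
    for c, comp in enumerate(sorted(nx.connected_components(G), key=lambda s: sorted(s)[0])):
        for node in comp:
            comp_of[node] = c
    degree = {n: float(sum(d["weight"] for d in G[n].values())) for n in G.nodes}
    closeness = dict.fromkeys(G.nodes, 0.0)
    betweenness = dict.fromkeys(G.nodes, 0.0)
    for source in G.nodes:
        dist, sigma, preds, order = _dijkstra(G, source)
        closeness[source] = float(
            sum(1.0 / d for n, d in dist.items() if n != source and d > 0)
        )
        # Brandes' dependency accumulation
        delta = dict.fromkeys(order, 0.0)
        for w in reversed(order):
            for u in preds[w]:
                delta[u] += sigma[u] / sigma[w] * (1.0 + delta[w])
            if w != source:
                betweenness[w] += delta[w]
    for n in betweenness:  # each unordered pair was accumulated from both endpoints
        betweenness[n] /= 2.0
    return pd.DataFrame(
        {
            "node": list(G.nodes),
            "component": [comp_of[n] for n in G.nodes],
            "degree": [degree[n] for n in G.nodes],
            "closeness": [closeness[n] for n in G.nodes],
            "betweenness": [betweenness[n] for n in G.nodes],
        }
    )


# ---------------------------------------------------------------------------
# central / peripheral partition


def _top_by_value(nodes: list, values: np.ndarray, fraction: float, largest: bool) -> set:
    """Top (or bottom) fraction by value, boundary ties included."""
    n = len(nodes)
    if n == 0:
        return set()
    k = max(1, math.ceil(fraction * n))
    order = np.argsort(values, kind="stable")
    if largest:
        order = order[::-1]
    boundary = values[order[k - 1]]
    if largest:
        chosen = values >= boundary
    else:
        chosen = values <= boundary
    return {nodes[i] for i in np.flatnonzero(chosen)}


def partition_central_peripheral(
    G: nx.Graph, cent: pd.DataFrame, fraction: float = 0.3
) -> dict[str, dict[str, set]]:
    """Central and peripheral fold sets per centrality measure.

    Central folds are the top 30% ranked by each measure (boundary ties
    included).  Peripheral folds are: by closeness the bottom 30% of
    connected nodes; by degree the nodes with at most one neighbour; by
    betweenness the connected nodes with zero betweenness.  Degree is ranked
    over all nodes; closeness and betweenness over connected nodes, pooled
    across components.  Central and peripheral sets are kept disjoint by
    removing central members from the peripheral sets.
    """
    nodes_all = cent["node"].tolist()
    connected_mask = cent["node"].map(lambda n: G.degree(n) > 0).to_numpy()
    conn = cent[connected_mask]
    out: dict[str, dict[str, set]] = {}

    central_deg = _top_by_value(nodes_all, cent["degree"].to_numpy(), fraction, largest=True)
    peripheral_deg = {n for n in G.nodes if G.degree(n) <= 1} - central_deg
    out["degree"] = {"central": central_deg, "peripheral": peripheral_deg}

    conn_nodes = conn["node"].tolist()
    central_clo = _top_by_value(conn_nodes, conn["closeness"].to_numpy(), fraction, largest=True)
    peripheral_clo = (
        _top_by_value(conn_nodes, conn["closeness"].to_numpy(), fraction, largest=False)
        - central_clo
    )
    out["closeness"] = {"central": central_clo, "peripheral": peripheral_clo}

    central_bet = _top_by_value(conn_nodes, conn["betweenness"].to_numpy(), fraction, largest=True)
    zero_bet = {r.node for r in conn.itertuples(index=False) if r.betweenness == 0.0}
    out["betweenness"] = {"central": central_bet, "peripheral": zero_bet - central_bet}
    return out


# ---------------------------------------------------------------------------
# communities


@dataclass
class CommunityPartition:
    network_id: str
    labels: dict
    modularity: float
    seed: int
    class_composition: pd.DataFrame

    def as_sets(self) -> list[set]:
        groups: dict[int, set] = {}
        for node, lab in self.labels.items():
            groups.setdefault(lab, set()).add(node)
        return [groups[k] for k in sorted(groups)]


def detect_communities(
    G: nx.Graph, seed: int = 0, restarts: int = 10, network_id: str = ""
) -> CommunityPartition:
    """Louvain communities on edge weights, over connected nodes only.

    Runs ``restarts`` seeded Louvain passes and keeps the partition with the
    highest modularity.  Each community is summarised by its SCOP-class
    composition (dominant class first).
    """
    _check_weights(G)
    H = G.subgraph([n for n in G.nodes if G.degree(n) > 0]).copy()
    if H.number_of_edges() == 0:
        warnings.warn("empty edge set; every connected node is its own community")
        labels = {n: i for i, n in enumerate(sorted(H.nodes))}
        comp = _class_composition(G, labels)
        return CommunityPartition(network_id, labels, 0.0, seed, comp)
    best = None
    for r in range(restarts):
        communities = nx.community.louvain_communities(H, weight="weight", seed=seed + r)
        q = nx.community.modularity(H, communities, weight="weight")
        if best is None or q > best[0]:
            best = (q, communities)
    q, communities = best
    ordered = sorted(communities, key=lambda s: (-len(s), sorted(s)[0]))
    labels = {node: lab for lab, com in enumerate(ordered) for node in com}
    return CommunityPartition(network_id, labels, float(q), seed, _class_composition(G, labels))


def _class_composition(G: nx.Graph, labels: Mapping) -> pd.DataFrame:
    rows = []
    by_label: dict[int, list] = {}
    for node, lab in labels.items():
        by_label.setdefault(lab, []).append(node)
    for lab in sorted(by_label):
        classes = pd.Series(
            [G.nodes[n].get("scop_class", "?") for n in by_label[lab]]
        ).value_counts()
        rows.append(
            {
                "community": lab,
                "n_folds": len(by_label[lab]),
                "dominant_class": classes.index[0],
                "composition": ",".join(f"{c}:{k}" for c, k in classes.items()),
            }
        )
    return pd.DataFrame(rows, columns=["community", "n_folds", "dominant_class", "composition"])


# ---------------------------------------------------------------------------
# statistics panel


def network_statistics(
    G: nx.Graph, sibling_networks: Iterable[nx.Graph] = ()
) -> dict[str, float]:
    """Summary statistics for one network (S1-Fig-style panel).

    Reports connected-node and edge counts, unique edges relative to the
    sibling networks at the same threshold, density and average neighbour
    count over connected nodes, the average reciprocal-weight shortest path
    in the largest connected component, the global clustering coefficient
    (closed connected triplets over all connected triplets), and component
    counts.
    """
    connected = [n for n in G.nodes if G.degree(n) > 0]
    nc = len(connected)
    n_edges = G.number_of_edges()
    sibling_edges = set()
    for S in sibling_networks:
        sibling_edges |= {frozenset(e) for e in S.edges()}
    unique = sum(1 for e in G.edges() if frozenset(e) not in sibling_edges)
    components = [c for c in nx.connected_components(G) if len(c) > 1]
    if components:
        lcc = max(components, key=len)
        H = G.subgraph(lcc)
        dists = shortest_paths(H)
        vals = [
            d
            for i, row in dists.items()
            for j, d in row.items()
            if i < j and math.isfinite(d)
        ]
        avg_path = float(np.mean(vals)) if vals else math.nan
    else:
        avg_path = math.nan
    return {
        "n_connected_nodes": nc,
        "n_edges": n_edges,
        "n_unique_edges": int(unique),
        "density": (2.0 * n_edges / (nc * (nc - 1))) if nc > 1 else math.nan,
        "avg_neighbours": (2.0 * n_edges / nc) if nc else math.nan,
        "avg_shortest_path_lcc": avg_path,
        "clustering_coefficient": float(nx.transitivity(G)),
        "n_components": len(components),
        "n_components_ge20": sum(1 for c in components if len(c) >= 20),
    }


def identify_pivotal(central_sets: Iterable[Mapping[str, Mapping[str, set]]]) -> set:
    """Folds central under every measure in every network.

    ``central_sets`` iterates over per-network partitions as produced by
    :func:`partition_central_peripheral`; the pivotal set is the
    intersection of all central sets across networks and measures.
    """
    pivotal: set | None = None
    for per_network in central_sets:
        for measure in MEASURES:
            central = set(per_network[measure]["central"])
            pivotal = central if pivotal is None else pivotal & central
    return pivotal if pivotal is not None else set()


def pooled_centrality_rank(centrality_frames) -> pd.Series:
    """Mean percentile rank of each node across networks and measures.

    Summarises how central a fold is overall: for every centrality frame
    (one per network) and every measure, nodes are percentile-ranked, and
    the ranks are averaged.  Useful as a single planted-signal axis when
    validating centrality-related analyses.
    """
    from scipy import stats as _stats

    ranks = []
    for frame in centrality_frames:
        df = frame.set_index("node")
        for measure in MEASURES:
            ranks.append(
                pd.Series(_stats.rankdata(df[measure]) / len(df), index=df.index)
            )
    return pd.concat(ranks, axis=1).mean(axis=1)


def centrality_table(
    G: nx.Graph, cent: pd.DataFrame, partitions: dict[str, dict[str, set]]
) -> pd.DataFrame:
    """Centrality frame with central/peripheral flags per measure."""
    df = cent.copy()
    for measure in MEASURES:
        df[f"central_{measure}"] = df["node"].isin(partitions[measure]["central"])
        df[f"peripheral_{measure}"] = df["node"].isin(partitions[measure]["peripheral"])
    return df
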