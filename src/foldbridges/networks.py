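"""Fold-level network construction from calibrated pairwise posteriors.

The domain x domain posterior array is collapsed to a group x group array
(family, superfamily or fold level) by keeping, for each pair of groups, the
single cross-group alignment with the highest posterior probability together
with its provenance (the domain pair and raw score).  Static networks are
cut at posterior thresholds (edges where posterior >= threshold), a dynamic
sequence sweeps the threshold downward recording each edge's birth
threshold, and consensus networks intersect the per-method edge sets with
mean-normalized averaged weights.

Networks are plain :class:`networkx.Graph` objects.  Graph-level metadata
lives in ``G.graph`` (``method``, ``level``, ``threshold``), nodes carry
``scop_class``, ``size`` and optionally ``age`` attributes, and edges carry
``posterior``, ``weight`` and provenance.  Unconnected groups are kept as
nodes: renderers may drop them but analyses see the full node universe.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

LEVELS = ("family", "superfamily", "fold")


# ---------------------------------------------------------------------------
# collapse


def collapse(
    pair_table: pd.DataFrame,
    annotation: pd.DataFrame,
    level: str = "fold",
) -> pd.DataFrame:
    """Collapse domain-pair posteriors to the best alignment per group pair.

    ``pair_table`` needs columns ``domain_i, domain_j, posterior`` (extra
    columns such as ``score`` and ``weight`` are carried through).  Rows
    whose domains share a group are dropped; for each unordered group pair
    the row with the maximal posterior is kept, with the winning domain pair
    recorded as ``provenance_domain_a/b``.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    group = annotation.set_index("domain_id")[level]
    ga = pair_table["domain_i"].map(group)
    gb = pair_table["domain_j"].map(group)
    if ga.isna().any() or gb.isna().any():
        offenders = sorted(
            set(pair_table.loc[ga.isna(), "domain_i"]).union(
                pair_table.loc[gb.isna(), "domain_j"]
            )
        )
        raise ValueError(f"domains missing {level} annotation: {offenders[:10]}")
    df = pair_table.copy()
    df["group_a"] = np.minimum(ga, gb)
    df["group_b"] = np.maximum(ga, gb)
    df = df[df["group_a"] != df["group_b"]]
    if df.empty:
        return pd.DataFrame(
            columns=["group_a", "group_b", "posterior", "provenance_domain_a", "provenance_domain_b"]
        )
    best = df.loc[df.groupby(["group_a", "group_b"], sort=True)["posterior"].idxmax()]
    best = best.rename(
        columns={"domain_i": "provenance_domain_a", "domain_j": "provenance_domain_b"}
    )
    front = ["group_a", "group_b", "posterior", "provenance_domain_a", "provenance_domain_b"]
    rest = [c for c in best.columns if c not in front]
    return best[front + rest].reset_index(drop=True)


# ---------------------------------------------------------------------------
# edge weights


def tm_d0(length: float) -> float:
    """TM-score normalization scale d0(L); floored for very short chains."""
    return max(1.24 * (length - 15.0) ** (1.0 / 3.0) - 1.8, 0.5) if length > 15 else 0.5


def fatcat_approx_tm(opt_rmsd: float, len_a: float, len_b: float, aligned_len: float | None = None) -> float:
    """Approximate TM-score from a FATCAT-style optimal RMSD and lengths.

    Uses the canonical TM-score functional with every residue deviation set
    to the reported RMSD, normalized by the mean domain length L:
    ``TM = (L_aln / L) / (1 + (rmsd / d0(L))^2)``.  With zero RMSD and a
    full-length alignment this is exactly 1.
    """
    mean_len = 0.5 * (len_a + len_b)
    if mean_len <= 0:
        raise ValueError("domain lengths must be positive")
    if aligned_len is None:
        aligned_len = mean_len
    return (aligned_len / mean_len) / (1.0 + (opt_rmsd / tm_d0(mean_len)) ** 2)


def inverse_distance(d: float) -> float:
    """Reciprocal of a distance-type score (e.g. an elastic metric)."""
    if d <= 0:
        raise ValueError(f"inverse weight undefined for nonpositive distance {d!r}")
    return 1.0 / d


def assign_edge_weight(convention: str, record: Mapping) -> float:
    """Edge weight for one alignment record under a method's convention.

    Conventions: ``tm_score`` (take the TM-score field verbatim — TM-align
    and MAMMOTH), ``fatcat_approx_tm`` (approximate TM from ``opt_rmsd`` and
    domain lengths), ``inverse_distance`` (reciprocal elastic metric — ESA),
    ``score`` (use the similarity-oriented score itself).  Weights are
    positive with "greater = more similar".
    """
    if convention == "tm_score":
        w = float(record["tm_score"] if "tm_score" in record else record["score"])
    elif convention == "fatcat_approx_tm":
        w = fatcat_approx_tm(
            float(record["opt_rmsd"]),
            float(record["len_a"]),
            float(record["len_b"]),
            float(record["aligned_len"]) if "aligned_len" in record else None,
        )
    elif convention == "inverse_distance":
        w = inverse_distance(float(record["score"]))
    elif convention == "score":
        w = float(record["score"])
    else:
        raise ValueError(f"unknown weight convention {convention!r}")
    if w <= 0:
        raise ValueError(f"edge weight must be positive, got {w}")
    return w


def assign_weights(pair_table: pd.DataFrame, convention: str) -> pd.DataFrame:
    """Vectorised weight assignment; adds a ``weight`` column."""
    df = pair_table.copy()
    if convention in ("score", "tm_score"):
        col = "tm_score" if (convention == "tm_score" and "tm_score" in df) else "score"
        df["weight"] = df[col].astype(float)
    elif convention == "inverse_distance":
        d = df["score"].astype(float)
        if (d <= 0).any():
            raise ValueError("inverse weight undefined for nonpositive distances")
        df["weight"] = 1.0 / d
    elif convention == "fatcat_approx_tm":
        df["weight"] = [
            fatcat_approx_tm(
                r["opt_rmsd"], r["len_a"], r["len_b"], r.get("aligned_len")
            )
            for r in df.to_dict("records")
        ]
    else:
        raise ValueError(f"unknown weight convention {convention!r}")
    if (df["weight"] <= 0).any():
        raise ValueError("edge weights must be positive")
    return df


# ---------------------------------------------------------------------------
# static / dynamic / consensus networks


def _node_universe(annotation: pd.DataFrame, level: str) -> pd.DataFrame:
    info = (
        annotation.groupby(level, sort=True)
        .agg(scop_class=("class", "first"), size=("domain_id", "count"))
        .reset_index()
        .rename(columns={level: "group"})
    )
    return info


def build_static_network(
    collapsed: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: float,
    method: str,
    level: str = "fold",
    ages: pd.DataFrame | None = None,
) -> nx.Graph:
    """Static network at one posterior threshold (closed: posterior >= t).

    All groups at the hierarchy level are nodes, connected or not.
    """
    G = nx.Graph(method=method, level=level, threshold=float(threshold))
    age_of = None if ages is None else ages.set_index("fold")["age"]
    for row in _node_universe(annotation, level).itertuples(index=False):
        attrs = {"scop_class": row.scop_class, "size": int(row.size)}
        if age_of is not None and row.group in age_of.index:
            attrs["age"] = float(age_of[row.group])
        G.add_node(row.group, **attrs)
    keep = collapsed[collapsed["posterior"] >= threshold]
    for row in keep.itertuples(index=False):
        G.add_edge(
            row.group_a,
            row.group_b,
            posterior=float(row.posterior),
            weight=float(getattr(row, "weight", 1.0)),
            provenance_domain_a=row.provenance_domain_a,
            provenance_domain_b=row.provenance_domain_b,
            raw_score=float(getattr(row, "score", np.nan)),
        )
    return G


def build_dynamic_sequence(
    collapsed: pd.DataFrame,
    annotation: pd.DataFrame,
    method: str,
    grid: Sequence[float] | None = None,
    level: str = "fold",
    ages: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[nx.Graph]]:
    """Threshold sweep from high to low with per-edge birth thresholds.

    ``grid`` must be strictly decreasing (default 1.00 down to 0.50 in steps
    of 0.01).  An edge's birth threshold is the highest grid value at which
    it appears, i.e. the largest grid value <= its posterior.  Returns the
    birth table and the ordered list of networks, one per grid value; the
    final frame equals the static network at the lowest grid value.
    """
    if grid is None:
        grid = np.round(np.arange(1.0, 0.5 - 1e-9, -0.01), 10)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size < 1 or np.any(np.diff(grid) >= 0):
        raise ValueError("grid must be strictly decreasing")
    post = collapsed["posterior"].to_numpy() if len(collapsed) else np.empty(0)
    asc = grid[::-1]
    idx = np.searchsorted(asc, post, side="right") - 1
    birth = np.where(idx >= 0, asc[np.clip(idx, 0, None)], np.nan)
    birth_table = collapsed[["group_a", "group_b", "posterior"]].copy()
    birth_table["birth_threshold"] = birth
    birth_of = {
        (r.group_a, r.group_b): r.birth_threshold
        for r in birth_table.itertuples(index=False)
    }
    graphs = []
    for t in grid:
        G = build_static_network(collapsed, annotation, t, method, level=level, ages=ages)
        for u, v, data in G.edges(data=True):
            data["birth_threshold"] = float(birth_of[(min(u, v), max(u, v))])
        graphs.append(G)
    return birth_table, graphs


def build_consensus(networks: Mapping[str, nx.Graph]) -> nx.Graph:
    """Consensus network: edges present in every contributing method.

    Per method, edge weights are first centred by dividing by that method's
    mean edge weight over its own network at this threshold; the consensus
    weight is the mean of the normalized weights.  Node attributes are taken
    from the first network (the node universe is shared).
    """
    methods = list(networks)
    if not methods:
        raise ValueError("at least one network is required")
    thresholds = {G.graph.get("threshold") for G in networks.values()}
    levels = {G.graph.get("level") for G in networks.values()}
    if len(thresholds) > 1 or len(levels) > 1:
        raise ValueError("consensus requires networks at one threshold and level")
    first = networks[methods[0]]
    C = nx.Graph(
        method="consensus",
        level=first.graph.get("level"),
        threshold=first.graph.get("threshold"),
        consensus_of=",".join(methods),
    )
    C.add_nodes_from(first.nodes(data=True))

    mean_weight = {}
    for m, G in networks.items():
        weights = [d["weight"] for _, _, d in G.edges(data=True)]
        if not weights:
            warnings.warn(f"method {m!r} has no edges at this threshold; consensus is empty")
            return C
        mean_weight[m] = float(np.mean(weights))

    common = set(frozenset(e) for e in first.edges())
    for m in methods[1:]:
        common &= set(frozenset(e) for e in networks[m].edges())
    for edge in common:
        u, v = sorted(edge)
        normalized = [networks[m][u][v]["weight"] / mean_weight[m] for m in methods]
        posterior = min(networks[m][u][v]["posterior"] for m in methods)
        C.add_edge(
            u,
            v,
            weight=float(np.mean(normalized)),
            posterior=float(posterior),
            multiplicity=len(methods),
        )
    return C


def static_network_sweep(
    collapsed_by_method: Mapping[str, pd.DataFrame],
    annotation: pd.DataFrame,
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    level: str = "fold",
    ages: pd.DataFrame | None = None,
) -> dict[tuple[str, float], nx.Graph]:
    """Build every per-method network plus the consensus at each threshold.

    With four methods and five thresholds this emits the full inventory of
    25 static networks.
    """
    suite: dict[tuple[str, float], nx.Graph] = {}
    for t in thresholds:
        per_method = {
            m: build_static_network(coll, annotation, t, m, level=level, ages=ages)
            for m, coll in collapsed_by_method.items()
        }
        suite.update({(m, t): G for m, G in per_method.items()})
        suite[("consensus", t)] = build_consensus(per_method)
    return suite


def edge_multiplicity(networks: Mapping[str, nx.Graph]) -> tuple[pd.DataFrame, dict[int, int]]:
    """Number of methods displaying each group pair as an edge.

    Returns a frame over *all* unordered pairs of the shared node universe
    (multiplicity 0 marks unconnected pairs) and the histogram over
    multiplicities 1..n_methods.  The histogram totals the union edge count.
    """
    universes = [set(G.nodes) for G in networks.values()]
    universe = sorted(set.union(*universes))
    if any(u != set(universe) for u in universes):
        raise ValueError("networks must share one node universe")
    counts: dict[frozenset, int] = {}
    for G in networks.values():
        for e in G.edges():
            counts[frozenset(e)] = counts.get(frozenset(e), 0) + 1
    rows = []
    n = len(universe)
    for a in range(n):
        for b in range(a + 1, n):
            pair = frozenset((universe[a], universe[b]))
            rows.append((universe[a], universe[b], counts.get(pair, 0)))
    frame = pd.DataFrame(rows, columns=["group_a", "group_b", "multiplicity"])
    hist = {
        k: int((frame["multiplicity"] == k).sum()) for k in range(1, len(networks) + 1)
    }
    return frame, hist


# ---------------------------------------------------------------------------
# export


def edge_list_frame(G: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, d in G.edges(data=True):
        rows.append(
            {
                "group_a": min(u, v),
                "group_b": max(u, v),
                "posterior": d.get("posterior"),
                "weight": d.get("weight"),
                "multiplicity": d.get("multiplicity"),
                "provenance_domain_a": d.get("provenance_domain_a"),
                "provenance_domain_b": d.get("provenance_domain_b"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a",
            "group_b",
            "posterior",
            "weight",
            "multiplicity",
            "provenance_domain_a",
            "provenance_domain_b",
        ],
    ).sort_values(["group_a", "group_b"], ignore_index=True)


def write_edge_list(G: nx.Graph, path) -> None:
    edge_list_frame(G).to_csv(path, sep="\t", index=False)


def write_graphml(G: nx.Graph, path) -> None:
    H = G.copy()
    for _, _, d in H.edges(data=True):
        for key in list(d):
            if d[key] is None or (isinstance(d[key], float) and np.isnan(d[key])):
                del d[key]
    nx.write_graphml(H, path)
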