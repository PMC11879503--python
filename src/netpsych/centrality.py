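"""Node and bridge centrality, and node predictability.

Conventions (the ones used throughout applied network psychometrics):

* strength_i   = sum_j |w_ij|           (signed version: expected influence)
* distances    d_ij = 1 / |w_ij| on present edges; shortest paths by Dijkstra
* closeness_i  = 1 / sum_j d*_ij        (d* = shortest-path distance,
  reachable nodes only for disconnected graphs)
* betweenness  = Brandes count of shortest paths through i, pairs counted
  once, endpoints excluded, ties split fractionally
* bridge variants restrict the sums / pairs to nodes outside i's community
  (bridge closeness uses the *mean* distance to outside nodes)
* predictability_i = R^2 of regressing node i on all other nodes.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .datasets import QuestionnaireDataset
from .ggm import WeightedNetwork

__all__ = [
    "node_centralities",
    "predictability",
    "bridge_centralities",
    "centrality_table",
    "select_bridge_nodes",
    "z_standardize",
    "tidy_table",
]

NODE_INDICES = ["strength", "closeness", "betweenness", "expected_influence"]
BRIDGE_INDICES = [
    "bridge_strength",
    "bridge_closeness",
    "bridge_betweenness",
    "bridge_expected_influence",
]


def _distance_graph(net: WeightedNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.p))
    for i in range(net.p):
        for j in range(i + 1, net.p):
            if net.W[i, j] != 0.0:
                G.add_edge(i, j, dist=1.0 / abs(net.W[i, j]))
    return G


def node_centralities(net: WeightedNetwork) -> pd.DataFrame:
    """Strength, closeness, betweenness and expected influence per node.

    On disconnected networks closeness sums distances over reachable
    nodes only; the ``n_reachable`` column records how many that was.
    """
    W, p = net.W, net.p
    G = _distance_graph(net)
    strength = np.abs(W).sum(axis=1)
    ei = W.sum(axis=1)
    closeness = np.zeros(p)
    reachable = np.zeros(p, dtype=int)
    for i in range(p):
        lengths = nx.single_source_dijkstra_path_length(G, i, weight="dist")
        total = sum(d for j, d in lengths.items() if j != i)
        reachable[i] = len(lengths) - 1
        closeness[i] = 1.0 / total if total > 0 else 0.0
    btw = nx.betweenness_centrality(G, normalized=False, weight="dist")
    out = pd.DataFrame(
        {
            "strength": strength,
            "closeness": closeness,
            "betweenness": [btw[i] for i in range(p)],
            "expected_influence": ei,
            "n_reachable": reachable,
        },
        index=pd.Index(net.node_names, name="node"),
    )
    return out


def predictability(data: QuestionnaireDataset) -> pd.Series:
    """Per-node R^2: variance explained by all remaining nodes.

    Computed by least squares on z-scored columns; this is the
    variance-explained reading of node predictability for
    quasi-continuous subscale sums.
    """
    X = data.values()
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    r2 = np.zeros(p)
    for j in range(p):
        others = np.delete(Z, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"singular design when predicting {data.node_names[j]}")
        coef, *_ = np.linalg.lstsq(design, Z[:, j], rcond=None)
        resid = Z[:, j] - design @ coef
        r2[j] = 1.0 - resid @ resid / (Z[:, j] @ Z[:, j])
    return pd.Series(np.clip(r2, 0.0, 1.0), index=pd.Index(data.node_names, name="node"),
                     name="predictability")


def _pair_betweenness_fraction(G, s, t, i):
    """Fraction of shortest s-t paths passing through interior node i."""
    try:
        paths = list(nx.all_shortest_paths(G, s, t, weight="dist"))
    except nx.NetworkXNoPath:
        return 0.0
    hits = sum(1 for path in paths if i in path[1:-1])
    return hits / len(paths)


def bridge_centralities(
    net: WeightedNetwork, communities: dict[str, str] | None = None
) -> pd.DataFrame:
    """Bridge strength / EI (1-step) / closeness / betweenness per node.

    Bridge strength (EI) sums absolute (signed) weights to nodes outside
    the node's own community; bridge closeness is the reciprocal of the
    mean shortest-path distance to outside nodes; bridge betweenness
    counts shortest paths between pairs of nodes from two different
    communities that pass through the node.
    """
    comm_map = communities or net.communities
    if not comm_map:
        raise ValueError("bridge centrality requires community labels")
    comm = [comm_map[name] for name in net.node_names]
    if len(set(comm)) < 2:
        raise ValueError("bridge centrality undefined with a single community")
    W, p = net.W, net.p
    G = _distance_graph(net)
    outside = [[j for j in range(p) if comm[j] != comm[i]] for i in range(p)]
    b_strength = np.array([sum(abs(W[i, j]) for j in outside[i]) for i in range(p)])
    b_ei = np.array([sum(W[i, j] for j in outside[i]) for i in range(p)])
    b_close = np.zeros(p)
    for i in range(p):
        lengths = nx.single_source_dijkstra_path_length(G, i, weight="dist")
        dists = [lengths[j] for j in outside[i] if j in lengths]
        b_close[i] = 1.0 / float(np.mean(dists)) if dists else 0.0
    b_btw = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            if comm[s] == comm[t]:
                continue
            for i in range(p):
                if i in (s, t):
                    continue
                b_btw[i] += _pair_betweenness_fraction(G, s, t, i)
    return pd.DataFrame(
        {
            "bridge_strength": b_strength,
            "bridge_closeness": b_close,
            "bridge_betweenness": b_btw,
            "bridge_expected_influence": b_ei,
        },
        index=pd.Index(net.node_names, name="node"),
    )


def z_standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``z_<col>`` column per index (mean 0, SD 1 across nodes)."""
    out = table.copy()
    for col in table.columns:
        vals = table[col].to_numpy(dtype=float)
        sd = vals.std(ddof=1)
        out[f"z_{col}"] = (vals - vals.mean()) / sd if sd > 0 else 0.0
    return out


def centrality_table(
    net: WeightedNetwork,
    data: QuestionnaireDataset | None = None,
    communities: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Combined node + bridge + predictability table with z-scores.

    Bridge indices are included when community labels are available;
    predictability when the underlying dataset is supplied.
    """
    parts = [node_centralities(net).drop(columns="n_reachable")]
    comm = communities or net.communities
    if comm and len(set(comm.values())) >= 2:
        parts.append(bridge_centralities(net, comm))
    if data is not None:
        parts.append(predictability(data).to_frame())
    table = pd.concat(parts, axis=1)
    z_cols = [c for c in table.columns if c != "predictability"]
    return pd.concat([table, z_standardize(table[z_cols]).filter(like="z_")], axis=1)


def select_bridge_nodes(
    table: pd.DataFrame, percentile: float = 80.0, indices: list[str] | None = None
) -> dict[str, list[str]]:
    """Nodes strictly above the given percentile of each bridge index.

    The percentile is computed with linear interpolation; ties at the
    cutoff are excluded (strict inequality), a deliberately conservative
    selection.
    """
    indices = indices or [c for c in BRIDGE_INDICES if c in table.columns]
    out = {}
    for col in indices:
        vals = table[col].to_numpy(dtype=float)
        cut = np.percentile(vals, percentile)
        out[col] = [node for node, v in zip(table.index, vals) if v > cut]
    return out


def tidy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long format (node, index, raw_value, z_value) for CSV export."""
    raw_cols = [c for c in table.columns if not c.startswith("z_")]
    rows = []
    for node in table.index:
        for col in raw_cols:
            rows.append(
                (node, col, table.loc[node, col], table.loc[node].get(f"z_{col}", np.nan))
            )
    return pd.DataFrame(rows, columns=["node", "index", "raw_value", "z_value"])
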