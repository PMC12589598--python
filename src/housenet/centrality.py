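"""Node centralities on the signed weighted partial-correlation network.

Four metrics, the standard psychometric-network set:

* expected influence -- sum of a node's *signed* edge weights (one step);
* strength -- sum of absolute edge weights;
* betweenness -- unnormalized shortest-path betweenness with edge length
  ``1/|weight|`` (strong edges are short);
* closeness -- for node i with reachable set R(i), ``|R(i)| / sum of
  shortest-path distances to R(i)``; 0 for isolated nodes.

Path-based metrics take absolute weights (the standard convention for
signed networks); betweenness is reported as raw pair counts.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .ggm import GGMNetwork, ZERO_TOL

METRICS = ("expected_influence", "strength", "betweenness", "closeness")


def _weight_matrix(net) -> tuple[np.ndarray, list[str]]:
    if isinstance(net, GGMNetwork):
        return net.weights, list(net.labels)
    w = np.asarray(net, dtype=float)
    return w, [f"v{i}" for i in range(w.shape[0])]


def to_graph(net) -> nx.Graph:
    """Graph with signed ``weight`` and ``length = 1/|weight|`` per edge.

    Zero-weight pairs carry no edge at all.
    """
    w, labels = _weight_matrix(net)
    g = nx.Graph()
    g.add_nodes_from(labels)
    p = w.shape[0]
    for i in range(p):
        for j in range(i + 1, p):
            if abs(w[i, j]) > ZERO_TOL:
                g.add_edge(
                    labels[i], labels[j], weight=w[i, j], length=1.0 / abs(w[i, j])
                )
    return g


def expected_influence(net) -> pd.Series:
    """One-step expected influence: row sums of the signed weight matrix."""
    w, labels = _weight_matrix(net)
    return pd.Series(w.sum(axis=1), index=labels, name="expected_influence")


def strength(net) -> pd.Series:
    """Row sums of absolute edge weights."""
    w, labels = _weight_matrix(net)
    return pd.Series(np.abs(w).sum(axis=1), index=labels, name="strength")


def betweenness(net) -> pd.Series:
    """Unnormalized shortest-path betweenness with 1/|weight| edge lengths."""
    g = to_graph(net)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    _, labels = _weight_matrix(net)
    return pd.Series([bc[v] for v in labels], index=labels, name="betweenness")


def closeness(net) -> pd.Series:
    """Reachable-set closeness: |R(i)| / sum of distances, 0 when isolated."""
    g = to_graph(net)
    cc = nx.closeness_centrality(g, distance="length", wf_improved=False)
    _, labels = _weight_matrix(net)
    return pd.Series([cc[v] for v in labels], index=labels, name="closeness")


_METRIC_FUNCS = {
    "expected_influence": expected_influence,
    "strength": strength,
    "betweenness": betweenness,
    "closeness": closeness,
}


def centrality_table(net, metrics=METRICS, zscore: bool = False) -> pd.DataFrame:
    """All requested centralities, one row per node.

    With ``zscore=True`` each metric column is additionally standardized
    (``<metric>_z``), the scale on which centrality plots are often drawn.
    """
    cols = {}
    for m in metrics:
        if m not in _METRIC_FUNCS:
            raise ValueError(f"unknown centrality metric {m!r}")
        cols[m] = _METRIC_FUNCS[m](net)
    table = pd.DataFrame(cols)
    table.index.name = "node"
    if zscore:
        for m in metrics:
            sd = table[m].std(ddof=0)
            table[m + "_z"] = (table[m] - table[m].mean()) / sd if sd > 0 else 0.0
    return table
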