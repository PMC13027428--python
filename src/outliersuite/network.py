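"""Thresholded Spearman co-expression networks and centrality comparison.

For each group an undirected graph is built over the variables: an edge
joins two variables when their Spearman correlation passes both the
strength (|r| > r_cut) and the significance (p < p_cut) thresholds.
Node importance is the normalized degree centrality degree/(n_nodes - 1).
Comparing the outlier and normal networks node-by-node yields the
centrality-delta table used to spot hub reconfiguration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationNetwork", "build_network", "compare_centrality"]


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    edges: pd.DataFrame           # columns: source, target, r, p
    centrality: pd.Series         # degree/(n_nodes-1), includes isolated nodes
    r_cut: float
    p_cut: float
    excluded: list[str] = field(default_factory=list)  # constant variables

    @property
    def n_edges(self) -> int:
        return int(self.graph.number_of_edges())


def _spearman_p(r: float, n: int) -> float:
    """Two-sided p for a Spearman coefficient via the t approximation."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def build_network(
    m: pd.DataFrame, r_cut: float = 0.5, p_cut: float = 0.05, exact_small: bool = False
) -> CorrelationNetwork:
    """Build the thresholded Spearman network over the matrix's variables.

    Tie-corrected rank correlations with t-approximation p-values (an
    exact permutation p is used for n < 10 when ``exact_small``).
    Constant variables have undefined correlations: they are kept as
    isolated nodes with centrality 0 and listed in ``excluded``.
    """
    n = m.shape[0]
    if n < 5:
        raise ValueError("network construction needs n >= 5")
    variables = list(m.columns)
    spread = m.max(axis=0) - m.min(axis=0)
    excluded = spread.index[spread == 0.0].tolist()
    graph = nx.Graph()
    graph.add_nodes_from(variables)
    rows = []
    for i, vi in enumerate(variables):
        for vj in variables[i + 1:]:
            if vi in excluded or vj in excluded:
                continue
            x, y = m[vi].to_numpy(dtype=float), m[vj].to_numpy(dtype=float)
            if exact_small and n < 10:
                res = stats.permutation_test(
                    (x,), lambda a: stats.spearmanr(a, y).statistic,
                    permutation_type="pairings", alternative="two-sided",
                    n_resamples=np.inf,
                )
                r, p = float(stats.spearmanr(x, y).statistic), float(res.pvalue)
            else:
                r = float(stats.spearmanr(x, y).statistic)
                p = _spearman_p(r, n)
            if abs(r) > r_cut and p < p_cut:
                graph.add_edge(vi, vj, r=r, p=p)
                rows.append(dict(source=vi, target=vj, r=r, p=p))
    edges = pd.DataFrame(rows, columns=["source", "target", "r", "p"])
    denom = max(len(variables) - 1, 1)
    centrality = pd.Series(
        {v: graph.degree(v) / denom for v in variables}, name="centrality"
    )
    return CorrelationNetwork(
        graph=graph, edges=edges, centrality=centrality,
        r_cut=r_cut, p_cut=p_cut, excluded=excluded,
    )


def compare_centrality(net_a: CorrelationNetwork, net_b: CorrelationNetwork) -> pd.DataFrame:
    """Per-node centrality delta (A - B), sorted by |delta| descending."""
    if set(net_a.centrality.index) != set(net_b.centrality.index):
        raise ValueError("networks have different node sets")
    table = pd.DataFrame({
        "centrality_a": net_a.centrality,
        "centrality_b": net_b.centrality.reindex(net_a.centrality.index),
    })
    table["delta"] = table["centrality_a"] - table["centrality_b"]
    return table.reindex(table["delta"].abs().sort_values(ascending=False).index)
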