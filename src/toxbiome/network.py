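"""Microbial co-occurrence networks and driver-taxon scoring.

Group-specific networks are built from Spearman correlations between the
relative abundances of prevalent taxa, with edges retained when the
BH-adjusted correlation p-value and the correlation magnitude pass fixed
thresholds.  Taxa whose neighborhood turns over and whose betweenness rises
from the low- to the high-toxicity network are scored as candidate drivers
of the community rewiring (a NetShift-inspired score; the original NESH
formula is not reproduced here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .associations import bh_adjust

__all__ = ["CooccurrenceNetwork", "build_network", "betweenness", "driver_scores"]


@dataclass
class CooccurrenceNetwork:
    """Thresholded correlation graph over prevalent taxa.

    ``graph`` contains every prevalent taxon as a node (isolated nodes are
    legitimate); ``edges`` lists the retained correlations with their sign
    and BH q-value.
    """

    graph: nx.Graph
    edges: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def build_network(
    table: pd.DataFrame,
    min_prevalence: float = 0.2,
    rho_min: float = 0.3,
    q_max: float = 0.05,
) -> CooccurrenceNetwork:
    """Build a co-occurrence network from a samples x taxa count table.

    Taxa present (nonzero) in at least ``min_prevalence`` of samples become
    nodes; Spearman correlations between their relative abundances are
    tested pairwise, BH-adjusted across all pairs, and kept as edges when
    ``q <= q_max`` and ``|rho| >= rho_min``.  Fewer than 10 samples is
    refused (rank correlations too unstable).
    """
    if len(table) < 10:
        raise ValueError("co-occurrence networks need >= 10 samples")
    x = table.astype(float)
    keep = (x > 0).mean(axis=0) >= min_prevalence
    x = x.loc[:, keep]
    rel = x.div(table.astype(float).sum(axis=1), axis=0)
    taxa = list(rel.columns)

    g = nx.Graph()
    g.add_nodes_from(taxa)
    if len(taxa) >= 2:
        rho, pval = stats.spearmanr(rel.values)
        rho = np.atleast_2d(rho)
        pval = np.atleast_2d(pval)
        iu = np.triu_indices(len(taxa), k=1)
        q = bh_adjust(pval[iu])
        edges = []
        for (i, j), qij in zip(zip(*iu), q):
            r = rho[i, j]
            if qij <= q_max and abs(r) >= rho_min:
                g.add_edge(taxa[i], taxa[j], rho=r, q=qij,
                           sign="+" if r > 0 else "-")
                edges.append(
                    {"u": taxa[i], "v": taxa[j], "rho": r, "q": qij,
                     "sign": "+" if r > 0 else "-"}
                )
        edges_df = pd.DataFrame(edges, columns=["u", "v", "rho", "q", "sign"])
    else:
        edges_df = pd.DataFrame(columns=["u", "v", "rho", "q", "sign"])
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    return CooccurrenceNetwork(
        graph=g,
        edges=edges_df,
        params={"min_prevalence": min_prevalence, "rho_min": rho_min, "q_max": q_max},
    )


def betweenness(net: CooccurrenceNetwork) -> pd.Series:
    """Normalized shortest-path betweenness on the unweighted edge set.

    Normalization divides by (n-1)(n-2)/2 node pairs; isolated nodes score 0.
    """
    bc = nx.betweenness_centrality(net.graph, normalized=True)
    return pd.Series(bc, name="betweenness")


def driver_scores(
    net_low: CooccurrenceNetwork,
    net_high: CooccurrenceNetwork,
    driver_quantile: float = 0.9,
) -> pd.DataFrame:
    """Rank taxa driving the rewiring between two condition networks.

    For every node present in both networks: the neighbor-shift score is the
    Jaccard distance between its neighbor sets (0 when both are empty); the
    betweenness delta is high minus low; the combined score is
    neighbor-shift x max(delta, 0), rescaled to [0, 1] over nodes.  Nodes
    whose combined score exceeds the ``driver_quantile`` quantile (and is
    positive, implying rising betweenness) are flagged as drivers.
    """
    shared = sorted(set(net_low.nodes) & set(net_high.nodes))
    if not shared:
        warnings.warn("networks share no nodes; empty driver table")
        return pd.DataFrame(
            columns=["node", "betweenness_low", "betweenness_high",
                     "delta_betweenness", "neighbor_shift", "score", "driver"]
        )
    b_low = betweenness(net_low)
    b_high = betweenness(net_high)
    rows = []
    for node in shared:
        nl = set(net_low.graph.neighbors(node))
        nh = set(net_high.graph.neighbors(node))
        union = nl | nh
        shift = 1.0 - len(nl & nh) / len(union) if union else 0.0
        delta = float(b_high[node] - b_low[node])
        rows.append(
            {
                "node": node,
                "betweenness_low": float(b_low[node]),
                "betweenness_high": float(b_high[node]),
                "delta_betweenness": delta,
                "neighbor_shift": shift,
                "score": shift * max(delta, 0.0),
            }
        )
    out = pd.DataFrame(rows)
    top = out["score"].max()
    if top > 0:
        out["score"] = out["score"] / top
    cutoff = out["score"].quantile(driver_quantile)
    out["driver"] = (out["score"] >= cutoff) & (out["score"] > 0)
    return out.sort_values("score", ascending=False).reset_index(drop=True)
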