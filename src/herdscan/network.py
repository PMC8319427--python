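"""Spearman co-occurrence network over core genera.

A co-occurrence event is a genus pair with |rho_s| > 0.25 and BH-adjusted
p < 0.001 (both strict); the hub is the maximal-degree node of the
resulting graph.  BH is applied over the upper triangle only — each
unordered pair is tested once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import bh_adjust

MIN_ABS_RHO = 0.25
MAX_Q = 0.001


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (average-rank ties) and two-sided t-approx p.

    Constant taxa yield NaN rows/columns (flagged with a warning); the
    diagonal is rho = 1 with p = NaN (untested).
    """
    if len(table) < 3:
        raise ValueError("need at least three samples")
    values = table.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant taxa; correlations undefined"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, p = stats.spearmanr(values)
    if np.ndim(rho) == 0:  # scipy collapses the two-taxon case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[np.nan, p], [p, np.nan]])
    np.fill_diagonal(p, np.nan)
    np.fill_diagonal(rho, 1.0)
    taxa = list(table.columns)
    return (
        pd.DataFrame(rho, index=taxa, columns=taxa),
        pd.DataFrame(p, index=taxa, columns=taxa),
    )


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    edges: pd.DataFrame  # source, target, rho, q, sign
    hubs: list[str]  # all maximal-degree nodes (empty if no edges)

    @property
    def degree_sum(self) -> int:
        return int(sum(d for _, d in self.graph.degree()))


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    min_rho: float = MIN_ABS_RHO,
    max_q: float = MAX_Q,
    node_labels: dict | None = None,
) -> CooccurrenceNetwork:
    """Threshold the correlation matrices into a co-occurrence graph.

    BH-adjusts the upper-triangle p-values, keeps pairs with
    |rho| > min_rho AND q < max_q (strict), and reports every node tied
    for maximal degree as a hub.  ``node_labels`` (e.g. breed-association
    classes) become node attributes.
    """
    if rho.empty:
        raise ValueError("empty correlation matrix")
    taxa = list(rho.index)
    r = rho.to_numpy(dtype=float)
    pv = p.to_numpy(dtype=float)
    iu = np.triu_indices(len(taxa), k=1)
    q_flat = bh_adjust(pv[iu])
    qmat = np.full_like(pv, np.nan)
    qmat[iu] = q_flat

    graph = nx.Graph()
    graph.add_nodes_from(taxa)
    rows = []
    for i, j in zip(*iu):
        rho_ij, q_ij = r[i, j], qmat[i, j]
        if not (np.isfinite(rho_ij) and np.isfinite(q_ij)):
            continue
        if abs(rho_ij) > min_rho and q_ij < max_q:
            graph.add_edge(
                taxa[i], taxa[j], rho=float(rho_ij), q=float(q_ij),
                sign="positive" if rho_ij > 0 else "negative",
            )
            rows.append(
                {
                    "source": taxa[i],
                    "target": taxa[j],
                    "rho": float(rho_ij),
                    "q": float(q_ij),
                    "sign": "positive" if rho_ij > 0 else "negative",
                }
            )
    degrees = dict(graph.degree())
    nx.set_node_attributes(graph, degrees, "degree")
    if node_labels:
        nx.set_node_attributes(
            graph, {t: node_labels.get(t, "") for t in taxa},
            "breed_association",
        )
    max_deg = max(degrees.values()) if degrees else 0
    hubs = (
        sorted(t for t, d in degrees.items() if d == max_deg)
        if max_deg > 0
        else []
    )
    edges = pd.DataFrame(
        rows, columns=["source", "target", "rho", "q", "sign"]
    )
    return CooccurrenceNetwork(graph=graph, edges=edges, hubs=hubs)


def write_edge_list(net: CooccurrenceNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
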