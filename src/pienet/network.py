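"""Residue interaction networks and information-theoretic graph comparison.

A protein residue network (PRN) represents residues/nucleotides as nodes and
keeps an edge for every attractive ensemble-mean interaction stronger than a
threshold E_lim (by convention −1 kcal/mol), weighted by that mean energy.

Two PRNs over the same node universe are compared through the joint
histogram of their edge weights: every unit pair with an edge in either
graph contributes one count at (bin of its weight in graph 1, bin in graph
2); a pair missing from one graph falls into a dedicated "no-edge" bin on
that axis.  The mutual information of the joint distribution, normalized by
the marginal entropies, gives the coefficients of constraint
C(1|2) = MI/H1 and C(2|1) = MI/H2 — 1 when either graph fully predicts the
other, 0 when they are independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GraphComparison",
    "build_prn",
    "pair_category",
    "joint_weight_histogram",
    "mutual_information",
    "compare_graphs",
    "average_comparisons",
    "export_edge_list",
    "export_graphml",
]

CATEGORY_KEYS = ("all", "nuc-nuc", "nuc-aa", "aa-aa")


@dataclass
class GraphComparison:
    """MI and entropy statistics between two interaction graphs."""

    mi: float
    h1: float
    h2: float
    c_1_given_2: float
    c_2_given_1: float
    n_bins: int
    e_lim: Optional[float] = None
    category: str = "all"

    def __post_init__(self):
        if self.mi < -1e-12:
            raise ValueError("mutual information must be non-negative")


def build_prn(
    table: pd.DataFrame,
    categories: Mapping[int, str],
    labels: Optional[Mapping[int, str]] = None,
    e_lim: float = -1.0,
    weight_col: str = "total_mean",
) -> nx.Graph:
    """Thresholded interaction graph from an ensemble-mean pair table.

    ``table`` must have columns unit_i, unit_j and ``weight_col``.  An edge
    is kept iff its mean energy is <= ``e_lim`` (attractive and stronger
    than the threshold); the weight is the mean energy itself.  All units in
    ``categories`` become nodes, so sparser graphs share the node universe.
    """
    if e_lim >= 0:
        raise ValueError("E_lim must be negative (attractive threshold)")
    g = nx.Graph(e_lim=e_lim)
    for uid, cat in categories.items():
        g.add_node(uid, category=cat,
                   label=labels[uid] if labels is not None else str(uid))
    for _, row in table.iterrows():
        w = float(row[weight_col])
        ui, uj = int(row["unit_i"]), int(row["unit_j"])
        if ui == uj:
            continue
        if w <= e_lim:
            g.add_edge(ui, uj, weight=w)
    return g


def pair_category(u: int, v: int, categories: Mapping[int, str]) -> str:
    """"nuc-nuc", "nuc-aa" or "aa-aa" for a unit pair."""
    cats = sorted((categories[u], categories[v]))
    if cats == ["nuc", "nuc"]:
        return "nuc-nuc"
    if cats == ["aa", "nuc"]:
        return "nuc-aa"
    return "aa-aa"


def joint_weight_histogram(
    graph1: nx.Graph,
    graph2: nx.Graph,
    n_bins: int = 40,
    category: str = "all",
) -> np.ndarray:
    """Joint edge-weight histogram of two graphs over the same node universe.

    Returns an (n_bins+1, n_bins+1) count matrix: the first ``n_bins`` bins
    along each axis cover [min weight over both graphs, E_lim] left-closed,
    and the final index is the no-edge bin for pairs absent from that graph.
    """
    if set(graph1.nodes) != set(graph2.nodes):
        raise ValueError("graphs must share the same node universe")
    if category not in CATEGORY_KEYS:
        raise ValueError(f"category must be one of {CATEGORY_KEYS}")
    cats1 = nx.get_node_attributes(graph1, "category")

    pairs = set(map(frozenset, graph1.edges)) | set(map(frozenset, graph2.edges))
    if category != "all":
        pairs = {p for p in pairs if pair_category(*sorted(p), cats1) == category}

    weights = [graph1.edges[tuple(p)]["weight"] for p in pairs if graph1.has_edge(*tuple(p))]
    weights += [graph2.edges[tuple(p)]["weight"] for p in pairs if graph2.has_edge(*tuple(p))]
    e_lim = graph1.graph.get("e_lim", graph2.graph.get("e_lim", -1.0))
    lo = min(weights) if weights else e_lim - 1.0
    edges = np.linspace(lo, e_lim, n_bins + 1)

    def bin_of(graph: nx.Graph, pair) -> int:
        u, v = tuple(pair)
        if not graph.has_edge(u, v):
            return n_bins  # no-edge bin
        w = graph.edges[u, v]["weight"]
        # left-closed bins; the rightmost energy bin includes E_lim itself
        k = int(np.searchsorted(edges, w, side="right")) - 1
        return min(max(k, 0), n_bins - 1)

    counts = np.zeros((n_bins + 1, n_bins + 1))
    for p in pairs:
        counts[bin_of(graph1, p), bin_of(graph2, p)] += 1
    return counts


def mutual_information(
    hist: np.ndarray,
    base: Optional[float] = None,
    e_lim: Optional[float] = None,
    category: str = "all",
    label_1_is_numerator: bool = True,
) -> GraphComparison:
    """MI, marginal entropies, and coefficients of constraint from a joint histogram.

    Natural logarithm by default (``base`` switches the unit).  With the
    default convention C(1|2) = MI/H1 and C(2|1) = MI/H2;
    ``label_1_is_numerator=False`` swaps the two normalizations.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise ValueError("histogram has no counts")
    p = hist / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def entropy(q: np.ndarray) -> float:
        q = q[q > 0]
        h = -np.sum(q * np.log(q))
        return float(h / np.log(base)) if base else float(h)

    nz = p > 0
    outer = px[:, None] * py[None, :]
    mi = float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))
    if base:
        mi /= np.log(base)
    mi = max(mi, 0.0)
    h1, h2 = entropy(px), entropy(py)
    c1 = mi / h1 if h1 > 0 else (1.0 if mi == 0 else np.nan)
    c2 = mi / h2 if h2 > 0 else (1.0 if mi == 0 else np.nan)
    if not label_1_is_numerator:
        c1, c2 = c2, c1
    return GraphComparison(
        mi=mi, h1=h1, h2=h2, c_1_given_2=c1, c_2_given_1=c2,
        n_bins=hist.shape[0] - 1, e_lim=e_lim, category=category,
    )


def compare_graphs(
    graph1: nx.Graph,
    graph2: nx.Graph,
    n_bins: int = 40,
    category: str = "all",
    base: Optional[float] = None,
) -> GraphComparison:
    """Joint histogram + MI in one step."""
    hist = joint_weight_histogram(graph1, graph2, n_bins=n_bins, category=category)
    e_lim = graph1.graph.get("e_lim")
    return mutual_information(hist, base=base, e_lim=e_lim, category=category)


def average_comparisons(comparisons: Sequence[GraphComparison]) -> GraphComparison:
    """Mean of per-snapshot comparison statistics (same bins/category)."""
    if not comparisons:
        raise ValueError("nothing to average")
    return GraphComparison(
        mi=float(np.mean([c.mi for c in comparisons])),
        h1=float(np.mean([c.h1 for c in comparisons])),
        h2=float(np.mean([c.h2 for c in comparisons])),
        c_1_given_2=float(np.mean([c.c_1_given_2 for c in comparisons])),
        c_2_given_1=float(np.mean([c.c_2_given_1 for c in comparisons])),
        n_bins=comparisons[0].n_bins,
        e_lim=comparisons[0].e_lim,
        category=comparisons[0].category,
    )


def export_edge_list(graph: nx.Graph, path=None) -> pd.DataFrame:
    """Three-column edge list (unit_i, unit_j, weight)."""
    rows = [
        {"unit_i": u, "unit_j": v, "weight": d["weight"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    frame = pd.DataFrame(rows, columns=["unit_i", "unit_j", "weight"])
    if path is not None:
        frame.to_csv(path, index=False)
    return frame


def export_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
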