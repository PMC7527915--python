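"""Patient-flow network and backbone extraction.

Readmitted patients' trajectories are summarized as a directed tripartite
graph: index diagnosis d1 -> specialty s -> readmission diagnosis d2, with
edge weights counting the patients that followed the link and a men/women
ratio annotation per link.  The full graph is dense, so a backbone is
extracted by overlapping the maximum spanning tree (connectivity) with the
disparity filter (edge significance): an edge with normalized weight p at a
degree-k endpoint has significance (1 - p)^(k - 1) and passes when that
value falls below the chosen level at either endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .cohort import CONTACT_PREFIX, specialties_of  # noqa: F401 - CONTACT_PREFIX re-used by callers

__all__ = [
    "build_flow_network",
    "disparity_filter",
    "disparity_significance",
    "maximum_spanning_tree",
    "extract_backbone",
    "Backbone",
    "export_edge_list",
]


def build_flow_network(
    records: pd.DataFrame,
    combinations: pd.DataFrame,
    specialties: Iterable[str] | None = None,
) -> nx.DiGraph:
    """Directed tripartite flow network d1 -> s -> d2.

    For each diagnosis combination in ``combinations`` (already filtered by
    the minimum-case rule) and each specialty, every readmitted patient of
    the combination's sex stratum carrying d1, readmitted with d2 and having
    had the contact adds one unit of weight to the edges d1 -> s and
    s -> d2.  Each edge carries the men and women counts and their ratio
    (``inf`` sentinel with ``sex_ratio_defined=False`` when no women
    followed the link).
    """
    if specialties is None:
        specialties = specialties_of(records)
    specialties = list(specialties)
    G = nx.DiGraph()
    re_rec = records[records["readmitted"]]
    combos = combinations[["d1", "d2", "sex"]].drop_duplicates() if len(combinations) else combinations

    def _bump(u, v, utype, vtype, n_m, n_f):
        n = n_m + n_f
        if n == 0:
            return
        if not G.has_node(u):
            G.add_node(u, type=utype)
        if not G.has_node(v):
            G.add_node(v, type=vtype)
        if G.has_edge(u, v):
            e = G[u][v]
            e["weight"] += n
            e["n_men"] += n_m
            e["n_women"] += n_f
        else:
            G.add_edge(u, v, weight=n, n_men=n_m, n_women=n_f)

    for combo in combos.itertuples(index=False):
        sub = re_rec[
            (re_rec["sex"] == combo.sex)
            & (re_rec["readmission_main_dx"] == combo.d2)
            & re_rec["index_dx"].map(lambda dx, d1=combo.d1: d1 in dx)
        ]
        if len(sub) == 0:
            continue
        for s in specialties:
            col = CONTACT_PREFIX + s
            n = int(sub[col].sum())
            if n == 0:
                continue
            n_m = n if combo.sex == "m" else 0
            n_f = n - n_m
            _bump(combo.d1, s, "diagnosis", "specialty", n_m, n_f)
            _bump(s, combo.d2, "specialty", "diagnosis", n_m, n_f)

    for u, v, e in G.edges(data=True):
        defined = e["n_women"] > 0
        e["sex_ratio"] = e["n_men"] / e["n_women"] if defined else float("inf")
        e["sex_ratio_defined"] = defined
    for node in G.nodes:
        G.nodes[node]["out_degree"] = G.out_degree(node)
    return G


def disparity_significance(G: nx.DiGraph) -> dict[tuple, float]:
    """Per-edge disparity significance, taken as the minimum over the two
    endpoints of (1 - p)^(k - 1).

    Degrees and strengths are computed on the undirected incidence view: all
    edges touching a node count toward its degree k and strength, and
    p = w / strength.  A degree-1 endpoint contributes significance 1 (such
    an edge can only pass through its other endpoint).
    """
    incident: dict = {n: [] for n in G.nodes}
    for u, v, e in G.edges(data=True):
        incident[u].append(((u, v), e["weight"]))
        incident[v].append(((u, v), e["weight"]))
    alpha: dict[tuple, float] = {edge: 1.0 for edge in G.edges}
    for node, edges in incident.items():
        k = len(edges)
        if k < 2:
            continue
        strength = float(sum(w for _, w in edges))
        for edge, w in edges:
            a = (1.0 - w / strength) ** (k - 1)
            alpha[edge] = min(alpha[edge], a)
    return alpha


def disparity_filter(G: nx.DiGraph, alpha_level: float = 0.05) -> set[tuple]:
    """Edges significant under the disparity filter at ``alpha_level``.

    An edge is kept when its significance (1 - p)^(k - 1) is below
    ``alpha_level`` from at least one endpoint's perspective.  Edges whose
    only endpoint has degree 1 never pass on that endpoint alone.
    """
    alpha = disparity_significance(G)
    return {edge for edge, a in alpha.items() if a < alpha_level}


def maximum_spanning_tree(G: nx.Graph) -> set[tuple]:
    """Maximum-weight spanning forest of the undirected view of ``G``.

    Kruskal with ties broken lexicographically by edge key, so the result is
    deterministic; returns one edge set per the original (directed) edges,
    with n_nodes - n_components edges in total.
    """
    edges = sorted(
        G.edges(data="weight"),
        key=lambda e: (-e[2], str(e[0]), str(e[1])),
    )
    uf = nx.utils.UnionFind(G.nodes)
    chosen: set[tuple] = set()
    for u, v, _w in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            chosen.add((u, v))
    return chosen


@dataclass
class Backbone:
    """Backbone edge subset with per-edge provenance in {mst, disparity, both}."""

    edges: dict[tuple, str]
    alpha_level: float
    mode: str

    def to_graph(self, G: nx.DiGraph) -> nx.DiGraph:
        H = G.edge_subgraph(self.edges).copy()
        for edge, prov in self.edges.items():
            H.edges[edge]["provenance"] = prov
        return H


def extract_backbone(
    G: nx.DiGraph, alpha_level: float = 0.05, mode: str = "union"
) -> Backbone:
    """Overlap the maximum spanning tree with the disparity filter.

    ``mode='union'`` (default) keeps MST edges plus disparity-significant
    edges — the MST guarantees every component stays connected while the
    filter adds the locally significant links.  ``mode='intersection'``
    keeps only edges found by both.
    """
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    mst = maximum_spanning_tree(G)
    disp = disparity_filter(G, alpha_level)
    if mode == "union":
        kept = mst | disp
    else:
        kept = mst & disp
    edges = {}
    for e in sorted(kept, key=lambda t: (str(t[0]), str(t[1]))):
        in_mst, in_disp = e in mst, e in disp
        edges[e] = "both" if (in_mst and in_disp) else ("mst" if in_mst else "disparity")
    return Backbone(edges=edges, alpha_level=alpha_level, mode=mode)


def export_edge_list(G: nx.DiGraph, backbone: Backbone | None = None) -> pd.DataFrame:
    """Plain edge-list table (source, target, weight, sex_ratio, provenance)."""
    rows = []
    edges = backbone.edges if backbone is not None else {e: "" for e in G.edges}
    for (u, v), prov in edges.items():
        e = G[u][v]
        rows.append(
            {
                "source": u,
                "target": v,
                "weight": e["weight"],
                "n_men": e["n_men"],
                "n_women": e["n_women"],
                "sex_ratio": e["sex_ratio"],
                "provenance": prov,
            }
        )
    return pd.DataFrame(rows, columns=["source", "target", "weight", "n_men", "n_women", "sex_ratio", "provenance"])


def write_graphml(G: nx.DiGraph, path: str | Path) -> None:
    """GraphML export (infinite sex ratios serialized as a large float is
    avoided by writing the string 'inf', which round-trips through float)."""
    H = G.copy()
    for _u, _v, e in H.edges(data=True):
        if e.get("sex_ratio") == float("inf"):
            e["sex_ratio"] = "inf"
    nx.write_graphml(H, str(path))
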