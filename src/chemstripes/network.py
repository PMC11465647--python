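"""Weighted chemical co-occurrence networks and centrality ranking.

Nodes are the CIDs of a chemical list (a suspect list such as a PFAS or
bisphenol inventory); an edge joins two CIDs whenever at least one patent
mentions both, weighted by the number of co-appearances. Networks can be
restricted to the patents of one region before projection. Chemicals are then
ranked by degree (or strength) centrality and by PageRank on the weighted
undirected graph, and the top-k extracted with a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .patent_core import PatentRecord
from .regional import DEFAULT_REGION_MAP, RegionMap

__all__ = [
    "CoocNetwork",
    "CentralityResult",
    "ConvergenceError",
    "build_network",
    "degree_centrality",
    "pagerank_centrality",
    "top_k",
    "write_edgelist_csv",
    "write_graphml",
    "centrality_to_csv",
    "plot_top_k",
]


class ConvergenceError(RuntimeError):
    """PageRank power iteration failed to reach tolerance within max_iter."""


@dataclass(frozen=True)
class CoocNetwork:
    """Weighted undirected co-occurrence graph over a CID list.

    All CIDs of the input list are nodes, including isolates, so list
    coverage stays visible; weights count shared patents.
    """

    graph: nx.Graph
    region: str = "all"
    n_patents: int = 0

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    def weight(self, a: int, b: int) -> int:
        data = self.graph.get_edge_data(a, b)
        return 0 if data is None else data["weight"]

    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


@dataclass(frozen=True)
class CentralityResult:
    """Scores of one centrality measure with the parameters that produced it."""

    measure: str  # "degree", "strength" or "pagerank"
    scores: Mapping[int, float]
    parameters: Mapping[str, object] = field(default_factory=dict)


def build_network(
    records: Iterable[PatentRecord],
    cid_list: Iterable[int],
    region: str | None = None,
    region_map: RegionMap = DEFAULT_REGION_MAP,
) -> CoocNetwork:
    """Project patent–CID incidence onto a weighted CID co-occurrence graph.

    Each record's CIDs are restricted to ``cid_list``; every unordered pair
    co-mentioned by one patent gains +1 weight. ``region`` (a region label)
    keeps only patents whose office maps to that region; a patent belongs to
    exactly one office, so no double counting can arise. Records are expected
    to be deduplicated already.
    """
    cids = set(cid_list)
    if not cids:
        raise ValueError("cid_list must be nonempty")
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(sorted(cids))
    n_used = 0
    for rec in records:
        if region is not None and region != "all":
            if region_map.region_of(rec.identifier.office) != region:
                continue
        members = sorted(cids & rec.cids)
        if not members:
            continue
        n_used += 1
        for a, b in combinations(members, 2):
            if g.has_edge(a, b):
                g[a][b]["weight"] += 1
            else:
                g.add_edge(a, b, weight=1)
    return CoocNetwork(graph=g, region=region or "all", n_patents=n_used)


def degree_centrality(net: CoocNetwork, weighted: bool = False) -> CentralityResult:
    """Degree (neighbor count) or strength (incident-weight sum) per node.

    Isolates score 0 in both variants.
    """
    if weighted:
        scores = {n: float(net.graph.degree(n, weight="weight")) for n in net.nodes}
        measure = "strength"
    else:
        scores = {n: float(net.graph.degree(n)) for n in net.nodes}
        measure = "degree"
    return CentralityResult(measure=measure, scores=scores,
                            parameters={"weighted": weighted})


def pagerank_centrality(
    net: CoocNetwork,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> CentralityResult:
    """Weighted PageRank on the undirected graph by sparse power iteration.

    Each edge acts as two directed arcs with transition probability
    proportional to its weight; isolated nodes are dangling and redistribute
    their mass uniformly. Iteration stops when the L1 change drops below
    ``tol``; scores are returned summing to exactly 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    nodes = net.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    w = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight",
                                 format="csr", dtype=float)
    strength = np.asarray(w.sum(axis=1)).ravel()
    dangling = strength == 0.0
    inv_strength = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, strength))
    wt = sp.csr_array(w.T)

    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        dangling_mass = x[dangling].sum()
        x_new = (1.0 - damping) / n + damping * (
            wt @ (x * inv_strength) + dangling_mass / n
        )
        residual = np.abs(x_new - x).sum()
        x = x_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} iterations "
            f"(L1 residual {residual:.3e} > tol {tol:.1e})"
        )
    x = x / x.sum()
    return CentralityResult(
        measure="pagerank",
        scores={node: float(s) for node, s in zip(nodes, x)},
        parameters={"damping": damping, "tol": tol, "max_iter": max_iter},
    )


def top_k(result: CentralityResult, k: int = 25) -> list[tuple[int, float]]:
    """Top-k nodes by score, descending; ties broken by ascending CID."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(result.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def write_edgelist_csv(net: CoocNetwork, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"cid_a": min(a, b), "cid_b": max(a, b), "weight": d["weight"]}
        for a, b, d in net.graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["cid_a", "cid_b", "weight"])
    df.sort_values(["cid_a", "cid_b"], kind="stable").to_csv(path, index=False)
    return path


def write_graphml(net: CoocNetwork, path: str | Path) -> Path:
    path = Path(path)
    nx.write_graphml(net.graph, path)
    return path


def centrality_to_csv(result: CentralityResult, path: str | Path) -> Path:
    path = Path(path)
    ranked = top_k(result, k=max(1, len(result.scores)))
    pd.DataFrame(ranked, columns=["cid", result.measure]).to_csv(path, index=False)
    return path


def plot_top_k(result: CentralityResult, path: str | Path, k: int = 25,
               title: str = "") -> Path:
    """Horizontal bar plot of the top-k centrality scores."""
    path = Path(path)
    ranked = top_k(result, k)
    labels = [str(cid) for cid, _ in ranked][::-1]
    values = [score for _, score in ranked][::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(ranked))), dpi=100)
    ax.barh(labels, values, color="#2c7bb6")
    ax.set_xlabel(result.measure)
    ax.set_ylabel("CID")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, metadata={"Software": "chemstripes"})
    plt.close(fig)
    return path
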