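"""Seeded PPI subnetwork construction, hub-gene identification, seed-hub
enrichment, and random-walk community detection.

Candidate causal genes seed a first-order subnetwork (seeds plus direct
neighbors, plus all edges among included nodes) of a tissue-filtered PPI
edge list.  Hub genes are nodes at or above the 90th-percentile degree;
seed-hub enrichment uses the exact hypergeometric upper tail.
Communities come from Walktrap (short random walks + agglomeration, cut
at maximal modularity) with a per-community hypergeometric seed
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("loop2target.netprior")


@dataclass
class SeededNetwork:
    """A first-order seeded subnetwork of the PPI."""

    graph: nx.Graph
    seeds: set
    provenance: dict = field(default_factory=dict)  # node -> "seed"|"neighbor"

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    def degree(self, node) -> int:
        return self.graph.degree(node)


def extract_subnetwork(ppi_edges: pd.DataFrame, seeds: list[str]) -> SeededNetwork:
    """Seeds plus all direct PPI neighbors, with all edges among them.

    Seeds absent from the PPI are retained as isolated nodes (logged);
    if no seed is present in the PPI at all, that is an error.
    """
    if not seeds:
        raise ValueError("seeds must be non-empty")
    full = nx.Graph()
    full.add_edges_from(
        (a, b) for a, b in zip(ppi_edges.iloc[:, 0], ppi_edges.iloc[:, 1]) if a != b
    )
    seed_set = set(seeds)
    present = seed_set & set(full.nodes)
    if not present:
        raise ValueError("no seed gene is present in the PPI")
    absent = seed_set - present
    for s in sorted(absent):
        logger.info("seed %s absent from PPI; retained as isolated node", s)
    nodes = set(seed_set)
    provenance = {s: "seed" for s in seed_set}
    for s in present:
        for nb in full.neighbors(s):
            if nb not in nodes:
                nodes.add(nb)
                provenance[nb] = "neighbor"
    sub = nx.Graph()
    sub.add_nodes_from(nodes)
    sub.add_edges_from(
        (a, b) for a, b in full.subgraph(nodes).edges()
    )
    return SeededNetwork(graph=sub, seeds=seed_set, provenance=provenance)


def _nearest_rank_threshold(degrees: np.ndarray, percentile: float) -> float:
    srt = np.sort(degrees)
    rank = min(max(int(np.ceil(percentile / 100.0 * len(srt))), 1), len(srt))
    return float(srt[rank - 1])


def hub_nodes(network: SeededNetwork | nx.Graph, percentile: float = 90) -> set:
    """Nodes with degree >= the nearest-rank percentile (ties included)."""
    g = network.graph if isinstance(network, SeededNetwork) else network
    if g.number_of_nodes() < 10:
        raise ValueError("hub calling requires >= 10 nodes")
    degs = dict(g.degree())
    thr = _nearest_rank_threshold(np.array(list(degs.values())), percentile)
    return {n for n, d in degs.items() if d >= thr}


def seed_hub_enrichment(
    network: SeededNetwork, seeds: set, hubs: set
) -> tuple[float, float]:
    """Hypergeometric upper-tail enrichment of seeds among hub nodes.

    Drawing |seeds| nodes from the network with |hubs| marked, the
    overlap |seeds & hubs| is tested; fold = observed / expected.
    """
    nodes = network.nodes
    if not hubs <= nodes:
        raise ValueError("hubs must be a subset of network nodes")
    n_total = len(nodes)
    n_hub = len(hubs)
    n_seed = len(seeds & nodes)
    obs = len(seeds & hubs)
    expected = n_seed * n_hub / n_total
    fold = obs / expected if expected > 0 else float("nan")
    if obs == 0:
        pval = 1.0
    else:
        pval = float(stats.hypergeom.sf(obs - 1, n_total, n_hub, n_seed))
    return float(fold), pval


@dataclass
class CommunityPartition:
    """A node partition with per-community seed-enrichment statistics."""

    membership: dict
    communities: pd.DataFrame  # community, size, seed_count, seed_enrichment_p
    modularity: float


def random_walk_communities(
    network: SeededNetwork | nx.Graph,
    walk_length: int = 4,
    seed: int = 0,
    seeds: set | None = None,
) -> CommunityPartition:
    """Walktrap communities with per-community hypergeometric seed enrichment.

    Short random walks of ``walk_length`` steps define node similarity;
    communities are agglomerated and the dendrogram is cut at maximal
    modularity.  Connected components are handled independently by the
    algorithm; the partition covers every node exactly once.
    """
    g = network.graph if isinstance(network, SeededNetwork) else network
    if seeds is None:
        seeds = network.seeds if isinstance(network, SeededNetwork) else set()
    nodes = list(g.nodes)
    if not nodes:
        raise ValueError("empty graph")
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in g.edges()]
    igr = ig.Graph(n=len(nodes), edges=edges)
    if igr.ecount() == 0:
        labels = list(range(len(nodes)))
    else:
        dendro = igr.community_walktrap(steps=walk_length)
        clustering = dendro.as_clustering()
        labels = clustering.membership
    membership = {n: int(c) for n, c in zip(nodes, labels)}
    mod = (
        igr.modularity(labels) if igr.ecount() else 0.0
    )
    n_total = len(nodes)
    n_seed = len(seeds & set(nodes))
    rows = []
    for cid in sorted(set(labels)):
        members = [n for n in nodes if membership[n] == cid]
        k_seed = len(set(members) & seeds)
        if n_seed and k_seed:
            p = float(stats.hypergeom.sf(k_seed - 1, n_total, n_seed, len(members)))
        else:
            p = 1.0
        rows.append(
            {
                "community": cid,
                "size": len(members),
                "seed_count": k_seed,
                "seed_enrichment_p": p,
            }
        )
    return CommunityPartition(
        membership=membership,
        communities=pd.DataFrame(rows),
        modularity=float(mod),
    )
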