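"""Overlapping density clustering of the similarity network (DPClusO-style).

Clusters are grown greedily from high-degree seeds under two constraints:

* density ``d_k = |E_k| / (|N_k| (|N_k| - 1) / 2)`` must stay at or above
  ``d_in`` (default 0.7), where ``|E_k|`` counts edges internal to the
  cluster;
* a candidate node n joins only if its cluster property
  ``cp_nk = |E_nk| / (d_k * |N_k|)`` is at least ``cp_in`` (default 0.5),
  with ``|E_nk|`` the number of edges between n and current cluster members.

In overlapping mode, nodes of an emitted cluster are excluded from future
seeding but stay in the graph and may be absorbed into later clusters — that
is what produces overlaps.  The procedure is fully deterministic: ties in
seed and candidate selection break by degree and then lexicographic node ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Union

import networkx as nx
import pandas as pd

from .similarity import SimilarityNetwork

logger = logging.getLogger(__name__)

GraphLike = Union[SimilarityNetwork, nx.Graph]


@dataclass(frozen=True)
class MetaboliteCluster:
    """One emitted cluster: node set, internal edge count and density."""

    cluster_id: int
    nodes: frozenset[str]
    n_edges: int

    @property
    def density(self) -> float:
        return density(len(self.nodes), self.n_edges)


@dataclass(frozen=True)
class CandidateScore:
    """Attachment score of a candidate node against the current cluster."""

    node: str
    e_nk: int
    cp_nk: float


@dataclass(frozen=True)
class ClusteringParams:
    """Growth thresholds; defaults are the overlapping-mode setting
    cp_in = 0.5, d_in = 0.7, minimum cluster size 2."""

    cp_in: float = 0.5
    d_in: float = 0.7
    min_cluster_size: int = 2
    overlap_mode: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.d_in <= 1.0:
            raise ValueError("d_in must lie in (0, 1]")
        if self.cp_in <= 0.0:
            raise ValueError("cp_in must be positive")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")


def _max_edges(n: int) -> int:
    return n * (n - 1) // 2


def density(n_nodes: int, n_edges: int) -> float:
    """Cluster density d_k = |E_k| / |E_k|max with |E_k|max = n(n-1)/2."""
    if n_nodes < 2:
        raise ValueError("density is undefined for clusters of fewer than 2 nodes")
    return n_edges / _max_edges(n_nodes)


def cluster_property(
    graph: nx.Graph, node: str, members: Iterable[str], n_edges: int
) -> CandidateScore:
    """Score node n against a cluster: cp_nk = |E_nk| / (d_k * |N_k|)."""
    members = set(members)
    d_k = density(len(members), n_edges)
    if d_k == 0.0:
        raise ValueError("cluster_property is undefined against an edgeless cluster")
    e_nk = sum(1 for m in members if graph.has_edge(node, m))
    return CandidateScore(node=node, e_nk=e_nk, cp_nk=e_nk / (d_k * len(members)))


def _as_graph(net: GraphLike) -> nx.Graph:
    return net.to_graph() if isinstance(net, SimilarityNetwork) else net


def dpcluso_cluster(
    net: GraphLike, params: ClusteringParams | None = None
) -> tuple[list[MetaboliteCluster], list[str]]:
    """Run the overlapping density clustering over a similarity network.

    Returns the emitted clusters (IDs numbered from 1 in emission order) and
    the sorted list of nodes belonging to no cluster (single nodes).

    Procedure: repeatedly seed from the unclustered node of highest degree
    (ties: smallest ID); bootstrap a 2-node cluster with the seed's
    highest-degree neighbour; then repeatedly admit the best candidate —
    neighbours of the cluster ranked by descending |E_nk|, then degree, then
    ID — whose cp_nk >= cp_in and whose admission keeps density >= d_in.
    Growth stops when no candidate qualifies; the cluster is emitted if it
    reached min_cluster_size.
    """
    params = params or ClusteringParams()
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("dpcluso_cluster: empty network")

    work = g.copy()
    clustered: set[str] = set()
    clusters: list[MetaboliteCluster] = []

    while True:
        seeds = [n for n in work.nodes if n not in clustered and work.degree(n) > 0]
        if not seeds:
            break
        seed = min(seeds, key=lambda n: (-work.degree(n), n))
        first = min(work.neighbors(seed), key=lambda n: (-work.degree(n), n))
        members = {seed, first}
        n_edges = 1  # bootstrap pair is connected by construction

        while True:
            frontier = sorted(
                {nb for m in members for nb in work.neighbors(m)} - members
            )
            if not frontier:
                break
            d_k = density(len(members), n_edges)
            best = None
            for cand in frontier:
                e_nk = sum(1 for m in members if work.has_edge(cand, m))
                cp = e_nk / (d_k * len(members))
                new_d = (n_edges + e_nk) / _max_edges(len(members) + 1)
                if cp >= params.cp_in and new_d >= params.d_in:
                    key = (-e_nk, -work.degree(cand), cand)
                    if best is None or key < best[0]:
                        best = (key, cand, e_nk)
            if best is None:
                break
            members.add(best[1])
            n_edges += best[2]

        if len(members) >= params.min_cluster_size:
            clusters.append(
                MetaboliteCluster(len(clusters) + 1, frozenset(members), n_edges)
            )
            clustered |= members
            if not params.overlap_mode:
                work.remove_nodes_from(members)
        else:
            # growth stalled below the size floor: retire the seed as a single node
            clustered.add(seed)

    in_clusters = set().union(*(c.nodes for c in clusters)) if clusters else set()
    singletons = sorted(set(g.nodes) - in_clusters)
    logger.info(
        "dpcluso: %d clusters, %d single nodes (of %d; overlap=%s, cp>=%g, d>=%g)",
        len(clusters), len(singletons), g.number_of_nodes(),
        params.overlap_mode, params.cp_in, params.d_in,
    )
    return clusters, singletons


def overlap_graph(clusters: list[MetaboliteCluster]) -> pd.DataFrame:
    """Table of cluster pairs sharing at least one compound.

    Columns: cluster_i, cluster_j (i < j), n_shared, shared_compound_ids
    (semicolon-joined, sorted).  Disjoint clusterings give an empty table.
    """
    rows = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            shared = clusters[i].nodes & clusters[j].nodes
            if shared:
                rows.append(
                    (
                        clusters[i].cluster_id,
                        clusters[j].cluster_id,
                        len(shared),
                        ";".join(sorted(shared)),
                    )
                )
    return pd.DataFrame(
        rows, columns=["cluster_i", "cluster_j", "n_shared", "shared_compound_ids"]
    )


def verify_clusters(
    net: GraphLike, clusters: list[MetaboliteCluster], params: ClusteringParams
) -> None:
    """Recompute every cluster's edge count and density from the input graph
    and assert the emission contract (d_k >= d_in, size >= min_cluster_size).

    Independent of the growth procedure; raises AssertionError on violation.
    """
    g = _as_graph(net)
    for c in clusters:
        n_edges = sum(
            1 for a, b in g.edges if a in c.nodes and b in c.nodes
        )
        assert n_edges == c.n_edges, (
            f"cluster {c.cluster_id}: stored |E_k|={c.n_edges}, recount {n_edges}"
        )
        assert len(c.nodes) >= params.min_cluster_size
        assert density(len(c.nodes), n_edges) >= params.d_in
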