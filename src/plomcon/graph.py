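"""Covariation-network analysis: building the protein network,
overlapping clustering, dense-cluster extraction, and the two-condition
difference report.

Clustering follows the Overlapping Cluster Generator (OCG) idea: seed
an overlapping class system (maximal cliques by default, edges as
fallback), then greedily fuse the pair of classes whose fusion gives
the largest modularity gain, stopping when no fusion increases
modularity.  Nodes may end up in several clusters, which is what lets
one protein participate in two signalling modules at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import PlomconError
from .model import EDGE_EPS, BlockAdjacency


@dataclass
class CovariationNetwork:
    """Protein-level covariation network.

    Undirected, no self-loops; each edge is annotated with the partial
    correlation attaining the block maximum and its compartment pair.
    """

    graph: nx.Graph
    rho: float | None = None
    condition: str | None = None

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges}

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (
                min(a, b),
                max(a, b),
                d.get("weight", np.nan),
                d.get("compartment_a", ""),
                d.get("compartment_b", ""),
            )
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "weight", "compartment_a", "compartment_b"]
        ).sort_values(["protein_a", "protein_b"], ignore_index=True)


def build_network(
    adjacency: BlockAdjacency, rho: float | None = None, condition: str | None = None
) -> CovariationNetwork:
    """One edge per nonzero protein-pair entry of the block adjacency."""
    G = nx.Graph()
    G.add_nodes_from(adjacency.proteins)
    M = len(adjacency.proteins)
    for i in range(M):
        for j in range(i + 1, M):
            w = adjacency.A[i, j]
            if abs(w) > EDGE_EPS:
                pa, pb = adjacency.proteins[i], adjacency.proteins[j]
                ca, cb = adjacency.argmax_compartments.get((pa, pb), ("", ""))
                G.add_edge(pa, pb, weight=float(w), compartment_a=ca, compartment_b=cb)
    return CovariationNetwork(graph=G, rho=rho, condition=condition)


def mean_degree(network: CovariationNetwork | nx.Graph, nodes: Iterable[str] | None = None) -> float:
    """2|E|/|V| of the whole network, or of the subgraph induced by
    ``nodes`` (within-cluster edges only)."""
    G = network.graph if isinstance(network, CovariationNetwork) else network
    if nodes is None:
        n = G.number_of_nodes()
        if n == 0:
            raise ValueError("empty node set")
        return 2.0 * G.number_of_edges() / n
    nodes = list(nodes)
    if not nodes:
        raise ValueError("empty node set")
    sub = G.subgraph(nodes)
    return 2.0 * sub.number_of_edges() / len(nodes)


@dataclass
class ClusterSet:
    """Overlapping node clusters with modularity diagnostics."""

    clusters: tuple[frozenset, ...]
    modularity: float
    per_cluster_mean_degree: tuple[float, ...]
    network_mean_degree: float
    modularity_trace: tuple[float, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.clusters)


def _cluster_contribution(G: nx.Graph, nodes: frozenset, two_m: float) -> float:
    """Contribution of one cluster to overlapping modularity:
    (1/2m) * sum_{i != j in C} (A_ij - k_i k_j / 2m)."""
    nodes_l = list(nodes)
    deg = dict(G.degree())
    internal = G.subgraph(nodes_l).number_of_edges()
    ksum = sum(deg[v] for v in nodes_l)
    ksq = sum(deg[v] ** 2 for v in nodes_l)
    # sum_{i != j} k_i k_j = (sum k)^2 - sum k^2
    return (2.0 * internal - (ksum * ksum - ksq) / two_m) / two_m


def ocg_cluster(
    network: CovariationNetwork | nx.Graph,
    init: Literal["cliques", "edges"] = "cliques",
    clique_budget: int = 100_000,
    min_cluster_size: int = 2,
) -> ClusterSet:
    """Overlapping clustering by greedy modularity-maximizing fusion.

    Seeds are maximal cliques (falling back to edges when clique
    enumeration exceeds ``clique_budget``) on the unweighted topology.
    At each step the fusion with the largest modularity gain is applied
    (ties break to the lexicographically smallest cluster pair); a
    cluster swallowed by a fusion is absorbed and its contribution
    removed, so the recorded modularity trace is exact and
    nondecreasing.  Stops when no fusion increases modularity.
    """
    G = network.graph if isinstance(network, CovariationNetwork) else network
    m = G.number_of_edges()
    if m == 0:
        raise PlomconError("cannot cluster an edgeless network")
    two_m = 2.0 * m

    if init == "cliques":
        seeds: list[frozenset] = []
        for i, clique in enumerate(nx.find_cliques(G)):
            if i >= clique_budget:
                seeds = None
                break
            if len(clique) >= min_cluster_size:
                seeds.append(frozenset(clique))
        if seeds is None:
            seeds = [frozenset(e) for e in G.edges]
    elif init == "edges":
        seeds = [frozenset(e) for e in G.edges]
    else:
        raise ValueError("init must be 'cliques' or 'edges'")

    def cid(c: frozenset) -> tuple:
        return tuple(sorted(c))

    clusters = sorted(set(seeds), key=cid)
    contrib = {cid(c): _cluster_contribution(G, c, two_m) for c in clusters}
    trace = [sum(contrib.values())]

    while len(clusters) > 1:
        best = None  # (gain, pair_id, i, j, union, absorbed indices)
        for i, j in itertools.combinations(range(len(clusters)), 2):
            union = clusters[i] | clusters[j]
            q_union = _cluster_contribution(G, union, two_m)
            absorbed = [
                k
                for k in range(len(clusters))
                if k not in (i, j) and clusters[k] <= union
            ]
            gain = (
                q_union
                - contrib[cid(clusters[i])]
                - contrib[cid(clusters[j])]
                - sum(contrib[cid(clusters[k])] for k in absorbed)
            )
            pair_id = tuple(sorted((cid(clusters[i]), cid(clusters[j]))))
            if best is None or gain > best[0] + 1e-12 or (
                abs(gain - best[0]) <= 1e-12 and pair_id < best[1]
            ):
                best = (gain, pair_id, i, j, union, absorbed)
        if best is None or best[0] <= 1e-12:
            break
        gain, _, i, j, union, absorbed = best
        drop = {i, j, *absorbed}
        clusters = [c for k, c in enumerate(clusters) if k not in drop]
        if union not in clusters:
            clusters.append(union)
        clusters.sort(key=cid)
        contrib = {cid(c): _cluster_contribution(G, c, two_m) for c in clusters}
        trace.append(sum(contrib.values()))

    net_md = mean_degree(G)
    per_md = tuple(mean_degree(G, c) for c in clusters)
    return ClusterSet(
        clusters=tuple(clusters),
        modularity=trace[-1],
        per_cluster_mean_degree=per_md,
        network_mean_degree=net_md,
        modularity_trace=tuple(trace),
    )


def extract_dense_clusters(
    clusters: ClusterSet, network: CovariationNetwork | nx.Graph
) -> ClusterSet:
    """Keep clusters whose within-cluster mean degree strictly exceeds
    the mean degree of the whole network."""
    G = network.graph if isinstance(network, CovariationNetwork) else network
    net_md = mean_degree(G)
    kept = [
        (c, md)
        for c, md in zip(clusters.clusters, clusters.per_cluster_mean_degree)
        if md > net_md
    ]
    return ClusterSet(
        clusters=tuple(c for c, _ in kept),
        modularity=clusters.modularity,
        per_cluster_mean_degree=tuple(md for _, md in kept),
        network_mean_degree=net_md,
        modularity_trace=clusters.modularity_trace,
    )


@dataclass
class NetworkDifference:
    """Partition of protein-pair edges between two conditions."""

    lost: set[tuple[str, str]]
    gained: set[tuple[str, str]]
    retained: set[tuple[str, str]]
    multiplicity: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for status, pairs in (("lost", self.lost), ("gained", self.gained),
                              ("retained", self.retained)):
            for pair in sorted(pairs):
                mult = self.multiplicity.get(pair, {})
                rows.append((pair[0], pair[1], status,
                             mult.get("control", 1 if status != "gained" else 0),
                             mult.get("treated", 1 if status != "lost" else 0)))
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "status", "n_control", "n_treated"]
        )


def compare_networks(
    net_control: CovariationNetwork, net_treated: CovariationNetwork
) -> NetworkDifference:
    """Partition edges into lost (control only), gained (treated only)
    and retained.  Node universes must match."""
    if set(net_control.graph.nodes) != set(net_treated.graph.nodes):
        raise PlomconError("node universes differ between the two networks")
    e_ctrl = net_control.edges
    e_trt = net_treated.edges
    return NetworkDifference(
        lost=e_ctrl - e_trt, gained=e_trt - e_ctrl, retained=e_ctrl & e_trt
    )


def compare_network_grids(
    control: dict[float, CovariationNetwork], treated: dict[float, CovariationNetwork]
) -> NetworkDifference:
    """Compare two per-rho network families at the protein-pair level.

    A pair is *lost* when it has at least one edge in some control
    network and none in any treated network (and symmetrically for
    *gained*); pairs with edges on both sides are *retained*.  The
    multiplicity record counts, per pair, the number of (rho, edge)
    occurrences on each side.
    """
    if set(control) != set(treated):
        raise PlomconError("control and treated grids use different rho values")
    count_ctrl: dict[tuple[str, str], int] = {}
    count_trt: dict[tuple[str, str], int] = {}
    for nets, counts in ((control, count_ctrl), (treated, count_trt)):
        for net in nets.values():
            for pair in net.edges:
                counts[pair] = counts.get(pair, 0) + 1
    pairs = set(count_ctrl) | set(count_trt)
    lost = {p for p in pairs if p in count_ctrl and p not in count_trt}
    gained = {p for p in pairs if p in count_trt and p not in count_ctrl}
    retained = pairs - lost - gained
    multiplicity = {
        p: {"control": count_ctrl.get(p, 0), "treated": count_trt.get(p, 0)} for p in pairs
    }
    return NetworkDifference(lost=lost, gained=gained, retained=retained,
                             multiplicity=multiplicity)
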