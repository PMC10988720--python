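"""File-format helpers: TIFF stacks, label maps, matrices, GraphML,
edge lists, clusters and difference reports."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .datatypes import SceneGroundTruth
from .graph import ClusterSet, CovariationNetwork, NetworkDifference


def write_zstack(path, stack: np.ndarray) -> None:
    """Multi-page TIFF, one page per z-plane."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_zstack(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_label_map(path, labels: np.ndarray) -> None:
    """16-bit TIFF label image."""
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint16))


def read_label_map(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def write_ground_truth(path, truth: SceneGroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2))


def write_matrix_csv(path, M: np.ndarray, feature_index) -> None:
    """Square matrix CSV with 'protein|compartment' headers."""
    names = [f"{p}|{c}" for p, c in feature_index]
    pd.DataFrame(M, index=names, columns=names).to_csv(path)


def read_matrix_csv(path) -> tuple[np.ndarray, list[tuple[str, str]]]:
    df = pd.read_csv(path, index_col=0)
    features = [tuple(name.split("|", 1)) for name in df.index]
    return df.to_numpy(dtype=float), features


def write_network_graphml(path, network: CovariationNetwork) -> None:
    G = network.graph.copy()
    G.graph["rho"] = -1.0 if network.rho is None else float(network.rho)
    G.graph["condition"] = network.condition or ""
    nx.write_graphml(G, str(path))


def read_network_graphml(path) -> CovariationNetwork:
    G = nx.read_graphml(str(path))
    rho = G.graph.get("rho")
    return CovariationNetwork(
        graph=G, rho=None if rho in (None, -1.0) else float(rho),
        condition=G.graph.get("condition") or None,
    )


def write_edge_list(path, network: CovariationNetwork) -> None:
    network.edges_frame().to_csv(path, index=False)


def write_clusters_json(path, clusters: ClusterSet) -> None:
    payload = {
        "clusters": [sorted(c) for c in clusters.clusters],
        "modularity": clusters.modularity,
        "per_cluster_mean_degree": list(clusters.per_cluster_mean_degree),
        "network_mean_degree": clusters.network_mean_degree,
        "modularity_trace": list(clusters.modularity_trace),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_difference_csv(path, diff: NetworkDifference) -> None:
    diff.to_frame().to_csv(path, index=False)
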