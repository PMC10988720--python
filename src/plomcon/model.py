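"""Covariation-network model: a statsmodels-style Model/Results pair.

``CovariationModel`` wraps a :class:`~plomcon.datatypes.FeatureTable`
(median feature quantities over a time course); ``fit(rho)`` estimates
the sparse precision matrix by graphical lasso, converts it to partial
correlations, reduces the feature-level matrix to a protein-level
adjacency by blockwise extraction, and returns a
``CovariationResults`` carrying the estimates, diagnostics, a
``summary()`` table, clustering and network comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import FeatureId, FeatureTable, PlomconError
from .glasso import CovarianceModel, graphical_lasso, partial_correlation

#: entries of the sparse estimate below this magnitude are numerical zero
EDGE_EPS = 1e-8


def compute_covariance(
    table: FeatureTable, standardize: bool = True, on_drop: Literal["warn", "raise"] = "warn"
) -> tuple[np.ndarray, tuple[FeatureId, ...]]:
    """Sample covariance of the feature trajectories over time.

    With ``standardize`` (the default) each feature is z-scored over the
    time axis first, so S is the correlation matrix — fluorescence units
    are arbitrary and per-antibody scale would otherwise dominate.
    Zero-variance features are degenerate under standardization and are
    dropped with a warning.  Returns (S, kept features).
    """
    if table.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a covariance estimate")
    X = table.values.astype(float)
    features = table.features
    if standardize:
        sd = X.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            dropped = [features[i] for i in np.flatnonzero(~keep)]
            msg = f"dropping {len(dropped)} zero-variance feature(s): {dropped}"
            if on_drop == "raise":
                raise PlomconError(msg)
            warnings.warn(msg, stacklevel=2)
            X = X[keep]
            features = tuple(f for f, k in zip(features, keep) if k)
        X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
    S = np.cov(X, ddof=1)
    S = np.atleast_2d(S)
    S = 0.5 * (S + S.T)
    return S, features


@dataclass
class BlockAdjacency:
    """Protein-level adjacency from blockwise reduction of P.

    ``A[i, j]`` holds the extreme partial correlation over the block of
    (protein_i, protein_j) feature pairs; ``argmax_compartments`` maps
    each nonzero protein pair to the compartment pair attaining it.
    """

    proteins: tuple[str, ...]
    A: np.ndarray
    argmax_compartments: dict[tuple[str, str], tuple[str, str]]
    feature_index: tuple[FeatureId, ...]


def blockwise_adjacency(
    P: np.ndarray,
    feature_index: Sequence[FeatureId],
    mode: Literal["absolute", "signed"] = "absolute",
) -> BlockAdjacency:
    """Reduce a feature-level partial-correlation matrix to proteins.

    The K x K matrix is partitioned into blocks by protein; for each
    between-protein block the extreme entry is extracted — by default
    the entry of largest absolute value with its sign retained
    (``mode="signed"`` takes the largest signed value instead).  Ties
    break to the lexicographically smallest (compartment_i,
    compartment_j) pair.  Entries with |P| <= 1e-8 count as zero;
    all-zero blocks yield A_ij = 0 with no annotation.
    """
    P = np.asarray(P, dtype=float)
    feature_index = tuple((str(p), str(c)) for p, c in feature_index)
    if P.shape[0] != len(feature_index):
        raise ValueError("feature_index must cover every row of P")
    proteins: list[str] = []
    for p, _ in feature_index:
        if p not in proteins:
            proteins.append(p)
    rows_of: dict[str, list[int]] = {p: [] for p in proteins}
    for k, (p, _) in enumerate(feature_index):
        rows_of[p].append(k)
    # scan each block in lexicographic compartment order so that strict
    # improvement implements the documented tie-break
    order_of = {
        p: sorted(rows_of[p], key=lambda k: feature_index[k][1]) for p in proteins
    }
    M = len(proteins)
    A = np.zeros((M, M))
    argmax: dict[tuple[str, str], tuple[str, str]] = {}
    for i in range(M):
        for j in range(i + 1, M):
            best_val = 0.0
            best_key = -np.inf
            best_pair: tuple[str, str] | None = None
            for r in order_of[proteins[i]]:
                for c in order_of[proteins[j]]:
                    v = P[r, c]
                    if abs(v) <= EDGE_EPS:
                        continue
                    key = abs(v) if mode == "absolute" else v
                    if key > best_key:
                        best_key = key
                        best_val = v
                        best_pair = (feature_index[r][1], feature_index[c][1])
            if best_pair is not None:
                A[i, j] = A[j, i] = best_val
                argmax[(proteins[i], proteins[j])] = best_pair
    return BlockAdjacency(
        proteins=tuple(proteins), A=A, argmax_compartments=argmax,
        feature_index=feature_index,
    )


class CovariationModel:
    """Penalized Gaussian graphical model of protein covariation.

    Parameters
    ----------
    table
        Median feature quantities (K features x T time points) of one
        condition.
    standardize
        Z-score each feature over time before the covariance (default
        on; the published penalty weights 0.9/0.95 live on the
        correlation scale).
    """

    def __init__(self, table: FeatureTable, standardize: bool = True):
        self.table = table
        self.standardize = standardize
        self.S, self.features = compute_covariance(table, standardize=standardize)
        self.K = len(self.features)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition: str | None = None,
                       standardize: bool = True) -> "CovariationModel":
        """Build from a tidy frame (protein, compartment, time_h, condition, value)."""
        return cls(FeatureTable.from_frame(df, condition=condition), standardize=standardize)

    @classmethod
    def from_csv(cls, path, condition: str | None = None,
                 standardize: bool = True) -> "CovariationModel":
        return cls(FeatureTable.from_csv(path, condition=condition), standardize=standardize)

    def fit(
        self,
        rho: float = 0.9,
        tol: float = 1e-5,
        max_iter: int = 200,
        penalize_diagonal: bool = True,
        block_mode: Literal["absolute", "signed"] = "absolute",
    ) -> "CovariationResults":
        """Estimate the covariation network at penalty weight ``rho``."""
        fitted = graphical_lasso(self.S, rho=rho, tol=tol, max_iter=max_iter,
                                 penalize_diagonal=penalize_diagonal)
        P = partial_correlation(fitted.precision)
        adjacency = blockwise_adjacency(P, self.features, mode=block_mode)
        return CovariationResults(self, fitted, P, adjacency)

    def fit_grid(self, rhos: Sequence[float] = (0.9, 0.95), **kwargs) -> dict:
        """Fit once per penalty weight; returns {rho: CovariationResults}."""
        return {float(r): self.fit(rho=float(r), **kwargs) for r in rhos}


class CovariationResults:
    """Estimates and diagnostics of one fitted covariation network."""

    def __init__(self, model: CovariationModel, fitted: CovarianceModel,
                 P: np.ndarray, adjacency: BlockAdjacency):
        self.model = model
        self._fitted = fitted
        self.rho = fitted.rho
        self.S = fitted.S
        self.precision = fitted.precision
        self.partial_corr = P
        self.adjacency = adjacency
        self.objective_trace = fitted.objective_trace
        self.n_iter = fitted.n_iter
        self.converged = fitted.converged

    @property
    def condition(self) -> str:
        return self.model.table.condition

    @property
    def network(self):
        from .graph import build_network

        return build_network(self.adjacency, rho=self.rho, condition=self.condition)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(np.abs(self.adjacency.A) > EDGE_EPS, k=1)))

    def edges_frame(self) -> pd.DataFrame:
        """Edge list: protein_a, protein_b, weight, compartment_a, compartment_b."""
        rows = []
        prot = self.adjacency.proteins
        for (pa, pb), (ca, cb) in self.adjacency.argmax_compartments.items():
            w = self.adjacency.A[prot.index(pa), prot.index(pb)]
            rows.append((pa, pb, float(w), ca, cb))
        return pd.DataFrame(
            rows, columns=["protein_a", "protein_b", "weight", "compartment_a", "compartment_b"]
        ).sort_values(["protein_a", "protein_b"], ignore_index=True)

    def cluster(self, **kwargs):
        """Overlapping clustering of the network (see :func:`plomcon.graph.ocg_cluster`)."""
        from .graph import ocg_cluster

        return ocg_cluster(self.network, **kwargs)

    def compare(self, other: "CovariationResults"):
        """Difference report against another condition's network."""
        from .graph import compare_networks

        return compare_networks(self.network, other.network)

    def plot_network(self, ax=None, seed: int = 0):
        """Spring-layout drawing of the covariation network."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        G = self.network.graph
        pos = nx.spring_layout(G, seed=seed)
        nx.draw_networkx(G, pos=pos, ax=ax, node_size=300, font_size=7)
        ax.set_title(f"{self.condition} covariation network (rho={self.rho})")
        ax.axis("off")
        return ax

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        t = self.model.table
        mean_deg = 2 * self.n_edges / max(len(self.adjacency.proteins), 1)
        lines = [
            "Covariation Network Results",
            "=" * 46,
            f"{'condition':<28}{self.condition:>18}",
            f"{'features (K)':<28}{self.model.K:>18d}",
            f"{'proteins (M)':<28}{len(self.adjacency.proteins):>18d}",
            f"{'time points (T)':<28}{t.n_timepoints:>18d}",
            f"{'penalty rho':<28}{self.rho:>18.4g}",
            f"{'standardized':<28}{str(self.model.standardize):>18}",
            f"{'sweeps to converge':<28}{self.n_iter:>18d}",
            f"{'penalized log-likelihood':<28}{self.objective_trace[-1]:>18.6g}",
            f"{'protein edges':<28}{self.n_edges:>18d}",
            f"{'network mean degree':<28}{mean_deg:>18.4g}",
            "=" * 46,
        ]
        ef = self.edges_frame()
        if len(ef):
            lines.append("strongest edges (|partial correlation|):")
            top = ef.reindex(ef["weight"].abs().sort_values(ascending=False).index).head(10)
            for _, r in top.iterrows():
                lines.append(
                    f"  {r.protein_a}[{r.compartment_a}] -- {r.protein_b}"
                    f"[{r.compartment_b}]  {r.weight:+.3f}"
                )
        return "\n".join(lines)
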