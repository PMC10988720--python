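"""Shared data containers for the covariation-network pipeline.

The central object is the :class:`FeatureTable`: per-condition median
feature quantities, one row per (protein, compartment) feature and one
column per time point.  Everything downstream (covariance, graphical
lasso, block adjacency) consumes this table; the imaging stage and the
synthetic generator both produce it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: subcellular compartments at which a feature quantity can be measured
COMPARTMENTS = (
    "nucleus",
    "nuclear_membrane",
    "cytoplasm",
    "plasma_membrane",
    "nucleus/cytoplasm",
)

FeatureId = tuple[str, str]  # (protein, compartment)


class PlomconError(Exception):
    """Base class for pipeline errors."""


@dataclass(frozen=True)
class FeatureTable:
    """Median feature quantities over a time course for one condition.

    Parameters
    ----------
    features
        Ordered (protein, compartment) identifiers, length K, no duplicates.
    values
        K x T array of per-timepoint medians (arbitrary fluorescence units,
        finite and nonnegative).
    time_grid
        T strictly increasing time points in hours.
    condition
        Condition label, e.g. ``"control"`` or ``"treated"``.
    """

    features: tuple[FeatureId, ...]
    values: np.ndarray
    time_grid: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple((str(p), str(c)) for p, c in self.features))
        values = np.asarray(self.values, dtype=float)
        time_grid = np.asarray(self.time_grid, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "time_grid", time_grid)
        if values.ndim != 2:
            raise ValueError("values must be a K x T matrix")
        if values.shape != (len(self.features), time_grid.size):
            raise ValueError(
                f"shape mismatch: {values.shape} vs {len(self.features)} features, "
                f"{time_grid.size} time points"
            )
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicated feature identifiers")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        if np.any(values < 0):
            raise ValueError("feature values must be nonnegative")
        if time_grid.size >= 2 and not np.all(np.diff(time_grid) > 0):
            raise ValueError("time_grid must be strictly increasing")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_timepoints(self) -> int:
        return int(self.time_grid.size)

    @property
    def proteins(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for p, _ in self.features:
            seen.setdefault(p, None)
        return tuple(seen)

    def subset(self, keep: Sequence[int]) -> "FeatureTable":
        keep = list(keep)
        return FeatureTable(
            features=tuple(self.features[i] for i in keep),
            values=self.values[keep, :],
            time_grid=self.time_grid,
            condition=self.condition,
        )

    # -- tidy-frame round trip -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: protein, compartment, time_h, condition, value."""
        rows = []
        for (protein, compartment), row in zip(self.features, self.values):
            for t, v in zip(self.time_grid, row):
                rows.append((protein, compartment, float(t), self.condition, float(v)))
        return pd.DataFrame(rows, columns=["protein", "compartment", "time_h", "condition", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str | None = None) -> "FeatureTable":
        if condition is not None:
            df = df[df["condition"] == condition]
        conditions = df["condition"].unique()
        if len(conditions) != 1:
            raise ValueError(f"expected exactly one condition, got {list(conditions)}")
        time_grid = np.array(sorted(df["time_h"].unique()), dtype=float)
        wide = df.pivot_table(
            index=["protein", "compartment"], columns="time_h", values="value", aggfunc="first"
        )
        wide = wide.reindex(columns=time_grid)
        if wide.isna().any().any():
            raise ValueError("incomplete table: some feature is missing at some time point")
        features = tuple((str(p), str(c)) for p, c in wide.index)
        return cls(features=features, values=wide.to_numpy(), time_grid=time_grid,
                   condition=str(conditions[0]))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition: str | None = None) -> "FeatureTable":
        return cls.from_frame(pd.read_csv(path), condition=condition)


@dataclass
class CompartmentLabelMap:
    """Per-field segmentation masks sharing cell label ids.

    ``cell_labels`` is the watershed cell segmentation (0 = background);
    nucleus, cytoplasm and the two membrane rings use the same integer id
    per cell.  Invariants (checked by :meth:`validate`): nucleus inside
    cell, cytoplasm = cell minus nucleus, plasma-membrane ring inside
    cell, one nucleus per cell.
    """

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    cytoplasm_labels: np.ndarray
    plasma_membrane_labels: np.ndarray
    nuclear_membrane_labels: np.ndarray
    ratio_feature: bool = True

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.cell_labels)
        return ids[ids > 0]

    def validate(self) -> None:
        cell = self.cell_labels
        for name, arr in (
            ("nucleus_labels", self.nucleus_labels),
            ("cytoplasm_labels", self.cytoplasm_labels),
            ("plasma_membrane_labels", self.plasma_membrane_labels),
            ("nuclear_membrane_labels", self.nuclear_membrane_labels),
        ):
            if arr.shape != cell.shape:
                raise ValueError(f"{name} shape mismatch")
        for cid in self.cell_ids:
            cmask = cell == cid
            nmask = self.nucleus_labels == cid
            ymask = self.cytoplasm_labels == cid
            pmask = self.plasma_membrane_labels == cid
            if not nmask.any():
                raise ValueError(f"cell {cid} has no nucleus")
            if np.any(nmask & ~cmask):
                raise ValueError(f"nucleus {cid} not contained in its cell")
            if np.any(ymask != (cmask & ~nmask)):
                raise ValueError(f"cytoplasm {cid} != cell minus nucleus")
            if np.any(pmask & ~cmask):
                raise ValueError(f"plasma-membrane ring {cid} not contained in its cell")


@dataclass(frozen=True)
class SceneGroundTruth:
    """Exact (by construction) geometry of a synthetic microscopy field."""

    cell_centers: tuple[tuple[float, float], ...]
    cell_radii: tuple[float, ...]
    nucleus_radii: tuple[float, ...]
    per_cell_compartment_intensities: Mapping[tuple[int, str], float]
    confluency: float
    seed: int
    cell_labels: np.ndarray = field(repr=False, default=None)
    nucleus_labels: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for rc, rn in zip(self.cell_radii, self.nucleus_radii):
            if not rn < rc:
                raise ValueError("nucleus radius must be smaller than cell radius")
        if not 0.0 <= self.confluency <= 1.0:
            raise ValueError("confluency must be a fraction in [0, 1]")
        for v in self.per_cell_compartment_intensities.values():
            if v < 0:
                raise ValueError("intensities must be nonnegative")

    def to_json_dict(self) -> dict:
        return {
            "cell_centers": [list(c) for c in self.cell_centers],
            "cell_radii": list(self.cell_radii),
            "nucleus_radii": list(self.nucleus_radii),
            "per_cell_compartment_intensities": {
                f"{cid}:{comp}": v
                for (cid, comp), v in self.per_cell_compartment_intensities.items()
            },
            "confluency": self.confluency,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class LatentFactor:
    """A latent trajectory driving covariation of its member features.

    ``condition=None`` means the factor is active in every condition;
    a condition label restricts it to that condition, which plants a
    condition-specific network edge among its members.
    """

    members: tuple[FeatureId, ...]
    loadings: tuple[float, ...]
    condition: str | None = None

    def __post_init__(self) -> None:
        if len(self.members) != len(self.loadings):
            raise ValueError("one loading per member feature")
        if len(self.members) < 2:
            raise ValueError("a factor needs at least two member features")


@dataclass(frozen=True)
class PlantedStructureSpec:
    """Design of a synthetic two-condition time-course feature table."""

    n_proteins: int
    compartments_per_protein: Mapping[str, tuple[str, ...]]
    latent_factors: tuple[LatentFactor, ...]
    noise_sd: float
    time_grid: np.ndarray
    baseline: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_grid", np.asarray(self.time_grid, dtype=float))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.time_grid.size >= 2 and not np.all(np.diff(self.time_grid) > 0):
            raise ValueError("time_grid must be strictly increasing")
        universe = set(self.feature_universe)
        for f in self.latent_factors:
            for m in f.members:
                if m not in universe:
                    raise ValueError(f"factor member {m} not in the feature universe")

    @property
    def feature_universe(self) -> tuple[FeatureId, ...]:
        return tuple(
            (protein, comp)
            for protein, comps in self.compartments_per_protein.items()
            for comp in comps
        )

    @property
    def condition_specific_edges(self) -> tuple[tuple[tuple[FeatureId, ...], str], ...]:
        return tuple(
            (f.members, f.condition) for f in self.latent_factors if f.condition is not None
        )


@dataclass
class ExpressionMatrix:
    """Nonnegative gene-expression signal matrix with group labels.

    ``values`` is genes x samples; ``groups`` assigns each sample to
    ``"control"`` or ``"treated"``; ``detected`` flags which entries carry
    a detected signal (all-detected by default).
    """

    genes: tuple[str, ...]
    samples: tuple[str, ...]
    values: np.ndarray
    groups: tuple[str, ...]
    detected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("values must be genes x samples")
        if len(self.groups) != len(self.samples):
            raise ValueError("one group label per sample")
        if np.any(self.values < 0):
            raise ValueError("signals must be nonnegative")
        if self.detected is None:
            self.detected = np.ones_like(self.values, dtype=bool)
        else:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != self.values.shape:
                raise ValueError("detected flags must match the value matrix")
        if not self.detected.any(axis=0).all():
            raise ValueError("every sample needs at least one detected gene")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.genes), columns=list(self.samples))
        df.index.name = "gene"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, groups: Iterable[str]) -> "ExpressionMatrix":
        return cls(
            genes=tuple(str(g) for g in df.index),
            samples=tuple(str(s) for s in df.columns),
            values=df.to_numpy(dtype=float),
            groups=tuple(groups),
        )
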