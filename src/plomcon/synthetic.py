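"""Ground-truthed synthetic data: microscopy scenes, two-condition
time-course feature tables with planted covariation, and expression
matrices.

The generator emulates the study design the pipeline targets: ~36
proteins measured at up to five subcellular compartments over a 9-point
time course (0.5-8 h) under a control and a treated condition, with
covariation driven by smooth latent-factor trajectories and
fluorescence-like nonnegative noise.  Condition-specific factors plant
edges that exist in one condition only, giving downstream network
differencing a known answer.

All randomness flows from the explicit ``seed`` argument of each
function; regenerating with the same seed is bit-identical.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .datatypes import (
    COMPARTMENTS,
    ExpressionMatrix,
    FeatureId,
    FeatureTable,
    LatentFactor,
    PlantedStructureSpec,
    PlomconError,
    SceneGroundTruth,
)

CONDITIONS = ("control", "treated")


class InfeasibleSceneError(PlomconError):
    """Requested cell density cannot satisfy the minimum separation."""


#: default per-channel compartment intensity profiles (arbitrary units):
#: bright nuclear marker inside nuclei, cytoplasmic marker over the whole
#: cell, and a generic protein stain measurable in both compartments.
DEFAULT_CHANNEL_SPECS: Mapping[str, Mapping[str, float]] = {
    "nuclear_marker": {"nucleus": 220.0, "cytoplasm": 15.0},
    "cyto_marker": {"nucleus": 60.0, "cytoplasm": 140.0},
}


def _place_centers(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    radius: float,
    min_separation: float,
    max_tries: int,
) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    margin = radius + 1.0
    tries = 0
    while len(centers) < n_cells:
        if tries >= max_tries:
            raise InfeasibleSceneError(
                f"could not place {n_cells} cells with separation "
                f"{min_separation:.1f} px in {shape} after {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_separation**2 for rr, cc in centers):
            centers.append((r, c))
    return centers


def generate_scene(
    n_cells: int,
    image_shape: tuple[int, int] = (256, 256),
    channel_specs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    *,
    n_planes: int = 3,
    cell_radius: float = 14.0,
    nucleus_radius: float = 6.0,
    min_separation: float | None = None,
    blur_sigma: float = 2.0,
    background: float = 3.0,
    max_tries: int = 20_000,
) -> tuple[dict[str, np.ndarray], SceneGroundTruth]:
    """Render a multi-channel z-stack field of disk-shaped cells.

    Cells are flat disks (nucleus disk inside a larger cell disk) spread
    over ``n_planes`` z-planes with plane-dependent attenuation, blurred
    with a Gaussian (sigma ``blur_sigma``) and corrupted with Poisson
    noise, so that thresholding, projection and watershed all have work
    to do.  Ground-truth label masks are recorded by construction.

    Returns a dict channel name -> (n_planes, H, W) float stack, plus the
    :class:`SceneGroundTruth` (confluency computed by pixel counting).
    """
    if n_cells < 0:
        raise ValueError("n_cells must be nonnegative")
    if image_shape[0] <= 0 or image_shape[1] <= 0:
        raise ValueError("image_shape must be positive")
    if not nucleus_radius < cell_radius:
        raise ValueError("nucleus_radius must be smaller than cell_radius")
    if channel_specs is None:
        channel_specs = DEFAULT_CHANNEL_SPECS
    if min_separation is None:
        min_separation = 2.0 * cell_radius + 4.0

    rng = np.random.default_rng(seed)
    centers = _place_centers(rng, n_cells, image_shape, cell_radius, min_separation, max_tries)

    rr, cc = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
    cell_labels = np.zeros(image_shape, dtype=np.int32)
    nucleus_labels = np.zeros(image_shape, dtype=np.int32)
    for i, (r0, c0) in enumerate(centers, start=1):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        cell_labels[d2 <= cell_radius**2] = i
        nucleus_labels[d2 <= nucleus_radius**2] = i

    confluency = float((cell_labels > 0).mean())

    intensities: dict[tuple[int, str], float] = {}
    stacks: dict[str, np.ndarray] = {}
    # plane weights: one in-focus plane at full weight, neighbours attenuated
    weights = np.array([math.exp(-0.5 * ((p - (n_planes - 1) / 2) / 1.0) ** 2) for p in range(n_planes)])
    weights /= weights.max()
    for channel, profile in channel_specs.items():
        base = np.full(image_shape, background, dtype=float)
        for i in range(1, n_cells + 1):
            nuc = nucleus_labels == i
            cyt = (cell_labels == i) & ~nuc
            nuc_int = float(profile.get("nucleus", profile.get("cell", 0.0)))
            cyt_int = float(profile.get("cytoplasm", profile.get("cell", 0.0)))
            base[nuc] += nuc_int
            base[cyt] += cyt_int
            intensities[(i, f"{channel}:nucleus")] = nuc_int
            intensities[(i, f"{channel}:cytoplasm")] = cyt_int
        stack = np.empty((n_planes,) + tuple(image_shape), dtype=float)
        for p in range(n_planes):
            plane = ndimage.gaussian_filter(base * weights[p], sigma=blur_sigma)
            stack[p] = rng.poisson(np.clip(plane, 0.0, None)).astype(float)
        stacks[channel] = stack

    truth = SceneGroundTruth(
        cell_centers=tuple(centers),
        cell_radii=tuple(cell_radius for _ in centers),
        nucleus_radii=tuple(nucleus_radius for _ in centers),
        per_cell_compartment_intensities=intensities,
        confluency=confluency,
        seed=seed,
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
    )
    return stacks, truth


# ---------------------------------------------------------------------------
# time-course feature tables with planted covariation
# ---------------------------------------------------------------------------


def _factor_trajectories(spec: PlantedStructureSpec, seed: int) -> np.ndarray:
    """Smooth standardized trajectory per latent factor, shared across
    conditions for a given seed (random cubic trend over the time grid)."""
    rng = np.random.default_rng([seed, 1715])
    t = spec.time_grid
    if t.size == 0:
        return np.zeros((len(spec.latent_factors), 0))
    x = (t - t.min()) / max(t.max() - t.min(), 1e-12) * 2.0 - 1.0
    trajs = np.empty((len(spec.latent_factors), t.size))
    for i in range(len(spec.latent_factors)):
        coef = rng.normal(size=4)
        y = coef[0] + coef[1] * x + coef[2] * x**2 + coef[3] * x**3
        sd = y.std()
        if sd < 1e-9:  # degenerate draw: fall back to a linear ramp
            y = x.copy()
            sd = y.std()
        trajs[i] = (y - y.mean()) / sd
    return trajs


def generate_timecourse_features(
    spec: PlantedStructureSpec, condition: str, seed: int = 0
) -> FeatureTable:
    """Simulate the median feature quantities of one condition.

    Each feature trajectory is ``baseline + sum(loading * factor(t)) +
    Gaussian noise`` truncated at zero.  Factors carrying a condition
    label contribute only in that condition; factor trajectories depend
    on the seed but not on the condition, so the two condition tables of
    one seed share their common structure.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    features = spec.feature_universe
    index = {f: i for i, f in enumerate(features)}
    T = spec.time_grid.size
    values = np.full((len(features), T), spec.baseline, dtype=float)

    trajs = _factor_trajectories(spec, seed)
    for f, traj in zip(spec.latent_factors, trajs):
        if f.condition is not None and f.condition != condition:
            continue
        for member, loading in zip(f.members, f.loadings):
            values[index[member]] += loading * traj

    rng = np.random.default_rng([seed, 2947, CONDITIONS.index(condition)])
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    return FeatureTable(features=features, values=values, time_grid=spec.time_grid,
                        condition=condition)


def default_study_spec(
    n_proteins: int = 36,
    *,
    noise_sd: float = 4.0,
    n_shared_factors: int = 8,
    planted_pair: tuple[FeatureId, FeatureId] | None = None,
    planted_condition: str = "control",
    factor_seed: int = 7,
) -> PlantedStructureSpec:
    """Planted structure mirroring the study design: ``n_proteins``
    proteins over nine time points (0.5-8 h), two conditions.

    Compartment subsets cycle through sizes 2-5 (every protein has at
    least nucleus and cytoplasm).  ``n_shared_factors`` smooth factors
    shared by both conditions give the network background; one strong
    factor restricted to ``planted_condition`` links ``planted_pair``
    (default: the nuclear features of the first two proteins), which is
    the planted condition-specific edge.
    """
    proteins = [f"P{i + 1:02d}" for i in range(n_proteins)]
    subsets = (
        ("nucleus", "cytoplasm"),
        ("nucleus", "cytoplasm", "plasma_membrane"),
        ("nucleus", "cytoplasm", "nuclear_membrane", "plasma_membrane"),
        COMPARTMENTS,
    )
    compartments = {p: subsets[i % len(subsets)] for i, p in enumerate(proteins)}
    if planted_pair is None:
        planted_pair = ((proteins[0], "nucleus"), (proteins[1], "nucleus"))

    universe = [
        (p, c)
        for p, comps in compartments.items()
        for c in comps
        if p not in (planted_pair[0][0], planted_pair[1][0])
    ]
    rng = np.random.default_rng(factor_seed)
    factors: list[LatentFactor] = []
    for _ in range(n_shared_factors):
        k = int(rng.integers(3, 7))
        members = tuple(universe[j] for j in rng.choice(len(universe), size=k, replace=False))
        loadings = tuple(float(rng.uniform(15, 30) * rng.choice([-1, 1])) for _ in members)
        factors.append(LatentFactor(members=members, loadings=loadings))
    factors.append(
        LatentFactor(members=planted_pair, loadings=(40.0, 40.0), condition=planted_condition)
    )
    return PlantedStructureSpec(
        n_proteins=n_proteins,
        compartments_per_protein=compartments,
        latent_factors=tuple(factors),
        noise_sd=noise_sd,
        time_grid=np.array([0.5, 1, 2, 3, 4, 5, 6, 7, 8], dtype=float),
    )


# ---------------------------------------------------------------------------
# expression matrices for the microarray prefilter
# ---------------------------------------------------------------------------


def generate_expression_matrix(
    n_genes: int,
    n_samples_per_group: int,
    de_spec: Sequence[tuple[str | int, float]] = (),
    seed: int = 0,
    *,
    noise_sd: float = 0.1,
    baseline_log_mean: float = math.log(50.0),
    baseline_log_sd: float = 1.0,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Lognormal baseline per gene; DE genes shifted multiplicatively.

    ``de_spec`` lists (gene, log2 fold change) pairs applied to the
    treated group.  Returns the matrix plus ground-truth ``{"up": [...],
    "down": [...]}`` gene lists.
    """
    if n_genes <= 0 or n_samples_per_group <= 0:
        raise ValueError("counts must be positive")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    name_of = {g: g for g in genes}
    name_of.update({i: genes[i] for i in range(n_genes)})
    seen: set[str] = set()
    log2fc = np.zeros(n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for gene, fc in de_spec:
        if not np.isfinite(fc):
            raise ValueError("fold changes must be finite")
        g = name_of.get(gene)
        if g is None:
            raise ValueError(f"unknown gene {gene!r}")
        if g in seen:
            raise ValueError(f"duplicate gene {g} in de_spec")
        seen.add(g)
        log2fc[gene_pos[g]] = fc

    rng = np.random.default_rng(seed)
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes))
    n = n_samples_per_group
    noise = np.exp(rng.normal(0.0, noise_sd, size=(n_genes, 2 * n)))
    values = baseline[:, None] * noise
    values[:, n:] *= (2.0**log2fc)[:, None]

    samples = tuple(f"ctrl_{i + 1}" for i in range(n)) + tuple(f"trt_{i + 1}" for i in range(n))
    groups = ("control",) * n + ("treated",) * n
    em = ExpressionMatrix(genes=tuple(genes), samples=samples, values=values, groups=groups)
    truth = {
        "up": [g for g, f in zip(genes, log2fc) if f > 0],
        "down": [g for g, f in zip(genes, log2fc) if f < 0],
    }
    return em, truth
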