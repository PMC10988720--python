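"""Image feature extraction: z-stack to per-(protein, compartment)
median feature quantities.

The chain mirrors standard high-content-screening practice: maximum
intensity projection of each z-stack, nucleus detection on the nuclear
marker channel (Hoechst-like) as watershed seeds, marker-controlled
watershed on the cytoplasmic marker channel (GAPDH-like) for the cell
area, compartment derivation (cytoplasm = cell minus nucleus, membrane
rings from region contours), mean fluorescence per compartment per cell,
and a per-timepoint median over all cells of the retained fields.
Fields are retained only when cell confluency lies in [20%, 65%]
(boundaries inclusive).
"""

from __future__ import annotations

import logging
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .datatypes import CompartmentLabelMap, FeatureTable, PlomconError

logger = logging.getLogger(__name__)


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Pixelwise maximum over the planes of a z-stack (planes first)."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("zstack must be a nonempty (planes, H, W) array")
    return zstack.max(axis=0)


def detect_nuclei(
    nuclear_channel: np.ndarray, min_area: int = 40, smooth_sigma: float = 1.0
) -> np.ndarray:
    """Detect nuclei as connected bright regions of the nuclear-marker
    channel (Otsu threshold on the smoothed image), dropping regions
    smaller than ``min_area`` pixels.  Returns a label image (1..n)."""
    img = np.asarray(nuclear_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nuclear channel must be a 2D grayscale image")
    smoothed = gaussian(img, sigma=smooth_sigma, preserve_range=True)
    if smoothed.max() - smoothed.min() < 1e-12:
        return np.zeros(img.shape, dtype=np.int32)
    mask = smoothed > threshold_otsu(smoothed)
    # drop regions strictly smaller than min_area
    mask = remove_small_objects(mask, max_size=min_area - 1)
    return sk_label(mask).astype(np.int32)


def segment_cells(
    cyto_channel: np.ndarray, nucleus_labels: np.ndarray, smooth_sigma: float = 1.0
) -> np.ndarray:
    """Marker-controlled watershed of the cytoplasmic-marker channel.

    Nuclei are the seeds; the foreground mask is the Otsu threshold of
    the smoothed channel (union the seeds, which by definition are cell
    pixels).  Each returned cell keeps its seed's label id, so cell and
    nucleus label images share ids.  No seeds -> empty labeling.
    """
    cyto = np.asarray(cyto_channel, dtype=float)
    nucleus_labels = np.asarray(nucleus_labels)
    if cyto.shape != nucleus_labels.shape:
        raise ValueError("cytoplasm channel and nucleus labels must share a shape")
    if nucleus_labels.max() == 0:
        return np.zeros(cyto.shape, dtype=np.int32)
    smoothed = gaussian(cyto, sigma=smooth_sigma, preserve_range=True)
    if smoothed.max() - smoothed.min() < 1e-12:
        fg = np.zeros(cyto.shape, dtype=bool)
    else:
        fg = smoothed > threshold_otsu(smoothed)
    fg |= nucleus_labels > 0
    return watershed(-smoothed, markers=nucleus_labels, mask=fg).astype(np.int32)


def derive_compartments(
    cell_labels: np.ndarray, nucleus_labels: np.ndarray, membrane_width: int = 2
) -> CompartmentLabelMap:
    """Split each cell into cytoplasm and membrane-ring compartments.

    cytoplasm = cell minus nucleus; plasma-membrane ring = cell pixels
    within ``membrane_width`` of the cell contour (cell minus its
    erosion); nuclear-membrane ring = pixels within ``membrane_width``
    of the nucleus contour (dilation minus erosion), clipped to the
    cell.  A cell paired with zero or more than one nucleus signals an
    upstream segmentation failure and is dropped with a warning.
    """
    cell_labels = np.asarray(cell_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    if cell_labels.shape != nucleus_labels.shape:
        raise ValueError("label images must share a shape")
    if membrane_width < 1:
        raise ValueError("membrane_width must be >= 1 pixel")

    out_cell = np.zeros_like(cell_labels, dtype=np.int32)
    out_nuc = np.zeros_like(out_cell)
    out_cyt = np.zeros_like(out_cell)
    out_pm = np.zeros_like(out_cell)
    out_nm = np.zeros_like(out_cell)

    slices = ndimage.find_objects(cell_labels)
    for cid, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        pad = membrane_width + 1
        slc = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(slc, cell_labels.shape)
        )
        cmask = cell_labels[slc] == cid
        nuc_ids = np.unique(nucleus_labels[slc][cmask])
        nuc_ids = nuc_ids[nuc_ids > 0]
        if nuc_ids.size != 1:
            logger.warning("cell %d has %d nuclei; dropped", cid, nuc_ids.size)
            continue
        nmask = (nucleus_labels[slc] == nuc_ids[0]) & cmask
        cyt = cmask & ~nmask
        eroded = ndimage.binary_erosion(cmask, iterations=membrane_width)
        pm = cmask & ~eroded
        ndil = ndimage.binary_dilation(nmask, iterations=membrane_width)
        nero = ndimage.binary_erosion(nmask, iterations=membrane_width)
        nm = (ndil & ~nero) & cmask
        out_cell[slc][cmask] = cid
        out_nuc[slc][nmask] = cid
        out_cyt[slc][cyt] = cid
        out_pm[slc][pm] = cid
        out_nm[slc][nm] = cid

    return CompartmentLabelMap(
        cell_labels=out_cell,
        nucleus_labels=out_nuc,
        cytoplasm_labels=out_cyt,
        plasma_membrane_labels=out_pm,
        nuclear_membrane_labels=out_nm,
    )


def compute_confluency(cell_labels: np.ndarray) -> float:
    """Fraction of the field covered by labeled cells."""
    cell_labels = np.asarray(cell_labels)
    return float((cell_labels > 0).mean())


def filter_fields(
    fields: Sequence[Any],
    confluencies: Sequence[float],
    low: float = 0.20,
    high: float = 0.65,
) -> list[Any]:
    """Keep fields whose confluency lies in [low, high], inclusive."""
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("need 0 <= low < high <= 1")
    if len(fields) != len(confluencies):
        raise ValueError("one confluency per field")
    return [f for f, c in zip(fields, confluencies) if low <= c <= high]


def measure_features(
    protein_channel: np.ndarray,
    compartment_map: CompartmentLabelMap,
    protein: str,
    include_ratio: bool = True,
) -> pd.DataFrame:
    """Mean protein-channel intensity per compartment per cell.

    Emits one record per (cell, compartment) with at least one pixel;
    the derived ``nucleus/cytoplasm`` ratio feature is emitted only when
    both means are positive.  Columns: cell, protein, compartment, value.
    """
    img = np.asarray(protein_channel, dtype=float)
    if img.shape != compartment_map.cell_labels.shape:
        raise ValueError("protein channel and label maps must share a shape")
    comps = {
        "nucleus": compartment_map.nucleus_labels,
        "cytoplasm": compartment_map.cytoplasm_labels,
        "plasma_membrane": compartment_map.plasma_membrane_labels,
        "nuclear_membrane": compartment_map.nuclear_membrane_labels,
    }
    records: list[tuple[int, str, str, float]] = []
    for cid in compartment_map.cell_ids:
        means: dict[str, float] = {}
        for comp, lab in comps.items():
            mask = lab == cid
            if mask.any():
                means[comp] = float(img[mask].mean())
                records.append((int(cid), protein, comp, means[comp]))
        if (
            include_ratio
            and compartment_map.ratio_feature
            and means.get("nucleus", 0.0) > 0
            and means.get("cytoplasm", 0.0) > 0
        ):
            records.append(
                (int(cid), protein, "nucleus/cytoplasm", means["nucleus"] / means["cytoplasm"])
            )
    return pd.DataFrame(records, columns=["cell", "protein", "compartment", "value"])


def aggregate_median(records: pd.DataFrame, condition: str) -> FeatureTable:
    """Median feature quantity per time point over all pooled cells.

    ``records`` needs columns protein, compartment, time_h, value, with
    cells pooled across the retained fields of each time point.  A
    feature absent at some time point cannot enter the (complete-matrix)
    network stage; it is excluded with a warning.
    """
    required = {"protein", "compartment", "time_h", "value"}
    if not required.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(required)}")
    if len(records) == 0:
        raise PlomconError("no feature records to aggregate")
    med = (
        records.groupby(["protein", "compartment", "time_h"])["value"]
        .median()
        .unstack("time_h")
    )
    complete = med.dropna()
    dropped = med.index.difference(complete.index)
    for protein, comp in dropped:
        logger.warning("feature (%s, %s) missing at some time point; excluded", protein, comp)
    time_grid = np.array(sorted(complete.columns), dtype=float)
    complete = complete[sorted(complete.columns)]
    return FeatureTable(
        features=tuple((str(p), str(c)) for p, c in complete.index),
        values=complete.to_numpy(dtype=float),
        time_grid=time_grid,
        condition=condition,
    )


def process_field(
    channels: dict[str, np.ndarray],
    protein_channels: dict[str, str],
    *,
    nuclear_channel: str = "nuclear_marker",
    cyto_channel: str = "cyto_marker",
    min_area: int = 40,
    membrane_width: int = 2,
    include_ratio: bool = True,
) -> tuple[pd.DataFrame, float, CompartmentLabelMap]:
    """Run the full per-field chain on a dict of z-stacks.

    ``protein_channels`` maps channel name -> protein name for the
    stains to quantify.  Returns (per-cell records, confluency,
    compartment map).
    """
    mips = {name: max_intensity_projection(stack) for name, stack in channels.items()}
    nuclei = detect_nuclei(mips[nuclear_channel], min_area=min_area)
    cells = segment_cells(mips[cyto_channel], nuclei)
    cmap = derive_compartments(cells, nuclei, membrane_width=membrane_width)
    confluency = compute_confluency(cmap.cell_labels)
    frames = [
        measure_features(mips[ch], cmap, protein, include_ratio=include_ratio)
        for ch, protein in protein_channels.items()
    ]
    records = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["cell", "protein", "compartment", "value"])
    )
    return records, confluency, cmap
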