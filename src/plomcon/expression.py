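"""Microarray prefilter: global median normalization and the 1.5-fold
differential-expression gate.

Each array (sample) is rescaled multiplicatively so that the median of
its detected signals equals a fixed target (25 by default); genes are
then called up- or downregulated when the ratio of treated to control
group means reaches the fold threshold (inclusive on both sides:
ratio >= 1.5 or ratio <= 1/1.5 at the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PlomconError


def global_normalize(matrix: ExpressionMatrix, target_median: float = 25.0) -> ExpressionMatrix:
    """Rescale each sample so its median detected signal equals
    ``target_median``.  A sample with zero median signals a failed array."""
    values = matrix.values.copy()
    for j in range(values.shape[1]):
        detected = matrix.detected[:, j]
        med = float(np.median(values[detected, j]))
        if med <= 0:
            raise PlomconError(f"sample {matrix.samples[j]} has a zero median signal")
        values[:, j] *= target_median / med
    return ExpressionMatrix(
        genes=matrix.genes, samples=matrix.samples, values=values,
        groups=matrix.groups, detected=matrix.detected.copy(),
    )


@dataclass
class FoldChangeResult:
    """Gene lists from the fold-change gate plus per-gene log2 ratios."""

    down: tuple[str, ...]
    up: tuple[str, ...]
    log2_fold_change: pd.Series
    excluded: tuple[str, ...]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        status = pd.Series("unchanged", index=self.log2_fold_change.index)
        status.loc[list(self.up)] = "up"
        status.loc[list(self.down)] = "down"
        return pd.DataFrame({"log2_fold_change": self.log2_fold_change, "status": status})


def fold_change_filter(matrix: ExpressionMatrix, threshold: float = 1.5) -> FoldChangeResult:
    """Call up-/downregulated genes from group-mean ratios.

    ratio = mean(treated) / mean(control) on normalized signals; a gene
    is *up* when ratio >= threshold and *down* when ratio <= 1/threshold
    (both inclusive).  Genes with a zero control mean have no defined
    ratio and are excluded (reported in ``excluded``).
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    groups = np.asarray(matrix.groups)
    ctrl = groups == "control"
    trt = groups == "treated"
    if not ctrl.any() or not trt.any():
        raise PlomconError("both groups must be nonempty")
    mean_c = matrix.values[:, ctrl].mean(axis=1)
    mean_t = matrix.values[:, trt].mean(axis=1)
    genes = np.asarray(matrix.genes)
    ok = mean_c > 0
    ratio = np.full(len(genes), np.nan)
    ratio[ok] = mean_t[ok] / mean_c[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(ratio)
    up = tuple(genes[ok & (ratio >= threshold)])
    down = tuple(genes[ok & (ratio <= 1.0 / threshold)])
    return FoldChangeResult(
        down=down, up=up,
        log2_fold_change=pd.Series(log2fc, index=genes, name="log2_fold_change"),
        excluded=tuple(genes[~ok]), threshold=threshold,
    )
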