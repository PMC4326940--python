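"""Per-cell mean fluorescence intensity (MFI) and CD39-style classification.

Cells are segmented on the structural channel (IbaI/GFP-like), and the mean
of the second channel over each cell's mask gives its MFI.  Cells are then
classed *low* / *pos* / *high* against thresholds taken from the MFI
distribution of a reference group (young wild-type fields): the lower and
upper thresholds default to the 5th and 95th reference percentiles, the
reproducible analogue of thresholds drawn on a reference scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .spatial import max_projection, threshold_binarize
from .tracing import ImageStack

__all__ = [
    "CellIntensityRecord",
    "segment_cells",
    "cell_mfi",
    "classify_reference",
    "class_percentages",
]

CLASS_LABELS = ("low", "pos", "high")


@dataclass
class CellIntensityRecord:
    cell_id: int
    mask_area: float            # μm²
    mfi: float                  # mean channel-2 intensity, arbitrary units
    centroid: tuple[float, float] = (np.nan, np.nan)  # μm
    cd39_class: str | None = None


def segment_cells(
    channel1_stack: ImageStack,
    threshold="otsu",
    min_area: float = 20.0,
) -> np.ndarray:
    """Label candidate cells on the structural channel.

    Thresholds the maximum z-projection, labels 8-connected components, and
    discards components smaller than ``min_area`` μm².  Returns a 2-D int
    label image (0 = background); an empty foreground yields an all-zero
    image rather than an error.
    """
    proj = max_projection(channel1_stack)
    mask, _ = threshold_binarize(proj, method=threshold)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels
    px_area = channel1_stack.voxel_size[0] * channel1_stack.voxel_size[1]
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes * px_area >= min_area) + 1
    out = np.zeros_like(labels)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def cell_mfi(labels: np.ndarray, channel2_stack: ImageStack) -> list[CellIntensityRecord]:
    """Mean channel-2 (max-projection) intensity over each labeled cell."""
    proj = max_projection(channel2_stack)
    if proj.shape != labels.shape:
        raise ParameterError(
            f"label image {labels.shape} and channel 2 {proj.shape} differ in geometry"
        )
    n = int(labels.max())
    if n == 0:
        return []
    dx, dy = channel2_stack.voxel_size[0], channel2_stack.voxel_size[1]
    idx = np.arange(1, n + 1)
    means = ndimage.mean(proj, labels, index=idx)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=idx)
    cents = ndimage.center_of_mass(np.ones_like(labels), labels, index=idx)
    return [
        CellIntensityRecord(
            cell_id=int(i),
            mask_area=float(s * dx * dy),
            mfi=float(m),
            centroid=((c[1] + 0.5) * dx, (c[0] + 0.5) * dy),
        )
        for i, s, m, c in zip(idx, sizes, means, cents)
    ]


def classify_reference(
    records: list[CellIntensityRecord],
    reference_mfis,
    lower_q: float = 0.05,
    upper_q: float = 0.95,
) -> tuple[list[CellIntensityRecord], dict[str, float]]:
    """Class each cell low/pos/high against reference-distribution quantiles.

    ``T_low``/``T_high`` are the ``lower_q``/``upper_q`` quantiles of the
    reference MFIs; a cell is *low* if mfi < T_low, *high* if mfi > T_high,
    otherwise *pos*.  Returns the updated records and the percentage of each
    class (summing to 100 exactly).
    """
    ref = np.asarray(list(reference_mfis), dtype=float)
    if ref.size == 0:
        raise ParameterError("reference MFI set is empty")
    if not (0.0 < lower_q < upper_q < 1.0):
        raise ParameterError("need 0 < lower_q < upper_q < 1")
    t_low = float(np.quantile(ref, lower_q))
    t_high = float(np.quantile(ref, upper_q))
    for r in records:
        if r.mfi < t_low:
            r.cd39_class = "low"
        elif r.mfi > t_high:
            r.cd39_class = "high"
        else:
            r.cd39_class = "pos"
    return records, class_percentages(records) | {
        "threshold_low": t_low,
        "threshold_high": t_high,
    }


def class_percentages(records: list[CellIntensityRecord]) -> dict[str, float]:
    """Percentage of each class among classified cells; sums to 100 exactly."""
    classed = [r for r in records if r.cd39_class is not None]
    if not classed:
        return {c: 0.0 for c in CLASS_LABELS}
    n = len(classed)
    counts = {c: sum(r.cd39_class == c for r in classed) for c in CLASS_LABELS}
    return {c: 100.0 * k / n for c, k in counts.items()}


def records_to_frame(records: list[CellIntensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(cell_id=r.cell_id, mask_area=r.mask_area, mfi=r.mfi,
                 cd39_class=r.cd39_class)
            for r in records
        ]
    )
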