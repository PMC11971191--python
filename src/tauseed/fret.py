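"""Inclusion scoring of tau biosensor cell fields.

Biosensor cells exposed to seeding-competent tau form bright intracellular
inclusions.  The readout is the percentage of cells carrying at least one
inclusion, computed per field from a two-channel image: channel 0 shows the
cell bodies, channel 1 the inclusion puncta.  Scoring is deterministic
threshold-based segmentation; merged cells count as one (a documented
limitation of connectivity-based cell detection on crowded fields).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

__all__ = ["InclusionResult", "detect_cells", "score_inclusions", "quantify_field"]


@dataclass(frozen=True)
class InclusionResult:
    """Per-field inclusion scoring outcome."""

    n_cells: int
    n_with_inclusions: int

    @property
    def percent(self) -> float:
        """Percent of cells with inclusions; NaN when no cells were found."""
        if self.n_cells == 0:
            return math.nan
        return 100.0 * self.n_with_inclusions / self.n_cells

    @property
    def undefined(self) -> bool:
        return self.n_cells == 0


def detect_cells(
    cell_channel: np.ndarray, threshold: float, min_cell_area_px: int = 50
) -> np.ndarray:
    """Label cell bodies: 8-connected components above ``threshold`` of at
    least ``min_cell_area_px`` pixels.  Returns a label image (0 is
    background); an empty image yields zero cells, not an error."""
    mask = np.asarray(cell_channel) > threshold
    labels = label(mask, connectivity=2)
    keep = np.zeros(labels.max() + 1, dtype=np.int32)
    next_id = 1
    for p in regionprops(labels):
        if p.area >= min_cell_area_px:
            keep[p.label] = next_id
            next_id += 1
    return keep[labels]


def score_inclusions(
    cell_labels: np.ndarray,
    inclusion_channel: np.ndarray,
    punctum_threshold: float,
    min_punctum_px: int = 4,
) -> InclusionResult:
    """Count cells containing at least one inclusion punctum.

    A punctum is an 8-connected region of at least ``min_punctum_px``
    pixels above ``punctum_threshold`` (the size floor suppresses
    single-pixel noise); a cell is positive when a punctum overlaps its
    mask.
    """
    cell_labels = np.asarray(cell_labels)
    inclusion = np.asarray(inclusion_channel)
    if cell_labels.shape != inclusion.shape:
        raise ValueError("cell and inclusion channels must have the same shape")
    n_cells = int(cell_labels.max())
    punctum_labels = label(inclusion > punctum_threshold, connectivity=2)
    positive: set[int] = set()
    for p in regionprops(punctum_labels):
        if p.area < min_punctum_px:
            continue
        rows, cols = p.coords[:, 0], p.coords[:, 1]
        owners = np.unique(cell_labels[rows, cols])
        positive.update(int(o) for o in owners if o != 0)
    return InclusionResult(n_cells=n_cells, n_with_inclusions=len(positive))


def quantify_field(
    field: np.ndarray,
    cell_threshold: float,
    punctum_threshold: float,
    min_cell_area_px: int = 50,
    min_punctum_px: int = 4,
) -> InclusionResult:
    """Score a ``(2, H, W)`` stack (cells in channel 0, puncta in channel 1)."""
    field = np.asarray(field)
    if field.ndim != 3 or field.shape[0] != 2:
        raise ValueError("expected a (2, H, W) two-channel image stack")
    cells = detect_cells(field[0], cell_threshold, min_cell_area_px)
    return score_inclusions(cells, field[1], punctum_threshold, min_punctum_px)
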