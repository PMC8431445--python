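"""Nucleus / cell segmentation and mask reconciliation.

The baseline segmenters are classical (smoothing, global threshold,
distance-transform markers, watershed split, small-object removal) and stand
behind the same mask contract as externally produced label masks (e.g. from
a trained instance-segmentation network), which can be loaded instead via
:func:`melcpipe.io.read_label_mask`.

Reconciliation keeps a cell object only if a nucleus object is reproduced
inside it: at least one nucleus has more than half of its pixels within the
cell.  Each kept cell is paired with its largest-overlap such nucleus and the
nucleus compartment downstream is the intersection nucleus & cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)


@dataclass
class LabelMask:
    """Integer-labeled mask, 0 = background; labels need not be consecutive."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("label mask must be 2D")
        if lab.min() < 0:
            raise ValueError("labels are nonnegative")
        self.labels = lab.astype(np.int64)

    @property
    def ids(self) -> np.ndarray:
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)


@dataclass
class CellTable:
    """Reconciled nucleus-cell pairing plus the masks it refers to."""

    records: pd.DataFrame  # cell_id, cell_label, nucleus_label, centroid_x, centroid_y, border_touching
    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    n_cells_dropped: int = 0
    n_nuclei_unassigned: int = 0

    def __len__(self) -> int:
        return len(self.records)


def _baseline_segment(
    intensity: np.ndarray,
    sigma: float,
    min_size: int,
    min_distance: int,
    erosion: int = 0,
) -> LabelMask:
    """Smooth -> Otsu threshold -> distance-transform markers -> watershed."""
    smooth = ndimage.gaussian_filter(np.asarray(intensity, dtype=np.float64), sigma)
    if np.ptp(smooth) == 0:  # blank image
        return LabelMask(np.zeros(intensity.shape, dtype=np.int64))
    mask = smooth > threshold_otsu(smooth)
    if erosion > 0:
        mask = ndimage.binary_erosion(mask, iterations=erosion)
    mask = remove_small_objects(mask, max_size=min_size - 1)
    if not mask.any():
        return LabelMask(np.zeros(intensity.shape, dtype=np.int64))
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(intensity.shape, dtype=np.int64)
    for i, (y, x) in enumerate(peaks, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        markers, _ = ndimage.label(mask)
    labels = watershed(-distance, markers, mask=mask)
    labels = remove_small_objects(labels, max_size=min_size - 1)
    return LabelMask(labels.astype(np.int64))


def segment_nuclei(
    nuclear_stain: np.ndarray,
    sigma: float = 2.0,
    min_size: int = 30,
    min_distance: int = 7,
) -> LabelMask:
    """Baseline nucleus segmentation of a nuclear-stain fluorescence image."""
    nuclear_stain = np.asarray(nuclear_stain)
    if nuclear_stain.ndim != 2:
        raise ValueError("nuclear stain image must be 2D")
    return _baseline_segment(nuclear_stain, sigma, min_size, min_distance)


def segment_cells(
    phase_contrast: np.ndarray,
    sigma: float = 2.0,
    min_size: int = 60,
    min_distance: int = 10,
    texture_window: int = 3,
    erosion: int = 2,
) -> LabelMask:
    """Baseline cell segmentation of a phase-contrast image.

    Phase contrast carries cells as texture rather than brightness, so a
    local-variance map over ``texture_window`` replaces raw intensity before
    the same threshold/watershed chain as for nuclei.  The variance window
    and smoothing dilate the mask by a couple of pixels; ``erosion`` shrinks
    it back before splitting so that adjacent cells are not bridged.
    """
    phase = np.asarray(phase_contrast, dtype=np.float64)
    if phase.ndim != 2:
        raise ValueError("phase-contrast image must be 2D")
    mean = ndimage.uniform_filter(phase, texture_window)
    sq_mean = ndimage.uniform_filter(phase**2, texture_window)
    variance = np.clip(sq_mean - mean**2, 0.0, None)
    return _baseline_segment(variance, sigma, min_size, min_distance, erosion=erosion)


def reconcile_masks(
    cell_mask: LabelMask | np.ndarray,
    nucleus_mask: LabelMask | np.ndarray,
    min_containment: float = 0.5,
) -> CellTable:
    """Keep cell objects reproduced in the nucleus mask and pair them.

    A cell is kept iff at least one nucleus has strictly more than
    ``min_containment`` of its pixels inside the cell; the cell is paired
    with its largest-overlap qualifying nucleus, and each nucleus is
    assigned to at most one cell (its own largest-overlap cell).
    """
    cells = cell_mask.labels if isinstance(cell_mask, LabelMask) else np.asarray(cell_mask)
    nucs = nucleus_mask.labels if isinstance(nucleus_mask, LabelMask) else np.asarray(nucleus_mask)
    if cells.shape != nucs.shape:
        raise ValueError("cell and nucleus mask shapes differ")

    nuc_ids = np.unique(nucs[nucs > 0])
    nuc_sizes = {int(n): int(np.sum(nucs == n)) for n in nuc_ids}

    # overlap counts between every (cell, nucleus) label pair
    both = (cells > 0) & (nucs > 0)
    pairs: dict[tuple[int, int], int] = {}
    if both.any():
        keys = cells[both].astype(np.int64) * (nucs.max() + 1) + nucs[both]
        uniq, counts = np.unique(keys, return_counts=True)
        for k, cnt in zip(uniq, counts):
            pairs[(int(k // (nucs.max() + 1)), int(k % (nucs.max() + 1)))] = int(cnt)

    # nucleus -> the cell holding most of it, if > min_containment of its pixels
    nucleus_home: dict[int, tuple[int, int]] = {}
    for (c, n), cnt in pairs.items():
        if cnt / nuc_sizes[n] > min_containment:
            if n not in nucleus_home or cnt > nucleus_home[n][1]:
                nucleus_home[n] = (c, cnt)

    # cell -> its largest-overlap assigned nucleus
    cell_choice: dict[int, tuple[int, int]] = {}
    for n, (c, cnt) in nucleus_home.items():
        if c not in cell_choice or cnt > cell_choice[c][1]:
            cell_choice[c] = (n, cnt)

    cell_ids = np.unique(cells[cells > 0])
    h, w = cells.shape
    rows = []
    for cid, c in enumerate(sorted(cell_choice), start=1):
        n = cell_choice[c][0]
        region = cells == c
        ys, xs = np.nonzero(region)
        border = bool(ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1)
        rows.append(
            {
                "cell_id": cid,
                "cell_label": c,
                "nucleus_label": n,
                "centroid_x": float(xs.mean()),
                "centroid_y": float(ys.mean()),
                "border_touching": border,
            }
        )
    records = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "cell_label",
            "nucleus_label",
            "centroid_x",
            "centroid_y",
            "border_touching",
        ],
    )
    n_dropped = int(cell_ids.size - len(records))
    n_unassigned = int(nuc_ids.size - len(nucleus_home))
    if n_dropped or n_unassigned:
        logger.info(
            "reconcile_masks: %d cell objects dropped (no reproduced nucleus), "
            "%d nuclei unassigned",
            n_dropped,
            n_unassigned,
        )
    return CellTable(
        records=records,
        cell_mask=cells.astype(np.int64),
        nucleus_mask=nucs.astype(np.int64),
        n_cells_dropped=n_dropped,
        n_nuclei_unassigned=n_unassigned,
    )


def apply_exclusions(table: CellTable, regions: list[list[tuple[float, float]]]) -> CellTable:
    """Drop cells whose centroid lies strictly inside any exclusion polygon.

    Regions are lists of (x, y) vertices in pixel coordinates.  A centroid
    exactly on a polygon edge is kept.  Malformed (self-intersecting)
    polygons raise.
    """
    if not regions:
        return table
    polys = []
    for verts in regions:
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError(f"malformed exclusion polygon: {verts}")
        polys.append(poly)
    keep = []
    for rec in table.records.itertuples():
        pt = Point(rec.centroid_x, rec.centroid_y)
        keep.append(not any(poly.contains(pt) for poly in polys))  # contains = strict interior
    removed = int(len(keep) - sum(keep))
    if removed:
        logger.info("apply_exclusions: removed %d cells inside exclusion regions", removed)
    return replace(table, records=table.records[np.asarray(keep, dtype=bool)].reset_index(drop=True))
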