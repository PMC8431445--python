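"""Per-cell morphology and compartment-resolved intensity features.

Each cell is described by 6 morphological features (cell size/perimeter,
nucleus size/perimeter/roundness/solidity) and, per marker, 9 intensity
features: mean (ME), total (TO) and mean of the top 20% pixel intensities
(M20), each in three compartments — nucleus, whole cell, and
cytoplasm/membrane (cell minus nucleus).

Conventions fixed for exact testability:

* sizes are pixel counts; perimeter is the number of unit pixel edges on the
  object/background interface (image border edges count),
* roundness = 4*pi*A / P**2 under that perimeter estimator,
* solidity = A / area of the convex hull of the union of pixel squares,
* M20 averages the k = max(1, ceil(0.2 * n)) largest pixel values.

The edge-count perimeter is biased high on smooth curved outlines relative
to a perimeter of the continuous boundary; features are used comparatively,
so the bias is accepted for the determinism it buys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from melcpipe.correction import MelcRun
from melcpipe.segmentation import CellTable

MORPHOLOGY_COLUMNS = [
    "cell_size",
    "cell_perimeter",
    "nucleus_size",
    "nucleus_perimeter",
    "nucleus_roundness",
    "nucleus_solidity",
]
INTENSITY_STATS = ["ME", "TO", "M20"]
COMPARTMENTS = ["nucleus", "cell", "cytomem"]
METADATA_COLUMNS = ["cell_id", "sample_id", "fov_id", "cyto_empty"]


@dataclass
class MorphologyFeatures:
    cell_size: int
    cell_perimeter: int
    nucleus_size: int
    nucleus_perimeter: int
    nucleus_roundness: float
    nucleus_solidity: float


def boundary_edge_count(mask: np.ndarray) -> int:
    """Count unit pixel edges between object and non-object (incl. image border)."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    edges = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int(np.sum(padded & ~np.roll(padded, shift, axis=axis)))
    return edges


def convex_hull_area(mask: np.ndarray) -> float:
    """Area of the convex hull of the union of the object's pixel squares."""
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if ys.size == 0:
        raise ValueError("empty mask has no convex hull")
    # all four corners of every pixel square; never collinear, so hull is 2D
    corners = np.empty((4 * ys.size, 2), dtype=np.float64)
    for i, (dy, dx) in enumerate(((0, 0), (0, 1), (1, 0), (1, 1))):
        corners[i * ys.size : (i + 1) * ys.size, 0] = ys + dy
        corners[i * ys.size : (i + 1) * ys.size, 1] = xs + dx
    return float(ConvexHull(corners).volume)  # "volume" is area in 2D


def compute_morphology(cell_mask: np.ndarray, nucleus_mask: np.ndarray) -> MorphologyFeatures:
    """Morphological features of one cell and its nucleus (boolean masks)."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    n_cell = int(cell_mask.sum())
    n_nuc = int(nucleus_mask.sum())
    if n_cell == 0 or n_nuc == 0:
        raise ValueError("cell and nucleus pixel sets must be nonempty")
    p_cell = boundary_edge_count(cell_mask)
    p_nuc = boundary_edge_count(nucleus_mask)
    return MorphologyFeatures(
        cell_size=n_cell,
        cell_perimeter=p_cell,
        nucleus_size=n_nuc,
        nucleus_perimeter=p_nuc,
        nucleus_roundness=4.0 * math.pi * n_nuc / p_nuc**2,
        nucleus_solidity=n_nuc / convex_hull_area(nucleus_mask),
    )


def intensity_stats(values: np.ndarray) -> tuple[float, float, float]:
    """(ME, TO, M20) of a compartment's pixel values; (0, 0, 0) if empty."""
    values = np.asarray(values, dtype=np.float64).ravel()
    n = values.size
    if n == 0:
        return 0.0, 0.0, 0.0
    me = float(values.mean())
    to = float(values.sum())
    k = max(1, math.ceil(0.2 * n))
    top = np.partition(values, n - k)[n - k :]
    return me, to, float(top.mean())


def compute_intensity(
    channel: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
) -> dict[str, float]:
    """All nine intensity features of one marker channel for one cell.

    Keys are ``{stat}_{compartment}`` with stats ME/TO/M20 and compartments
    nucleus / cell / cytomem (cell minus nucleus).  An empty
    cytoplasm/membrane compartment (nucleus fills the cell) yields zeros.
    """
    channel = np.asarray(channel, dtype=np.float64)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if channel.shape != cell_mask.shape:
        raise ValueError("channel and mask shapes differ")
    if not cell_mask.any() or not nucleus_mask.any():
        raise ValueError("compartments must be nonempty")
    cyto_mask = cell_mask & ~nucleus_mask
    out: dict[str, float] = {}
    for comp, mask in (("nucleus", nucleus_mask), ("cell", cell_mask), ("cytomem", cyto_mask)):
        me, to, m20 = intensity_stats(channel[mask])
        out[f"ME_{comp}"] = me
        out[f"TO_{comp}"] = to
        out[f"M20_{comp}"] = m20
    return out


def feature_columns_for(markers: list[str]) -> list[str]:
    """Deterministic feature column order: morphology block, then per marker
    the 9 intensity columns (stat-major: ME/TO/M20 x nucleus/cell/cytomem)."""
    cols = list(MORPHOLOGY_COLUMNS)
    for m in markers:
        for stat in INTENSITY_STATS:
            for comp in COMPARTMENTS:
                cols.append(f"{m}_{stat}_{comp}")
    return cols


def intensity_columns(df: pd.DataFrame, markers: list[str] | None = None) -> list[str]:
    """The intensity-feature columns of a feature table, in table order."""
    suffix = tuple(f"_{s}_{c}" for s in INTENSITY_STATS for c in COMPARTMENTS)
    cols = [c for c in df.columns if c.endswith(suffix)]
    if markers is not None:
        cols = [c for c in cols if c.rsplit("_", 2)[0] in set(markers)]
    return cols


def build_feature_table(
    channels: "dict[str, np.ndarray] | MelcRun",
    table: CellTable,
    markers: list[str] | None = None,
) -> pd.DataFrame:
    """One row of features per kept cell.

    Parameters
    ----------
    channels:
        Either a corrected :class:`MelcRun` (tag images are used) or a mapping
        marker -> corrected channel image.  Negative-control channels should
        be included so the normalization stage can consume them.
    table:
        Reconciled cell table carrying the label masks.
    markers:
        Column order of the marker blocks; defaults to the order of
        ``channels``.

    Returns
    -------
    DataFrame with metadata columns (cell_id, sample_id, fov_id, cyto_empty)
    followed by 6 morphology columns and 9 intensity columns per marker.
    """
    sample_id, fov_id = "sample", "fov1"
    if isinstance(channels, MelcRun):
        run = channels
        sample_id, fov_id = run.sample_id, run.fov_id
        channels = {c.marker: c.tag_image for c in run.cycles}
    if markers is None:
        markers = list(channels)
    missing = [m for m in markers if m not in channels]
    if missing:
        raise KeyError(f"markers missing from run: {missing}")

    shape = table.cell_mask.shape
    for m in markers:
        if channels[m].shape != shape:
            raise ValueError(f"channel {m!r} shape {channels[m].shape} != mask shape {shape}")

    rows = []
    for rec in table.records.itertuples():
        cell_mask = table.cell_mask == rec.cell_label
        nucleus_mask = (table.nucleus_mask == rec.nucleus_label) & cell_mask
        morph = compute_morphology(cell_mask, nucleus_mask)
        row: dict = {
            "cell_id": rec.cell_id,
            "sample_id": sample_id,
            "fov_id": fov_id,
            "cyto_empty": bool(morph.cell_size == morph.nucleus_size),
            **morph.__dict__,
        }
        for m in markers:
            feats = compute_intensity(channels[m], cell_mask, nucleus_mask)
            for key, val in feats.items():
                stat, comp = key.split("_", 1)
                row[f"{m}_{stat}_{comp}"] = val
        rows.append(row)

    columns = METADATA_COLUMNS + feature_columns_for(markers)
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]
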