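"""Single-cell atlas: embedding, mean-shift clustering, profiles, composition.

Cells are embedded to 2D with t-SNE on z-scored features and clustered by
Gaussian mean shift (GMS): each point climbs the Gaussian-kernel density of
the embedding to its mode, and a cluster is a mode's basin of attraction.
The mean shift runs on a gridded kernel-density estimate with deterministic
hill-climbing assignment; an exact per-point iteration is available behind a
flag for small inputs.

Cluster phenotypes are summarized as feature-wise min-max-scaled median
profiles (heatmap rows), selected clusters can be subdivided by
complete-linkage hierarchical clustering, and per-sample cluster
compositions quantify how the atlas distributes over samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage

from melcpipe.cluster_eval import _embed, _zscore


@dataclass
class AtlasParams:
    perplexity: float = 30.0
    gms_bandwidth: float | None = None  # embedding units; default extent / 6
    mode_merge_tol: float | None = None  # default = bandwidth
    grid_size: int = 256
    n_subclusters: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gms_bandwidth is not None and self.gms_bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.n_subclusters < 1:
            raise ValueError("need at least one sub-cluster")


def embed_cells(
    table: pd.DataFrame, params: AtlasParams, feature_cols: list[str] | None = None
) -> np.ndarray:
    """2D t-SNE embedding of z-scored feature columns; rows align with the table."""
    if feature_cols is None:
        from melcpipe.cluster_eval import variant_columns

        feature_cols = variant_columns(table, "I")
    x = table[feature_cols].to_numpy(dtype=np.float64)
    if params.perplexity >= x.shape[0]:
        raise ValueError(
            f"perplexity ({params.perplexity}) must be < number of cells ({x.shape[0]})"
        )
    return _embed(_zscore(x), params.perplexity, seed=params.seed)


def _grid_mean_shift(emb: np.ndarray, bandwidth: float, tol: float, grid_size: int) -> np.ndarray:
    """Mean shift on a gridded KDE: hill-climb every grid node to its mode."""
    lo = emb.min(axis=0) - 3 * bandwidth
    hi = emb.max(axis=0) + 3 * bandwidth
    span = float(np.max(hi - lo))
    h = span / grid_size  # grid spacing, equal on both axes
    shape = (
        int(np.ceil((hi[0] - lo[0]) / h)) + 1,
        int(np.ceil((hi[1] - lo[1]) / h)) + 1,
    )
    ix = np.clip(((emb - lo) / h).astype(int), 0, np.array(shape) - 1)
    density = np.zeros(shape)
    np.add.at(density, (ix[:, 0], ix[:, 1]), 1.0)
    density = ndimage.gaussian_filter(density, sigma=bandwidth / h, mode="constant")

    # steepest-ascent pointer for every node (8-neighborhood), then pointer
    # doubling until every node points at a fixed point (a mode)
    padded = np.pad(density, 1, constant_values=-np.inf)
    best = np.zeros(shape, dtype=np.int64)
    best_val = np.full(shape, -np.inf)
    n_cols = shape[1]
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            neigh = padded[1 + dy : 1 + dy + shape[0], 1 + dx : 1 + dx + shape[1]]
            better = neigh > best_val
            best_val = np.where(better, neigh, best_val)
            idx_flat = (
                (np.arange(shape[0])[:, None] + dy) * n_cols
                + (np.arange(shape[1])[None, :] + dx)
            )
            best = np.where(better, idx_flat, best)
    flat = best.ravel()
    for _ in range(64):  # pointer doubling; converges in O(log path length)
        nxt = flat[flat]
        if np.array_equal(nxt, flat):
            break
        flat = nxt

    modes_flat = np.unique(flat)
    # merge modes closer than tol (single link on mode coordinates)
    my, mx = np.unravel_index(modes_flat, shape)
    coords = np.stack([my * h + lo[0], mx * h + lo[1]], axis=1)
    if len(modes_flat) > 1:
        z = linkage(coords, method="single")
        merged = fcluster(z, t=tol, criterion="distance")
    else:
        merged = np.array([1])
    mode_label = dict(zip(modes_flat.tolist(), merged.tolist()))
    point_modes = flat[ix[:, 0] * n_cols + ix[:, 1]]
    return np.array([mode_label[int(m)] for m in point_modes], dtype=np.int64)


def _exact_mean_shift(emb: np.ndarray, bandwidth: float, tol: float) -> np.ndarray:
    """Direct per-point Gaussian mean-shift iteration (small n only)."""
    pts = emb.copy()
    for _ in range(300):
        d2 = ((pts[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        w = np.exp(-d2 / (2 * bandwidth**2))
        new = (w[:, :, None] * emb[None, :, :]).sum(1) / w.sum(1)[:, None]
        if np.max(np.abs(new - pts)) < 1e-6 * bandwidth:
            pts = new
            break
        pts = new
    z = linkage(pts, method="single")
    return np.asarray(fcluster(z, t=tol, criterion="distance"), dtype=np.int64)


def gms_cluster(
    embedding: np.ndarray, params: AtlasParams, exact: bool = False
) -> np.ndarray:
    """Gaussian mean-shift clustering of a 2D embedding.

    Bandwidth defaults to 1/6 of the embedding's larger extent (calibrated
    once on the synthetic fixtures: large enough that a single Gaussian blob
    yields one mode, small enough to keep well-separated t-SNE islands apart;
    not portable to other tools' bandwidth units); modes closer
    than ``mode_merge_tol`` (default: one bandwidth) are merged.  Labels are
    relabelled 1..K by decreasing cluster size.  Deterministic.
    """
    emb = np.asarray(embedding, dtype=np.float64)
    if not np.all(np.isfinite(emb)):
        raise ValueError("embedding must be finite")
    extent = float(np.max(emb.max(axis=0) - emb.min(axis=0)))
    if extent == 0:
        return np.ones(len(emb), dtype=np.int64)
    bandwidth = params.gms_bandwidth if params.gms_bandwidth is not None else extent / 6.0
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    tol = params.mode_merge_tol if params.mode_merge_tol is not None else bandwidth
    labels = (
        _exact_mean_shift(emb, bandwidth, tol)
        if exact
        else _grid_mean_shift(emb, bandwidth, tol, params.grid_size)
    )
    # stable relabelling by decreasing size
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order, start=1)}
    return np.array([remap[int(l)] for l in labels], dtype=np.int64)


def cluster_profile_heatmap(
    table: pd.DataFrame, labels: np.ndarray, feature_cols: list[str] | None = None
) -> pd.DataFrame:
    """Per-cluster median profiles with feature-wise min-max scaling to [0, 1].

    Features whose cluster medians are all equal map to 0.  Rows are
    clusters, columns features.
    """
    if feature_cols is None:
        from melcpipe.cluster_eval import variant_columns

        feature_cols = variant_columns(table, "I")
    labels = np.asarray(labels)
    if len(labels) != len(table):
        raise ValueError("labels must align with table rows")
    med = (
        table[feature_cols]
        .groupby(labels)
        .median()
        .sort_index()
    )
    rng = med.max(axis=0) - med.min(axis=0)
    scaled = (med - med.min(axis=0)).div(rng.replace(0, np.inf))
    return scaled.fillna(0.0)


def hierarchical_subcluster(
    table: pd.DataFrame,
    feature_cols: list[str],
    params: AtlasParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage sub-clustering of one cluster's cells.

    Euclidean distance over the selected (normalized) feature columns; the
    tree is cut into ``params.n_subclusters`` groups.  Returns (labels,
    linkage matrix).
    """
    x = table[feature_cols].to_numpy(dtype=np.float64)
    k = params.n_subclusters
    if k > x.shape[0]:
        raise ValueError(f"cannot form {k} sub-clusters from {x.shape[0]} cells")
    if x.shape[0] == 1:
        return np.array([1]), np.empty((0, 4))
    z = linkage(x, method="complete")
    return np.asarray(fcluster(z, t=k, criterion="maxclust")), z


def composition_summary(
    labels: np.ndarray,
    sample_ids: "np.ndarray | list[str]",
    groups: "dict[str, str] | None" = None,
) -> pd.DataFrame:
    """Cell counts and proportions per sample x cluster.

    Absent (sample, cluster) combinations get proportion 0, so proportions
    sum to 1 within every sample.  ``groups`` optionally maps sample id to a
    grouping factor (e.g. infiltration class) added as a column.
    """
    labels = np.asarray(labels)
    sample_ids = np.asarray(sample_ids)
    if len(labels) != len(sample_ids):
        raise ValueError("every cell needs a sample id")
    df = pd.DataFrame({"sample_id": sample_ids, "cluster": labels})
    counts = (
        df.groupby(["sample_id", "cluster"], sort=True).size().rename("count").reset_index()
    )
    full = (
        counts.pivot(index="sample_id", columns="cluster", values="count")
        .fillna(0)
        .astype(int)
        .stack()
        .rename("count")
        .reset_index()
    )
    totals = full.groupby("sample_id")["count"].transform("sum")
    full["proportion"] = full["count"] / totals.replace(0, np.nan)
    full["proportion"] = full["proportion"].fillna(0.0)
    if groups is not None:
        full["group"] = full["sample_id"].map(groups)
    return full
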