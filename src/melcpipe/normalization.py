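"""Feature normalization: negative-control ratios and background levels.

Two stages, both per image (sample x field of view), both monotone in each
marker's features so the within-image ordering of cells is preserved:

1. **NC-ratio normalization** — for markers stained indirectly, every
   intensity feature is divided by the same cell's corresponding feature in
   the paired negative-control channel (bare secondary antibody), cancelling
   per-cell unspecific binding of the secondary.

2. **Background-level normalization** — for each marker and image, a
   background level ``b`` (the threshold separating signal from
   noise/background) is estimated from a mutually exclusive counterpart
   marker: cells strongly positive for the counterpart cannot genuinely
   express the marker, so the upper quantile of the marker's feature among
   those cells is background.  Dividing by ``b`` puts every marker in every
   image on a common background-relative scale (1.0 = background), which is
   simultaneously the batch correction across images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from melcpipe.features import INTENSITY_STATS, COMPARTMENTS

logger = logging.getLogger(__name__)


@dataclass
class NormalizationConfig:
    nc_pairs: dict[str, str] = field(default_factory=dict)  # marker -> NC channel
    exclusive_pairs: dict[str, str] = field(default_factory=dict)  # marker -> counterpart
    q_counterpart: float = 0.8  # quantile defining counterpart-positive cells
    q_background: float = 0.95  # quantile of marker feature among those cells
    reference_stat: str = "M20"
    reference_compartment: str = "cytomem"
    min_reference_cells: int = 20
    eps: float = 1e-6

    def __post_init__(self) -> None:
        for q in (self.q_counterpart, self.q_background):
            if not 0 < q < 1:
                raise ValueError("quantiles must be in (0, 1)")
        if self.reference_stat not in INTENSITY_STATS:
            raise ValueError(f"unknown reference stat {self.reference_stat!r}")
        if self.reference_compartment not in COMPARTMENTS:
            raise ValueError(f"unknown reference compartment {self.reference_compartment!r}")

    def reference_column(self, marker: str) -> str:
        return f"{marker}_{self.reference_stat}_{self.reference_compartment}"


def _marker_intensity_columns(df: pd.DataFrame, marker: str) -> list[str]:
    cols = [
        f"{marker}_{stat}_{comp}"
        for stat in INTENSITY_STATS
        for comp in COMPARTMENTS
    ]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"feature table lacks columns {missing}")
    return cols


def nc_ratio_normalize(table: pd.DataFrame, config: NormalizationConfig) -> pd.DataFrame:
    """Divide each NC-paired marker's intensity features by the cell's NC features.

    Morphology and unpaired markers are untouched; NC columns are dropped
    after use.  Cells whose NC feature is zero anywhere are flagged in a
    boolean ``nc_zero`` column (the eps guard keeps the ratio finite).
    """
    out = table.copy()
    nc_zero = np.zeros(len(out), dtype=bool)
    for marker, nc in config.nc_pairs.items():
        m_cols = _marker_intensity_columns(out, marker)
        try:
            nc_cols = _marker_intensity_columns(out, nc)
        except KeyError as err:
            raise KeyError(f"negative-control channel {nc!r} for {marker!r}: {err}") from err
        nc_vals = out[nc_cols].to_numpy(dtype=np.float64)
        nc_zero |= (nc_vals == 0).any(axis=1)
        out[m_cols] = out[m_cols].to_numpy(dtype=np.float64) / (nc_vals + config.eps)
    drop = sorted(
        {c for nc in config.nc_pairs.values() for c in _marker_intensity_columns(out, nc)}
    )
    out = out.drop(columns=drop)
    out["nc_zero"] = nc_zero
    return out


@dataclass
class BackgroundLevels:
    """Per (sample, fov, marker) background threshold; a flag marks markers
    whose reference population was degenerate or missing."""

    levels: pd.DataFrame  # sample_id, fov_id, marker, level, flagged

    def lookup(self, sample_id: str, fov_id: str, marker: str) -> float | None:
        sel = self.levels[
            (self.levels.sample_id == sample_id)
            & (self.levels.fov_id == fov_id)
            & (self.levels.marker == marker)
        ]
        if sel.empty:
            return None
        return float(sel.level.iloc[0])


def estimate_background_levels(
    table: pd.DataFrame, config: NormalizationConfig
) -> BackgroundLevels:
    """Estimate one background level per (image, marker) from exclusive counterparts.

    Counterpart-positive cells are those above quantile ``q_counterpart`` of
    the counterpart marker's reference feature within the image; the level is
    quantile ``q_background`` of the marker's reference feature among them.
    Markers with too few counterpart-positive cells are skipped with a
    warning and later pass through unnormalized.
    """
    rows = []
    for (sample_id, fov_id), img in table.groupby(["sample_id", "fov_id"], sort=True):
        for marker, counterpart in config.exclusive_pairs.items():
            ref_col = config.reference_column(marker)
            cp_col = config.reference_column(counterpart)
            if ref_col not in img.columns or cp_col not in img.columns:
                raise KeyError(f"reference columns missing for {marker!r}/{counterpart!r}")
            cp = img[cp_col].to_numpy(dtype=np.float64)
            thr = np.quantile(cp, config.q_counterpart)
            positive = img[cp > thr]
            if len(positive) < config.min_reference_cells:
                logger.warning(
                    "insufficient mutually-exclusive reference population for %s in %s/%s "
                    "(%d cells); marker passes through unnormalized",
                    marker,
                    sample_id,
                    fov_id,
                    len(positive),
                )
                continue
            level = float(np.quantile(positive[ref_col].to_numpy(dtype=np.float64), config.q_background))
            flagged = level <= 0
            if flagged:
                level = config.eps
            rows.append(
                {
                    "sample_id": sample_id,
                    "fov_id": fov_id,
                    "marker": marker,
                    "level": level,
                    "flagged": flagged,
                }
            )
    return BackgroundLevels(
        pd.DataFrame(rows, columns=["sample_id", "fov_id", "marker", "level", "flagged"])
    )


def apply_background_normalization(
    table: pd.DataFrame, levels: BackgroundLevels
) -> pd.DataFrame:
    """Divide each marker's intensity features by its image's background level.

    After division, 1.0 means "at background".  Markers without a level for
    their image (no exclusive pair, or insufficient reference population)
    pass through unchanged with a warning.
    """
    out = table.copy()
    markers_with_levels = set(levels.levels.marker.unique())
    for (sample_id, fov_id), idx in out.groupby(["sample_id", "fov_id"], sort=False).groups.items():
        for marker in markers_with_levels:
            b = levels.lookup(sample_id, fov_id, marker)
            if b is None:
                logger.warning(
                    "no background level for %s in %s/%s; passing through", marker, sample_id, fov_id
                )
                continue
            cols = _marker_intensity_columns(out, marker)
            out.loc[idx, cols] = out.loc[idx, cols].to_numpy(dtype=np.float64) / b
    return out
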