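"""Latitude x depth richness surfaces, effort grids and uncertainty maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import STRATA, DepthBins, climate_band, lat_bin_of
from .interpolation import OccupancyCube


@dataclass
class LatDepthGrid:
    """A 2-D latitude x depth grid of counts or values."""

    values: np.ndarray          # (L, D)
    lat_bins: np.ndarray
    depth_bins: DepthBins
    kind: str = "richness"      # richness | effort | percent | environment

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (self.lat_bins.size, len(self.depth_bins)):
            raise ValueError("grid shape does not match axes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values,
                            index=pd.Index(self.lat_bins, name="lat_bin"),
                            columns=pd.Index(self.depth_bins.tops, name="depth_top_m"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def richness(cube: OccupancyCube) -> LatDepthGrid:
    """Number of species present per (latitude, depth) cell."""
    counts = cube.presence.sum(axis=0).astype(int)
    return LatDepthGrid(counts, cube.lat_bins, cube.depth_bins, kind="richness")


def latitudinal_curve(grid: LatDepthGrid, depth_m: float) -> pd.Series:
    """Richness against latitude at the depth bin containing ``depth_m``."""
    d = int(grid.depth_bins.index_of(depth_m))
    return pd.Series(grid.values[:, d], index=pd.Index(grid.lat_bins, name="lat_bin"),
                     name=f"depth_{grid.depth_bins.tops[d]:.0f}m")


def effort_grid(records: pd.DataFrame, lat_bins: np.ndarray,
                depth_bins: DepthBins | None = None) -> LatDepthGrid:
    """Record counts per 1-degree x 100-m cell (depths must be resolved)."""
    depth_bins = depth_bins or DepthBins.uniform(100.0)
    counts = np.zeros((lat_bins.size, len(depth_bins)))
    d = records["depth_m"].to_numpy(float)
    if np.any(~np.isfinite(d)):
        raise ValueError("effort grid requires resolved depths")
    lb = lat_bin_of(records["decimalLatitude"].to_numpy(float))
    lindex = {b: i for i, b in enumerate(lat_bins)}
    ok = np.array([b in lindex for b in lb]) & (d >= depth_bins.edges[0]) \
        & (d <= depth_bins.edges[-1])
    li = np.array([lindex[b] for b in lb[ok]], dtype=int)
    di = depth_bins.index_of(d[ok])
    np.add.at(counts, (li, di), 1)
    return LatDepthGrid(counts, lat_bins, depth_bins, kind="effort")


def effort_offset(effort: LatDepthGrid) -> LatDepthGrid:
    """ln(count + 1): the log-effort offset used by the Poisson driver models."""
    return LatDepthGrid(np.log1p(effort.values), effort.lat_bins,
                        effort.depth_bins, kind="effort")


def interpolation_uncertainty(raw: LatDepthGrid, interp: LatDepthGrid) -> LatDepthGrid:
    """Percentage of each cell's interpolated richness not backed by records:
    100 x (interpolated - raw) / interpolated, 0 where nothing was interpolated."""
    if raw.values.shape != interp.values.shape:
        raise ValueError("raw and interpolated grids must share axes")
    r, i = raw.values.astype(float), interp.values.astype(float)
    if np.any(r > i):
        raise ValueError("raw richness exceeds interpolated richness somewhere")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(i > 0, 100.0 * (i - r) / i, 0.0)
    return LatDepthGrid(pct, raw.lat_bins, raw.depth_bins, kind="percent")


def stratum_decline(grid: LatDepthGrid, strata: dict | None = None,
                    statistic: str = "max") -> pd.DataFrame:
    """Percentage decline of per-band stratum richness between successive strata.

    Bands are tropical (|lat| < 23.4), temperate (23.4-66.5) and polar
    (> 66.5), pooled across hemispheres; the per-stratum summary is the
    band maximum over cells (``statistic='mean'`` switches to the mean).
    Empty bands yield NaN rather than zero.
    """
    strata = strata or STRATA
    bands = climate_band(grid.lat_bins)
    rows = []
    names = list(strata)
    for band in ("tropical", "temperate", "polar"):
        sel = bands == band
        summaries = {}
        for name in names:
            dmask = grid.depth_bins.stratum_mask(name, strata)
            block = grid.values[np.ix_(sel, dmask)]
            if block.size == 0:
                summaries[name] = np.nan
            else:
                summaries[name] = float(block.max() if statistic == "max"
                                        else block.mean())
        for a, b in zip(names[:-1], names[1:]):
            va, vb = summaries[a], summaries[b]
            decline = np.nan if (not np.isfinite(va) or va == 0
                                 or not np.isfinite(vb)) else 100.0 * (va - vb) / va
            rows.append({"band": band, "from": a, "to": b,
                         "from_value": va, "to_value": vb,
                         "decline_pct": decline})
    return pd.DataFrame(rows)
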