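"""Gridded sea floor and per-latitude depth envelopes.

The bathymetry is a regular node grid of sea-floor depths in positive metres
down; values <= 0 encode land.  The depth *envelope* of a latitude band is the
(min, max) sea-floor depth available inside it, estimated exactly as for the
richness surfaces: each 1-degree cell is subsampled with 100 equally spaced
interior points (a 10 x 10 lattice), each point takes the depth of its nearest
grid node, and sea points (depth > 0) contribute to the cell's min/max.
Envelopes gate the range interpolation: a species cannot be filled across a
latitude whose available sea floor misses its bathymetric limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LAND = np.nan  # sentinel returned by depth_at over land


@dataclass
class BathymetryGrid:
    """Regular lon/lat grid of sea-floor depths (positive down; <=0 land).

    Nodes sit at cell centres: ``lat[i] = lat_min + resolution * (i + 1/2)``.
    ``resolution`` must divide one degree evenly so 1-degree bins align with
    whole node rows/columns.
    """

    depth: np.ndarray          # (nlat, nlon)
    lat_min: float
    lon_min: float
    resolution: float

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2 or self.depth.size == 0:
            raise ValueError("depth must be a non-empty 2-D array")
        per_deg = 1.0 / self.resolution
        if abs(per_deg - round(per_deg)) > 1e-9:
            raise ValueError("resolution must divide 1 degree evenly")

    @property
    def nlat(self) -> int:
        return self.depth.shape[0]

    @property
    def nlon(self) -> int:
        return self.depth.shape[1]

    @property
    def lats(self) -> np.ndarray:
        return self.lat_min + self.resolution * (np.arange(self.nlat) + 0.5)

    @property
    def lons(self) -> np.ndarray:
        return self.lon_min + self.resolution * (np.arange(self.nlon) + 0.5)

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.resolution * self.nlat

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.resolution * self.nlon

    def _node_index(self, lat, lon):
        i = np.floor((np.asarray(lat, dtype=float) - self.lat_min) / self.resolution)
        j = np.floor((np.asarray(lon, dtype=float) - self.lon_min) / self.resolution)
        return i.astype(int), j.astype(int)

    def inside(self, lat, lon):
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return ((lat >= self.lat_min) & (lat < self.lat_max + 1e-12)
                & (lon >= self.lon_min) & (lon < self.lon_max + 1e-12))

    def depth_at(self, lat, lon):
        """Nearest-node sea-floor depth; NaN over land; error outside domain."""
        if not np.all(self.inside(lat, lon)):
            raise ValueError("coordinate outside bathymetry domain")
        i, j = self._node_index(lat, lon)
        i = np.clip(i, 0, self.nlat - 1)
        j = np.clip(j, 0, self.nlon - 1)
        d = self.depth[i, j]
        return np.where(d > 0, d, LAND)

    # ---- plain-text round trip -------------------------------------------
    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.depth, index=self.lats, columns=self.lons)
        df.index.name = "lat"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BathymetryGrid":
        df = pd.read_csv(path, index_col=0)
        lats = df.index.to_numpy(dtype=float)
        lons = df.columns.to_numpy(dtype=float)
        res = float(np.round(np.diff(lats).mean(), 9)) if lats.size > 1 else 1.0
        return cls(df.to_numpy(dtype=float), float(lats[0] - res / 2),
                   float(lons[0] - res / 2), res)


def _lattice_offsets(n: int = 10) -> np.ndarray:
    # interior offsets 0.05, 0.15, ..., 0.95 within a 1-degree cell
    return (np.arange(n) + 0.5) / n


def cell_envelope(grid: BathymetryGrid, lat_bin: int, lon_bin: int
                  ) -> tuple[float, float, bool]:
    """(min, max, has_sea) over a 10 x 10 point lattice inside one 1x1-deg cell."""
    if not (grid.lat_min - 1e-9 <= lat_bin and lat_bin + 1 <= grid.lat_max + 1e-9
            and grid.lon_min - 1e-9 <= lon_bin and lon_bin + 1 <= grid.lon_max + 1e-9):
        raise ValueError("cell outside bathymetry domain")
    off = _lattice_offsets()
    la, lo = np.meshgrid(lat_bin + off, lon_bin + off, indexing="ij")
    d = grid.depth_at(la.ravel(), lo.ravel())
    sea = d[np.isfinite(d)]
    if sea.size == 0:
        return (np.nan, np.nan, False)
    return (float(sea.min()), float(sea.max()), True)


@dataclass
class CellEnvelopes:
    """Precomputed per-cell envelopes for every 1x1-degree cell of a grid."""

    lat_bins: np.ndarray       # integer southern edges, ascending
    lon_bins: np.ndarray
    cmin: np.ndarray           # (nlat_bins, nlon_bins); NaN where no sea
    cmax: np.ndarray
    has_sea: np.ndarray        # bool

    @classmethod
    def from_grid(cls, grid: BathymetryGrid) -> "CellEnvelopes":
        lat_b = np.arange(int(round(grid.lat_min)), int(round(grid.lat_max)), dtype=int)
        lon_b = np.arange(int(round(grid.lon_min)), int(round(grid.lon_max)), dtype=int)
        off = _lattice_offsets()
        # all lattice points for all cells at once
        plat = (lat_b[:, None] + off[None, :]).ravel()           # nlat_bins*10
        plon = (lon_b[:, None] + off[None, :]).ravel()
        i = np.clip(np.floor((plat - grid.lat_min) / grid.resolution).astype(int),
                    0, grid.nlat - 1)
        j = np.clip(np.floor((plon - grid.lon_min) / grid.resolution).astype(int),
                    0, grid.nlon - 1)
        d = grid.depth[np.ix_(i, j)]                             # point depths
        d = d.reshape(lat_b.size, 10, lon_b.size, 10).transpose(0, 2, 1, 3)
        d = d.reshape(lat_b.size, lon_b.size, 100)
        sea = d > 0
        dm = np.where(sea, d, np.inf).min(axis=2)
        dM = np.where(sea, d, -np.inf).max(axis=2)
        any_sea = sea.any(axis=2)
        cmin = np.where(any_sea, dm, np.nan)
        cmax = np.where(any_sea, dM, np.nan)
        return cls(lat_b, lon_b, cmin, cmax, any_sea)

    def _lon_slice(self, lon_range: tuple[float, float] | None) -> slice:
        if lon_range is None:
            return slice(None)
        lo, hi = lon_range
        mask = (self.lon_bins + 1 > lo) & (self.lon_bins < hi)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            return slice(0, 0)
        return slice(idx[0], idx[-1] + 1)

    def latitude_envelope(self, lon_range: tuple[float, float] | None = None
                          ) -> pd.DataFrame:
        """Per-latitude (min, max, has_sea) aggregated over a longitude range."""
        s = self._lon_slice(lon_range)
        cmin, cmax, sea = self.cmin[:, s], self.cmax[:, s], self.has_sea[:, s]
        if cmin.shape[1] == 0:
            sea_any = np.zeros(self.lat_bins.size, dtype=bool)
            mn = np.full(self.lat_bins.size, np.nan)
            mx = mn.copy()
        else:
            sea_any = sea.any(axis=1)
            mn = np.min(np.where(sea, cmin, np.inf), axis=1)
            mx = np.max(np.where(sea, cmax, -np.inf), axis=1)
            mn = np.where(sea_any, mn, np.nan)
            mx = np.where(sea_any, mx, np.nan)
        return pd.DataFrame(
            {"min_depth_m": mn, "max_depth_m": mx, "has_sea": sea_any},
            index=pd.Index(self.lat_bins, name="lat_bin"),
        )


def latitude_envelope(grid: BathymetryGrid, lat_bin: int,
                      lon_range: tuple[float, float] | None = None
                      ) -> tuple[float, float, bool]:
    """Envelope of one latitude band, aggregated over a longitude range."""
    env = CellEnvelopes.from_grid(grid).latitude_envelope(lon_range)
    row = env.loc[lat_bin]
    return (float(row["min_depth_m"]), float(row["max_depth_m"]), bool(row["has_sea"]))
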