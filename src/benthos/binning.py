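"""Shared latitude/depth binning conventions.

Latitude bins are half-open one-degree intervals ``[b, b + 1)`` labelled by
their southern edge ``b`` (an integer).  Depth bins are half-open
``[top, bottom)`` intervals, positive metres down, with the single exception
that the deepest bin is closed at its bottom edge so the domain maximum
(6,000 m by default) still falls inside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical depth strata: shallow shelf, upper bathyal, lower bathyal + abyssal.
STRATA: dict[str, tuple[float, float]] = {
    "shallow": (0.0, 200.0),
    "bathyal": (200.0, 2000.0),
    "abyssal": (2000.0, 6000.0),
}

#: Per-stratum bin widths (m) used for the richness surfaces.
STRATUM_WIDTHS: dict[str, float] = {"shallow": 10.0, "bathyal": 50.0, "abyssal": 200.0}

#: Tropic / polar circle latitudes bounding the climate bands.
TROPIC_LAT = 23.4
POLAR_LAT = 66.5


def lat_bins(lat_min: float, lat_max: float) -> np.ndarray:
    """Integer southern edges of the 1-degree bins covering [lat_min, lat_max)."""
    return np.arange(int(np.floor(lat_min)), int(np.ceil(lat_max)), dtype=int)


def lat_bin_of(lat):
    """Bin label (southern edge) containing latitude ``lat``."""
    return np.floor(np.asarray(lat)).astype(int)


def climate_band(lat_bin) -> np.ndarray:
    """Classify bins by their centre: tropical (<23.4), temperate, polar (>66.5)."""
    centre = np.abs(np.asarray(lat_bin, dtype=float) + 0.5)
    out = np.where(centre < TROPIC_LAT, "tropical",
                   np.where(centre <= POLAR_LAT, "temperate", "polar"))
    return out


@dataclass(frozen=True)
class DepthBins:
    """An ordered set of half-open depth bins defined by their edges."""

    edges: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("depth bin edges must be a strictly increasing 1-D array")
        object.__setattr__(self, "edges", e)

    @classmethod
    def stratified(cls, widths: dict[str, float] | None = None,
                   strata: dict[str, tuple[float, float]] | None = None) -> "DepthBins":
        """10/50/200-m bins over the shallow/bathyal/abyssal strata."""
        widths = widths or STRATUM_WIDTHS
        strata = strata or STRATA
        edges = [0.0]
        for name, (top, bottom) in strata.items():
            w = widths[name]
            edges.extend(np.arange(top + w, bottom + w / 2, w))
        return cls(np.asarray(edges))

    @classmethod
    def uniform(cls, width: float = 100.0, depth_max: float = 6000.0) -> "DepthBins":
        return cls(np.arange(0.0, depth_max + width / 2, width))

    def __len__(self) -> int:
        return self.edges.size - 1

    @property
    def tops(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def bottoms(self) -> np.ndarray:
        return self.edges[1:]

    @property
    def mids(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def index_of(self, depth) -> np.ndarray:
        """Bin index containing each depth (half-open; domain bottom closed)."""
        d = np.asarray(depth, dtype=float)
        idx = np.searchsorted(self.edges, d, side="right") - 1
        idx = np.where(d == self.edges[-1], len(self) - 1, idx)
        if np.any((idx < 0) | (idx >= len(self))):
            raise ValueError("depth outside the binned domain")
        return idx

    def interval_mask(self, depth_min: float, depth_max: float) -> np.ndarray:
        """Boolean mask of bins intersecting the closed interval [depth_min, depth_max].

        The interval is treated as ``[depth_min, depth_max)`` so that a range
        ending exactly on a bin edge does not bleed into the next bin (a
        0-100 m species occupies ten 10-m bins, not eleven); a degenerate
        point range falls in the single bin containing it.
        """
        if depth_max < depth_min:
            return np.zeros(len(self), dtype=bool)
        mask = (self.tops < depth_max) & (self.bottoms > depth_min)
        if not mask.any():
            mask = mask.copy()
            mask[self.index_of(min(depth_min, self.edges[-1]))] = True
        return mask

    def stratum_mask(self, name: str, strata: dict[str, tuple[float, float]] | None = None
                     ) -> np.ndarray:
        top, bottom = (strata or STRATA)[name]
        return (self.tops >= top) & (self.tops < bottom)
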