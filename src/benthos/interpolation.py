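"""Raw and informed-interpolated species occupancy over latitude x depth.

The raw flavour marks a species present only at latitudes holding at least
one record, continuous through its bathymetric limits there.  The informed
interpolation fills latitudinal gaps between occurrences, but only across
latitudes that are plausible for the species: a candidate latitude is
occupied iff

(a) it does not fall inside a catalogued disjunction (e.g. anti-tropical)
    band,
(b) the latitude's sea-floor depth envelope overlaps the species' catalogued
    bathymetric limits, and
(c) no blocked latitude separates it from an observed one -- blocked
    latitudes split the candidate span into segments, and segments without
    any observation are discarded rather than bridged.

Observed latitudes are always retained: a physical record outranks the
plausibility rules, which exist only to gate gap-filling.  Within an occupied
latitude the species occupies every depth bin of its bathymetric limits that
lies above the local envelope maximum.  Longitude is collapsed: envelopes are
taken over the species' observed longitudinal extent (padded one degree) and
no longitudinal occupancy is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bathymetry import CellEnvelopes
from .binning import DepthBins, lat_bin_of
from .occurrences import Catalogue, CatalogueEntry

log = logging.getLogger(__name__)

LON_PAD = 1.0  # degrees added to each side of a species' observed lon extent


@dataclass
class SpeciesRange:
    """One species' observed extents plus its catalogue constraints."""

    species_id: str
    observed_lat_bins: np.ndarray            # sorted unique integer bins
    observed_lon_extent: tuple[float, float]
    observed_depth_extent: tuple[float, float] | None
    catalogue: CatalogueEntry

    def depth_interval(self) -> tuple[float, float]:
        """Catalogued limits; shallow-flagged 0-10 m; else union of record depths."""
        dr = self.catalogue.depth_interval()
        if dr is not None:
            return dr
        if self.observed_depth_extent is not None:
            return self.observed_depth_extent
        raise ValueError(f"{self.species_id}: no depth information available")


def ranges_from_records(records: pd.DataFrame, catalogue: Catalogue
                        ) -> list[SpeciesRange]:
    """Build per-species ranges from validated records."""
    out = []
    for sid, grp in records.groupby("species_id", sort=True):
        if sid not in catalogue:
            raise KeyError(f"species {sid!r} missing from catalogue")
        depths = grp["depth_m"].to_numpy(float)
        depths = depths[np.isfinite(depths)]
        out.append(SpeciesRange(
            species_id=str(sid),
            observed_lat_bins=np.unique(lat_bin_of(grp["decimalLatitude"].to_numpy())),
            observed_lon_extent=(float(grp["decimalLongitude"].min()),
                                 float(grp["decimalLongitude"].max())),
            observed_depth_extent=(float(depths.min()), float(depths.max()))
            if depths.size else None,
            catalogue=catalogue[sid],
        ))
    return out


@dataclass
class OccupancyCube:
    """Boolean species x latitude-bin x depth-bin presence array."""

    presence: np.ndarray                     # (S, L, D) bool
    species_ids: list[str]
    lat_bins: np.ndarray
    depth_bins: DepthBins
    flavour: str = "raw"                     # raw | interpolated

    def __post_init__(self):
        S, L, D = self.presence.shape
        if S != len(self.species_ids) or L != self.lat_bins.size or D != len(self.depth_bins):
            raise ValueError("presence shape does not match axes")

    def to_triplets(self) -> pd.DataFrame:
        s, l, d = np.nonzero(self.presence)
        return pd.DataFrame({
            "species_id": np.asarray(self.species_ids, dtype=object)[s],
            "lat_bin": self.lat_bins[l],
            "depth_bin": d,
        })

    @classmethod
    def from_triplets(cls, df: pd.DataFrame, species_ids, lat_bins,
                      depth_bins: DepthBins, flavour: str) -> "OccupancyCube":
        species_ids = list(species_ids)
        sindex = {s: i for i, s in enumerate(species_ids)}
        lindex = {b: i for i, b in enumerate(np.asarray(lat_bins))}
        pres = np.zeros((len(species_ids), len(lindex), len(depth_bins)), dtype=bool)
        for sid, lb, db in df[["species_id", "lat_bin", "depth_bin"]].itertuples(index=False):
            pres[sindex[sid], lindex[int(lb)], int(db)] = True
        return cls(pres, species_ids, np.asarray(lat_bins), depth_bins, flavour)


# --------------------------------------------------------------------------- #
# envelope access per species
# --------------------------------------------------------------------------- #
def _species_envelope(envs: CellEnvelopes, rng: SpeciesRange,
                      lon_range: str = "species") -> pd.DataFrame:
    """Per-latitude envelope gating one species.

    ``lon_range='species'`` restricts to the observed longitudinal extent
    padded one degree (the default reading of an informed gate);
    ``'all'`` uses the full domain.
    """
    if lon_range == "all":
        return envs.latitude_envelope(None)
    lo, hi = rng.observed_lon_extent
    return envs.latitude_envelope((lo - LON_PAD, hi + LON_PAD))


def _depth_cells(depth_bins: DepthBins, interval: tuple[float, float],
                 env_max: float) -> np.ndarray:
    """Depth-bin mask: catalogued interval clipped at the envelope maximum."""
    lo, hi = interval
    if not np.isfinite(env_max):          # no sea in the envelope
        return np.zeros(len(depth_bins), dtype=bool)
    hi = min(hi, env_max)
    if hi < lo:
        return np.zeros(len(depth_bins), dtype=bool)
    return depth_bins.interval_mask(lo, hi)


# --------------------------------------------------------------------------- #
# raw occupancy
# --------------------------------------------------------------------------- #
def raw_occupancy(records: pd.DataFrame, catalogue: Catalogue,
                  envs: CellEnvelopes, depth_bins: DepthBins,
                  lat_bins: np.ndarray | None = None,
                  lon_range: str = "species") -> OccupancyCube:
    """Presence only at latitudes with records, continuous in depth there."""
    ranges = ranges_from_records(records, catalogue)
    lat_bins = envs.lat_bins if lat_bins is None else np.asarray(lat_bins)
    lindex = {b: i for i, b in enumerate(lat_bins)}
    pres = np.zeros((len(ranges), lat_bins.size, len(depth_bins)), dtype=bool)
    for si, rng in enumerate(ranges):
        env = _species_envelope(envs, rng, lon_range)
        interval = rng.depth_interval()
        for b in rng.observed_lat_bins:
            if b not in lindex:
                continue
            emax = float(env["max_depth_m"].get(b, np.nan))
            pres[si, lindex[b]] = _depth_cells(depth_bins, interval, emax)
    return OccupancyCube(pres, [r.species_id for r in ranges], lat_bins,
                         depth_bins, flavour="raw")


# --------------------------------------------------------------------------- #
# informed interpolation
# --------------------------------------------------------------------------- #
def occupied_latitudes(rng: SpeciesRange, env: pd.DataFrame) -> np.ndarray:
    """Integer latitude bins occupied after applying rules (a)-(c)."""
    obs = np.asarray(rng.observed_lat_bins, dtype=int)
    if obs.size == 0:
        raise ValueError(f"{rng.species_id}: no observed latitude bins")
    lat_lo, lat_hi = rng.catalogue.lat_min, rng.catalogue.lat_max
    cands = np.arange(obs.min(), obs.max() + 1)
    # a candidate bin must intersect the catalogued latitudinal limits
    cands = cands[(cands < lat_hi) & (cands + 1 > lat_lo)]
    if cands.size == 0:
        return obs.copy()
    interval = rng.depth_interval()
    obs_set = set(obs.tolist())

    def blocked(b: int) -> bool:
        centre = b + 0.5
        if any(lo < centre < hi for lo, hi in rng.catalogue.exclusion_bands):
            return True
        if b not in env.index:
            return True
        row = env.loc[b]
        if not bool(row["has_sea"]):
            return True
        return not (row["min_depth_m"] <= interval[1]
                    and row["max_depth_m"] >= interval[0])

    occupied = []
    segment: list[int] = []
    seg_has_obs = False

    def flush():
        nonlocal segment, seg_has_obs
        if seg_has_obs:
            occupied.extend(segment)
        segment, seg_has_obs = [], False

    for b in cands:
        if int(b) in obs_set:                # observation outranks the gate
            segment.append(int(b))
            seg_has_obs = True
        elif blocked(int(b)):
            flush()
        else:
            segment.append(int(b))
    flush()
    return np.unique(np.concatenate([np.asarray(occupied, dtype=int), obs]))


def interpolate_species(rng: SpeciesRange, env: pd.DataFrame,
                        depth_bins: DepthBins, lat_bins: np.ndarray
                        ) -> np.ndarray:
    """(L, D) boolean occupancy for one species given a per-latitude envelope
    frame (columns ``min_depth_m``, ``max_depth_m``, ``has_sea``)."""
    lat_bins = np.asarray(lat_bins)
    lindex = {int(b): i for i, b in enumerate(lat_bins)}
    out = np.zeros((lat_bins.size, len(depth_bins)), dtype=bool)
    interval = rng.depth_interval()
    for b in occupied_latitudes(rng, env):
        if int(b) not in lindex:
            continue
        emax = float(env["max_depth_m"].get(int(b), np.nan))
        out[lindex[int(b)]] = _depth_cells(depth_bins, interval, emax)
    return out


def informed_interpolate(rng: SpeciesRange, envs: CellEnvelopes,
                         depth_bins: DepthBins,
                         lat_bins: np.ndarray | None = None,
                         lon_range: str = "species") -> np.ndarray:
    """(L, D) boolean occupancy for one species under informed interpolation."""
    lat_bins = envs.lat_bins if lat_bins is None else np.asarray(lat_bins)
    env = _species_envelope(envs, rng, lon_range)
    return interpolate_species(rng, env, depth_bins, lat_bins)


def build_interpolated_cube(ranges: list[SpeciesRange], envs: CellEnvelopes,
                            depth_bins: DepthBins,
                            lat_bins: np.ndarray | None = None,
                            lon_range: str = "species") -> OccupancyCube:
    lat_bins = envs.lat_bins if lat_bins is None else np.asarray(lat_bins)
    pres = np.zeros((len(ranges), lat_bins.size, len(depth_bins)), dtype=bool)
    for si, rng in enumerate(ranges):
        pres[si] = informed_interpolate(rng, envs, depth_bins, lat_bins, lon_range)
    return OccupancyCube(pres, [r.species_id for r in ranges], lat_bins,
                         depth_bins, flavour="interpolated")


def interpolated_cube_from_records(records: pd.DataFrame, catalogue: Catalogue,
                                   envs: CellEnvelopes, depth_bins: DepthBins,
                                   **kw) -> OccupancyCube:
    return build_interpolated_cube(ranges_from_records(records, catalogue),
                                   envs, depth_bins, **kw)


# --------------------------------------------------------------------------- #
# regional clipping
# --------------------------------------------------------------------------- #
def clip_to_region(records: pd.DataFrame, catalogue: Catalogue, region: str,
                   region_mask, envs: CellEnvelopes, depth_bins: DepthBins,
                   flavour: str = "interpolated") -> OccupancyCube:
    """Recompute occupancy using only one region's records and limits.

    ``region_mask`` is any object with a vectorised ``contains(lat, lon)``
    (see :class:`benthos.environment.RegionMask`).  Species are kept when the
    catalogue lists them for the region (or as cross-regional); their
    latitudinal limits are swapped for the region-specific ones when the
    catalogue provides them.
    """
    if region is None:
        if flavour == "raw":
            return raw_occupancy(records, catalogue, envs, depth_bins)
        return interpolated_cube_from_records(records, catalogue, envs, depth_bins)
    inside = region_mask.contains(records["decimalLatitude"].to_numpy(float),
                                  records["decimalLongitude"].to_numpy(float))
    sub = records.loc[inside]
    regional = Catalogue()
    for sid, e in catalogue.items():
        if e.regions and region not in e.regions and "cross-regional" not in e.regions:
            continue
        lo, hi = e.lat_limits_for(region)
        bands = tuple((max(b0, lo), min(b1, hi)) for b0, b1 in e.exclusion_bands
                      if b0 < hi and b1 > lo)
        regional[sid] = CatalogueEntry(
            species_id=e.species_id, genus=e.genus, family=e.family,
            depth_min_m=e.depth_min_m, depth_max_m=e.depth_max_m,
            lat_min=lo, lat_max=hi, regions=e.regions, exclusion_bands=bands,
            shallow_flag=e.shallow_flag, region_lat_limits=e.region_lat_limits)
    sub = sub.loc[sub["species_id"].isin(regional)]
    if sub.empty:
        return OccupancyCube(np.zeros((0, envs.lat_bins.size, len(depth_bins)), bool),
                             [], envs.lat_bins, depth_bins, flavour)
    if flavour == "raw":
        return raw_occupancy(sub, regional, envs, depth_bins)
    return interpolated_cube_from_records(sub, regional, envs, depth_bins)
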