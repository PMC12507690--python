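"""Occurrence-record I/O, catalogue-based cleaning, and coverage reporting.

Records travel as a pandas DataFrame with Darwin-Core-like columns
``species_id, decimalLatitude, decimalLongitude, depth_m, source``; depth is
NaN when the collection event carried none.  Cleaning mirrors a
range-catalogue workflow: records are rejected when they fall outside a
species' described latitudinal limits, inside a known disjunction band,
outside its bathymetric limits, on land, or (after depth resolution) below
the hadal cutoff.  Every decision is tallied in a :class:`ValidationReport`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .bathymetry import BathymetryGrid

log = logging.getLogger(__name__)

RECORD_COLUMNS = ["species_id", "decimalLatitude", "decimalLongitude", "depth_m", "source"]

REGIONS = {"Atlantic", "IWP", "north/east Pacific", "Arctic", "Antarctic", "cross-regional"}


# --------------------------------------------------------------------------- #
# catalogue
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class CatalogueEntry:
    """Descriptive per-species constraints from the range catalogue."""

    species_id: str
    genus: str = ""
    family: str = ""
    depth_min_m: float = np.nan
    depth_max_m: float = np.nan
    lat_min: float = -90.0
    lat_max: float = 90.0
    regions: frozenset = frozenset()
    exclusion_bands: tuple = ()          # ((lo, hi), ...) degree intervals of absence
    shallow_flag: bool = False           # 'Intertidal'/'Shallow' -> generic 0-10 m
    region_lat_limits: tuple = ()        # ((region, lat_min, lat_max), ...)

    def __post_init__(self):
        if np.isfinite(self.depth_min_m) and np.isfinite(self.depth_max_m):
            if self.depth_min_m > self.depth_max_m:
                raise ValueError(f"{self.species_id}: depth_min > depth_max")
        if self.lat_min > self.lat_max:
            raise ValueError(f"{self.species_id}: lat_min > lat_max")
        for lo, hi in self.exclusion_bands:
            if not (self.lat_min <= lo < hi <= self.lat_max):
                raise ValueError(f"{self.species_id}: exclusion band outside lat limits")

    def depth_interval(self) -> tuple[float, float] | None:
        """Catalogued bathymetric limits; shallow-flagged species get 0-10 m."""
        if self.shallow_flag:
            return (0.0, 10.0)
        if np.isfinite(self.depth_min_m) and np.isfinite(self.depth_max_m):
            return (float(self.depth_min_m), float(self.depth_max_m))
        return None

    def lat_limits_for(self, region: str | None) -> tuple[float, float]:
        if region is not None:
            for name, lo, hi in self.region_lat_limits:
                if name == region:
                    return (lo, hi)
        return (self.lat_min, self.lat_max)


class Catalogue(dict):
    """Mapping species_id -> :class:`CatalogueEntry` with CSV round-trip."""

    @classmethod
    def from_entries(cls, entries) -> "Catalogue":
        return cls({e.species_id: e for e in entries})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.values():
            rows.append({
                "species_id": e.species_id, "genus": e.genus, "family": e.family,
                "depth_min_m": e.depth_min_m, "depth_max_m": e.depth_max_m,
                "lat_min": e.lat_min, "lat_max": e.lat_max,
                "regions": "|".join(sorted(e.regions)),
                "exclusion_bands": ";".join(f"{lo}:{hi}" for lo, hi in e.exclusion_bands),
                "shallow_flag": e.shallow_flag,
                "region_lat_limits": ";".join(
                    f"{r}:{lo}:{hi}" for r, lo, hi in e.region_lat_limits),
            })
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        # %.17g keeps the round trip lossless for float limits
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Catalogue":
        df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                         dtype={"species_id": str},
                         float_precision="round_trip")
        entries = []
        for row in df.itertuples(index=False):
            bands = tuple(
                tuple(float(x) for x in part.split(":"))
                for part in str(getattr(row, "exclusion_bands") or "").split(";") if part
            ) if isinstance(getattr(row, "exclusion_bands", ""), str) else ()
            rll = tuple(
                (p.rsplit(":", 2)[0], float(p.rsplit(":", 2)[1]), float(p.rsplit(":", 2)[2]))
                for p in str(getattr(row, "region_lat_limits") or "").split(";") if p
            ) if isinstance(getattr(row, "region_lat_limits", ""), str) else ()
            regions = frozenset(
                r for r in str(getattr(row, "regions") or "").split("|") if r)
            entries.append(CatalogueEntry(
                species_id=str(row.species_id),
                genus="" if pd.isna(row.genus) else str(row.genus),
                family="" if pd.isna(row.family) else str(row.family),
                depth_min_m=float(row.depth_min_m) if row.depth_min_m not in ("", None) and pd.notna(row.depth_min_m) else np.nan,
                depth_max_m=float(row.depth_max_m) if row.depth_max_m not in ("", None) and pd.notna(row.depth_max_m) else np.nan,
                lat_min=float(row.lat_min), lat_max=float(row.lat_max),
                regions=regions, exclusion_bands=bands,
                shallow_flag=str(row.shallow_flag) in ("True", "true", "1"),
                region_lat_limits=rll,
            ))
        return cls.from_entries(entries)


# --------------------------------------------------------------------------- #
# reading and simple filters
# --------------------------------------------------------------------------- #
def read_occurrences(path) -> pd.DataFrame:
    """Read an occurrence CSV, skipping malformed rows with a logged warning.

    Mandatory columns: species_id, decimalLatitude, decimalLongitude; depth_m
    and source are optional (missing depth stays NaN, missing source becomes
    "unknown").  Rows with non-finite or out-of-bounds coordinates, or a
    negative depth, are dropped and counted.
    """
    df = pd.read_csv(path, dtype={"species_id": str},
                     float_precision="round_trip")
    for col in ("species_id", "decimalLatitude", "decimalLongitude"):
        if col not in df.columns:
            raise ValueError(f"missing mandatory column: {col}")
    if "depth_m" not in df.columns:
        df["depth_m"] = np.nan
    if "source" not in df.columns:
        df["source"] = "unknown"
    df["decimalLatitude"] = pd.to_numeric(df["decimalLatitude"], errors="coerce")
    df["decimalLongitude"] = pd.to_numeric(df["decimalLongitude"], errors="coerce")
    df["depth_m"] = pd.to_numeric(df["depth_m"], errors="coerce")
    ok = (
        df["decimalLatitude"].between(-90, 90)
        & df["decimalLongitude"].ge(-180) & df["decimalLongitude"].lt(180)
        & (df["depth_m"].isna() | (df["depth_m"] >= 0))
        & df["species_id"].notna() & (df["species_id"] != "")
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("skipped %d malformed occurrence rows", n_bad)
    return df.loc[ok, RECORD_COLUMNS].reset_index(drop=True)


def filter_sources(records: pd.DataFrame, excluded_tags) -> pd.DataFrame:
    """Drop records whose source tag is excluded (e.g. citizen-science feeds)."""
    excluded = set(excluded_tags)
    if not excluded:
        return records.copy()
    return records.loc[~records["source"].isin(excluded)].reset_index(drop=True)


def trawl_midpoint(lat1, lon1, lat2, lon2) -> tuple[float, float]:
    """Great-circle midpoint of a trawl's start/end coordinates."""
    p1, p2 = np.radians([lat1, lat2]), np.radians([lon1, lon2])
    l1, l2 = np.radians(lon1), np.radians(lon2)
    v = np.array([np.cos(np.radians(lat1)) * np.cos(l1)
                  + np.cos(np.radians(lat2)) * np.cos(l2),
                  np.cos(np.radians(lat1)) * np.sin(l1)
                  + np.cos(np.radians(lat2)) * np.sin(l2),
                  np.sin(np.radians(lat1)) + np.sin(np.radians(lat2))])
    hyp = np.hypot(v[0], v[1])
    return (float(np.degrees(np.arctan2(v[2], hyp))),
            float(np.degrees(np.arctan2(v[1], v[0]))))


def collapse_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate events: same species, coordinates to 4 decimals,
    depth to 1 m (missing depths compare equal to each other only)."""
    key = pd.DataFrame({
        "s": records["species_id"],
        "la": records["decimalLatitude"].round(4),
        "lo": records["decimalLongitude"].round(4),
        "d": records["depth_m"].round(0),
    })
    keep = ~key.duplicated()
    return records.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------- #
# validation
# --------------------------------------------------------------------------- #
@dataclass
class ValidationReport:
    read: int = 0
    retained: int = 0
    rejected: dict = field(default_factory=dict)     # reason -> count
    per_source: dict = field(default_factory=dict)   # source -> {read, retained}

    def check(self) -> None:
        if self.retained + sum(self.rejected.values()) != self.read:
            raise AssertionError("validation tallies are not conserved")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def validate_against_catalogue(records: pd.DataFrame, catalogue: Catalogue,
                               bathy: BathymetryGrid | None = None,
                               depth_tolerance: float = 0.0,
                               ) -> tuple[pd.DataFrame, ValidationReport]:
    """Reject records violating the catalogue's described ranges.

    Checks, in order per record: species present in the catalogue; latitude
    inside [lat_min, lat_max] and outside every exclusion band; coordinate on
    sea (bathymetry > 0) when a grid is supplied; known depth within the
    catalogued bathymetric limits beyond ``depth_tolerance`` metres of slack.
    Records with no resolved depth pass the depth check.
    """
    if catalogue is None:
        raise ValueError("a range catalogue is required for validation")
    n = len(records)
    reason = np.full(n, "", dtype=object)

    lat = records["decimalLatitude"].to_numpy(float)
    lon = records["decimalLongitude"].to_numpy(float)
    depth = records["depth_m"].to_numpy(float)
    sids = records["species_id"].to_numpy(object)

    known = np.array([s in catalogue for s in sids])
    reason[~known] = "unknown_species"

    for i in np.nonzero(known)[0]:
        e = catalogue[sids[i]]
        if not (e.lat_min <= lat[i] <= e.lat_max) or any(
                lo < lat[i] < hi for lo, hi in e.exclusion_bands):
            reason[i] = "outside_lat_range"
    if bathy is not None:
        unresolved = reason == ""
        idx = np.nonzero(unresolved)[0]
        if idx.size:
            inside = bathy.inside(lat[idx], lon[idx])
            d = np.full(idx.size, np.nan)
            d[inside] = bathy.depth_at(lat[idx][inside], lon[idx][inside])
            on_land = inside & ~np.isfinite(d)
            reason[idx[on_land]] = "on_land"
    for i in np.nonzero(reason == "")[0]:
        if not np.isfinite(depth[i]):
            continue
        dr = catalogue[sids[i]].depth_interval()
        if dr is not None and not (dr[0] - depth_tolerance <= depth[i]
                                   <= dr[1] + depth_tolerance):
            reason[i] = "outside_depth_range"

    keep = reason == ""
    rejected: dict[str, int] = {}
    for r in reason[~keep]:
        rejected[r] = rejected.get(r, 0) + 1
    keep_s = pd.Series(keep, index=records.index)
    per_source = {}
    for src, grp in records.groupby("source"):
        per_source[str(src)] = {"read": int(len(grp)),
                                "retained": int(keep_s.loc[grp.index].sum())}
    report = ValidationReport(read=n, retained=int(keep.sum()),
                              rejected=rejected, per_source=per_source)
    report.check()
    return records.loc[keep].reset_index(drop=True), report


def impute_missing_depths(records: pd.DataFrame, bathy: BathymetryGrid) -> pd.DataFrame:
    """Fill missing depths from the nearest bathymetry node; flag imputations.

    Records over land or outside the grid keep a missing depth and are only
    flagged; records that arrived with a depth are untouched.
    """
    out = records.copy()
    out["depth_imputed"] = out.get("depth_imputed", False)
    missing = ~np.isfinite(out["depth_m"].to_numpy(float))
    idx = np.nonzero(missing)[0]
    if idx.size == 0:
        return out
    lat = out["decimalLatitude"].to_numpy(float)[idx]
    lon = out["decimalLongitude"].to_numpy(float)[idx]
    inside = bathy.inside(lat, lon)
    d = np.full(idx.size, np.nan)
    d[inside] = bathy.depth_at(lat[inside], lon[inside])
    good = np.isfinite(d)
    col_d = out.columns.get_loc("depth_m")
    col_f = out.columns.get_loc("depth_imputed")
    out.iloc[idx[good], col_d] = d[good]
    out.iloc[idx[good], col_f] = True
    n_fail = int((~good).sum())
    if n_fail:
        log.warning("could not impute depth for %d records (land or off-grid)", n_fail)
    return out


def remove_hadal(records: pd.DataFrame, cutoff: float = 6000.0) -> pd.DataFrame:
    """Drop records strictly deeper than the hadal cutoff (default 6,000 m)."""
    keep = ~(records["depth_m"] > cutoff)
    return records.loc[keep].reset_index(drop=True)


# --------------------------------------------------------------------------- #
# coverage arithmetic
# --------------------------------------------------------------------------- #
def percent(numerator: int, denominator: int) -> float:
    """Percentage to 1 decimal with half-up rounding (report convention)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def coverage_report(records: pd.DataFrame, catalogue: Catalogue) -> dict:
    """Counts and percentages of catalogue species/genera/families represented
    by at least one retained record."""
    if not catalogue:
        raise ValueError("empty catalogue")
    present = set(records["species_id"]) & set(catalogue)
    genera_all = {e.genus for e in catalogue.values() if e.genus}
    families_all = {e.family for e in catalogue.values() if e.family}
    genera = {catalogue[s].genus for s in present if catalogue[s].genus}
    families = {catalogue[s].family for s in present if catalogue[s].family}
    out = {
        "species": (len(present), len(catalogue)),
        "genera": (len(genera), len(genera_all)),
        "families": (len(families), len(families_all)),
    }
    return {
        level: {"count": c, "total": t,
                "percent": percent(c, t) if t else 0.0}
        for level, (c, t) in out.items()
    }


def coastline_ratio(north_km: float, south_km: float) -> float:
    """North:south tropical coastline-length ratio (habitat-complexity proxy)."""
    if south_km <= 0:
        raise ValueError("southern coastline length must be positive")
    return north_km / south_km
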