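"""Sea-floor environmental layers gridded to latitude x 100-m cells.

Environmental fields (temperature, salinity, oxygen, nitrate, silicate,
surface NPP) live on the bathymetry's node grid as *sea-floor* values.  Each
node contributes to the 1-degree x 100-m cell containing its sea-floor depth;
cell values are node means.  POC flux to the sea floor is derived from
surface NPP with a Martin-type power-law export curve, predictors are
screened for collinearity, and normalised per depth stratum ahead of the
driver models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bathymetry import BathymetryGrid
from .binning import STRATA, DepthBins, lat_bin_of

log = logging.getLogger(__name__)

ENV_VARIABLES = ["temperature", "salinity", "oxygen", "nitrate", "silicate", "npp"]

#: Power-law export defaults: open-ocean Martin exponent, 100-m reference depth.
MARTIN_B = 0.858
Z_REF = 100.0
EXPORT_RATIO = 0.1


@dataclass
class EnvFieldSet:
    """Node-aligned environmental fields on a bathymetry grid."""

    bathy: BathymetryGrid
    fields: dict                      # name -> (nlat, nlon) array
    threshold_temp: float | None = None

    def __post_init__(self):
        for name, arr in self.fields.items():
            if np.asarray(arr).shape != self.bathy.depth.shape:
                raise ValueError(f"field {name!r} does not match the bathymetry grid")


@dataclass
class RegionMask:
    """Named inclusion boxes, exclusion boxes and latitude caps."""

    name: str = "global"
    include: tuple = ()               # ((lat_lo, lat_hi, lon_lo, lon_hi), ...); empty = all
    exclude: tuple = ()               # e.g. a Mediterranean box
    lat_floor: float | None = None    # e.g. -50 to cut the Southern Ocean
    lat_ceiling: float | None = None

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if self.include:
            ok = np.zeros(lat.shape, dtype=bool)
            for la0, la1, lo0, lo1 in self.include:
                ok |= (lat >= la0) & (lat < la1) & (lon >= lo0) & (lon < lo1)
        else:
            ok = np.ones(lat.shape, dtype=bool)
        for la0, la1, lo0, lo1 in self.exclude:
            ok &= ~((lat >= la0) & (lat < la1) & (lon >= lo0) & (lon < lo1))
        if self.lat_floor is not None:
            ok &= lat >= self.lat_floor
        if self.lat_ceiling is not None:
            ok &= lat <= self.lat_ceiling
        return ok


def poc_export(npp, depth_m, b: float = MARTIN_B, z_ref: float = Z_REF,
               export_ratio: float = EXPORT_RATIO):
    """POC flux (g C m-2 yr-1) reaching ``depth_m``:
    ``export_ratio * NPP * (depth / z_ref) ** -b``; depths above the export
    reference are clamped to the reference value."""
    depth = np.asarray(depth_m, dtype=float)
    if np.any(depth < z_ref):
        log.warning("poc_export: depths above z_ref clamped to the export depth")
    depth = np.maximum(depth, z_ref)
    return export_ratio * np.asarray(npp, dtype=float) * (depth / z_ref) ** (-b)


def grid_environment(env: EnvFieldSet, mask: RegionMask | None = None,
                     depth_bins: DepthBins | None = None,
                     include_poc: bool = True, **poc_params) -> pd.DataFrame:
    """Average each field over sea-floor nodes per (lat_bin, depth_bin) cell.

    Cells with no contributing node are absent from the table rather than
    zero-filled.  POC flux is evaluated per node at its sea-floor depth, then
    averaged like the other fields.
    """
    bathy = env.bathy
    depth_bins = depth_bins or DepthBins.uniform(100.0)
    la, lo = np.meshgrid(bathy.lats, bathy.lons, indexing="ij")
    d = bathy.depth
    sea = (d > 0) & (d <= depth_bins.edges[-1])
    if mask is not None:
        sea &= mask.contains(la, lo)
    if not sea.any():
        cols = ["lat_bin", "depth_bin", "depth_mid_m", *ENV_VARIABLES]
        return pd.DataFrame(columns=cols + (["poc_flux"] if include_poc else []))
    data = {
        "lat_bin": lat_bin_of(la[sea]),
        "depth_bin": depth_bins.index_of(d[sea]),
    }
    for name in ENV_VARIABLES:
        if name in env.fields:
            data[name] = np.asarray(env.fields[name], dtype=float)[sea]
    if include_poc and "npp" in env.fields:
        data["poc_flux"] = poc_export(np.asarray(env.fields["npp"], float)[sea],
                                      d[sea], **poc_params)
    table = (pd.DataFrame(data)
             .groupby(["lat_bin", "depth_bin"], as_index=False).mean())
    table.insert(2, "depth_mid_m", depth_bins.mids[table["depth_bin"].to_numpy(int)])
    return table


def collinearity_screen(table: pd.DataFrame, predictors=None,
                        threshold: float = 0.7,
                        victim_priority=("silicate", "phosphate"),
                        ) -> tuple[list[str], pd.DataFrame]:
    """Drop one member of each strongly correlated predictor pair.

    Pairs with |Pearson r| strictly above ``threshold`` lose the first column
    on the victim priority list (silicate, then phosphate); pairs without a
    listed victim are reported but kept.  Constant columns cannot be screened
    and are flagged.
    """
    predictors = [c for c in (predictors or table.columns)]
    report_rows = []
    usable = []
    for c in predictors:
        if table[c].nunique() <= 1:
            report_rows.append({"var1": c, "var2": "", "r": np.nan,
                                "action": "constant_excluded"})
        else:
            usable.append(c)
    dropped: set[str] = set()
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            if a in dropped or b in dropped:
                continue
            r = float(np.corrcoef(table[a], table[b])[0, 1])
            if abs(r) > threshold:
                victim = next((v for v in victim_priority if v in (a, b)), None)
                if victim is not None:
                    dropped.add(victim)
                report_rows.append({"var1": a, "var2": b, "r": r,
                                    "action": f"dropped_{victim}" if victim
                                    else "flagged"})
    kept = [c for c in usable if c not in dropped]
    return kept, pd.DataFrame(report_rows, columns=["var1", "var2", "r", "action"])


def normalize_per_stratum(table: pd.DataFrame, predictors,
                          depth_bins: DepthBins | None = None,
                          strata: dict | None = None,
                          center_only: bool = False) -> pd.DataFrame:
    """Centre (and by default scale to unit SD) predictors within each stratum.

    The response and offset columns are never touched.  Zero-variance columns
    within a stratum are centred only.
    """
    strata = strata or STRATA
    depth_bins = depth_bins or DepthBins.uniform(100.0)
    out = table.copy()
    mids = depth_bins.mids[table["depth_bin"].to_numpy(int)]
    for name, (top, bottom) in strata.items():
        sel = (mids >= top) & (mids < bottom)
        if not sel.any():
            continue
        for c in predictors:
            x = out.loc[sel, c].to_numpy(float)
            x = x - x.mean()
            sd = x.std(ddof=0)
            if not center_only:
                if sd > 0:
                    x = x / sd
                else:
                    log.warning("normalize: %s constant within stratum %s", c, name)
            out.loc[sel, c] = x
    return out


def stratum_of(table: pd.DataFrame, depth_bins: DepthBins | None = None,
               strata: dict | None = None) -> pd.Series:
    """Stratum label per table row, from the depth-bin midpoints."""
    strata = strata or STRATA
    depth_bins = depth_bins or DepthBins.uniform(100.0)
    mids = depth_bins.mids[table["depth_bin"].to_numpy(int)]
    lab = np.full(len(table), "", dtype=object)
    for name, (top, bottom) in strata.items():
        lab[(mids >= top) & (mids < bottom)] = name
    lab[mids == list(strata.values())[-1][1]] = list(strata)[-1]
    return pd.Series(lab, index=table.index, name="stratum")
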