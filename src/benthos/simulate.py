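"""Synthetic benthic worlds with exported ground truth.

A *world* is a bathymetry grid with two wiggling continental margins and an
abyssal plain, sea-floor environmental fields (temperature falling with depth
and latitude toward a configurable cold regime, temperate-peaking NPP, a
water-mass salinity step, correlated nitrate/silicate), a species assemblage
drawn from latitudinal/bathymetric archetypes, and an effort-biased
occurrence sample concentrated on north-temperate shallow margins, with a
configurable share of depths withheld.  Everything is deterministic under the
configuration seed, and the generating truth (per-species latitudinal
intervals and depth limits, the thermal threshold) is exportable so each
downstream stage can be tested against known answers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bathymetry import BathymetryGrid, CellEnvelopes
from .binning import DepthBins, lat_bin_of, lat_bins as make_lat_bins
from .environment import EnvFieldSet, grid_environment
from .interpolation import SpeciesRange
from .occurrences import Catalogue, CatalogueEntry, RECORD_COLUMNS

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------- #
# configuration and archetypes
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class SpeciesArchetype:
    """A latitudinal/bathymetric range template."""

    name: str
    lat_center: float
    lat_spread: float
    depth_min: float
    depth_max: float
    antitropical_gap: tuple | None = None   # (lo, hi) degrees of absence

    def __post_init__(self):
        if self.depth_min >= self.depth_max:
            raise ValueError(f"{self.name}: depth_min must be < depth_max")


ARCHETYPES: dict[str, SpeciesArchetype] = {
    a.name: a for a in (
        SpeciesArchetype("shallow_tropical", 5.0, 22.0, 0.0, 150.0),
        SpeciesArchetype("shallow_antitropical", 38.0, 12.0, 0.0, 150.0,
                         antitropical_gap=(-23.0, 23.0)),
        SpeciesArchetype("bathyal_tropical", 0.0, 32.0, 200.0, 2000.0),
        SpeciesArchetype("bathyal_bimodal", 45.0, 14.0, 200.0, 2000.0,
                         antitropical_gap=(-15.0, 15.0)),
        SpeciesArchetype("abyssal_cosmopolitan", 0.0, 65.0, 2000.0, 6000.0),
        SpeciesArchetype("polar_endemic", -70.0, 7.0, 0.0, 1000.0),
    )
}

DEFAULT_MIX: dict[str, float] = {
    "shallow_tropical": 0.35, "shallow_antitropical": 0.10,
    "bathyal_tropical": 0.20, "bathyal_bimodal": 0.10,
    "abyssal_cosmopolitan": 0.15, "polar_endemic": 0.10,
}


@dataclass(frozen=True)
class WorldConfig:
    """Study-domain configuration for one synthetic world."""

    lat_min: float = -78.0
    lat_max: float = 82.0
    depth_max: float = 6000.0
    lon_count: int = 36            # number of 1-degree longitude columns
    resolution: float = 0.5        # bathymetry node spacing (degrees)
    n_species: int = 300
    archetype_mix: tuple = tuple(sorted(DEFAULT_MIX.items()))
    effort_bias: float = 1.0       # 0 = spatially uniform sampling
    missing_depth_fraction: float = 0.333
    total_samples: int = 12000
    threshold_temp: float = 1.5    # deg C; cold-regime placement
    flat_depth: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lat_min >= self.lat_max:
            raise ValueError("lat_min must be < lat_max")
        if self.depth_max <= 0:
            raise ValueError("depth_max must be positive")
        if self.lon_count <= 0:
            raise ValueError("lon_count must be positive")
        mix = dict(self.archetype_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype mix proportions must sum to 1")
        unknown = set(mix) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if not 0 <= self.missing_depth_fraction <= 1:
            raise ValueError("missing_depth_fraction must lie in [0, 1]")

    @property
    def mix(self) -> dict[str, float]:
        return dict(self.archetype_mix)

    def lat_bins(self) -> np.ndarray:
        return make_lat_bins(self.lat_min, self.lat_max)


@dataclass(frozen=True)
class TrueSpecies:
    """Ground-truth range for one synthetic species."""

    species_id: str
    archetype: str
    true_lat_intervals: tuple       # ((lo, hi), ...) disjoint, sorted, bin-aligned
    true_depth_interval: tuple      # (min_m, max_m)
    region_label: str = ""

    def __post_init__(self):
        iv = self.true_lat_intervals
        if not iv:
            raise ValueError(f"{self.species_id}: needs at least one interval")
        for (a0, a1), (b0, b1) in zip(iv, iv[1:]):
            if a1 > b0:
                raise ValueError(f"{self.species_id}: intervals overlap or unsorted")

    def lat_bin_set(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.true_lat_intervals:
            out.update(range(int(round(lo)), int(round(hi))))
        return out


# --------------------------------------------------------------------------- #
# bathymetry
# --------------------------------------------------------------------------- #
def _smooth_noise(rng, lat, lon, n_modes: int = 5, amp: float = 1.0):
    """Deterministic smooth random field as a sum of sinusoid products."""
    out = np.zeros((lat.size, lon.size))
    for _ in range(n_modes):
        fl, fo = rng.uniform(0.02, 0.12, 2)
        pl, po = rng.uniform(0, 2 * np.pi, 2)
        out += rng.normal(0, 1) * np.outer(np.sin(fl * lat + pl),
                                           np.sin(fo * lon + po))
    return amp * out / np.sqrt(n_modes)


def generate_bathymetry(config: WorldConfig) -> BathymetryGrid:
    """Two continental margins (shelf, slope) flanking an abyssal plain.

    Depth is positive metres down; land (<= 0) fills the area behind each
    wiggling coastline.  Latitudes north of 70 deg are progressively
    shallowed, mirroring the restricted deep-water area of an Arctic-like
    basin.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lats = np.arange(config.lat_min + config.resolution / 2, config.lat_max,
                     config.resolution)
    lons = np.arange(config.resolution / 2, config.lon_count, config.resolution)
    if config.flat_depth is not None:
        depth = np.full((lats.size, lons.size), float(config.flat_depth))
        return BathymetryGrid(depth, config.lat_min, 0.0, config.resolution)
    coast_w = 1.6 + 1.2 * np.sin(lats / 11.0) + 0.3 * np.sin(lats / 3.7)
    coast_e = config.lon_count - (1.6 + 1.2 * np.cos(lats / 9.0)
                                  + 0.3 * np.sin(lats / 5.1))
    x = np.minimum(lons[None, :] - coast_w[:, None],
                   coast_e[:, None] - lons[None, :])   # degrees seaward of coast
    depth = np.full(x.shape, -150.0)
    shelf = (x >= 0) & (x < 1)
    depth[shelf] = 5 + 190 * x[shelf]
    slope = (x >= 1) & (x < 3)
    depth[slope] = 200 + (x[slope] - 1) / 2 * 3800
    plain = x >= 3
    depth[plain] = 4200
    depth += np.where(x >= 0, _smooth_noise(rng, lats, lons, amp=250.0), 0.0)
    deep_sea = x >= 1.5
    depth[deep_sea] += 600 * np.broadcast_to(
        np.sin(lons / 4.3)[None, :] ** 2, x.shape)[deep_sea]
    # Arctic-like shallowing north of 70
    arctic = np.clip((lats - 70.0) / 12.0, 0, 1)
    depth *= np.where(depth > 0, 1 - 0.55 * arctic[:, None] ** 2, 1.0)
    depth = np.where(depth > 0, np.clip(depth, 1.0, config.depth_max), depth)
    return BathymetryGrid(depth, config.lat_min, 0.0, config.resolution)


# --------------------------------------------------------------------------- #
# environment
# --------------------------------------------------------------------------- #
def seafloor_temperature(lat, depth_m, threshold_temp: float = 1.5):
    """Temperature (deg C) at a sea-floor point: a latitudinal surface profile
    decaying exponentially with depth toward a deep-water value that drops
    below ``threshold_temp`` poleward of the polar fronts; floored at -1.9."""
    lat = np.asarray(lat, dtype=float)
    depth = np.asarray(depth_m, dtype=float)
    sst = -1.8 + 29.0 * np.cos(np.radians(lat)) ** 2
    s = np.clip((np.abs(lat) - 30.0) / 40.0, 0.0, 1.0)
    s = s * s * (3 - 2 * s)                       # smoothstep 30 -> 70 degrees
    t_deep = 3.8 + (threshold_temp - 1.2 - 3.8) * s
    t_deep = np.minimum(t_deep, sst)              # keep columns monotone
    return np.maximum(-1.9, t_deep + (sst - t_deep) * np.exp(-depth / 400.0))


def generate_environment(config: WorldConfig, bathy: BathymetryGrid,
                         threshold_temp: float | None = None) -> EnvFieldSet:
    """Sea-floor environmental fields on the bathymetry's node grid."""
    thr = config.threshold_temp if threshold_temp is None else threshold_temp
    if not -2.0 <= thr <= 30.0:
        raise ValueError("threshold_temp must lie in [-2, 30] deg C")
    rng = np.random.default_rng(config.seed + 1)
    la = bathy.lats[:, None] * np.ones_like(bathy.depth)
    d = np.maximum(bathy.depth, 0.0)
    sea = bathy.depth > 0

    temperature = seafloor_temperature(la, d, thr)
    npp = (150.0 + 280.0 * np.exp(-((np.abs(la) - 45.0) / 16.0) ** 2)
           + 60.0 * np.exp(-(la / 12.0) ** 2)
           + _smooth_noise(rng, bathy.lats, bathy.lons, amp=12.0))
    npp = np.clip(npp, 30.0, None)
    salinity = 34.2 + 0.6 * (la > 42.0) + 0.01 * _smooth_noise(
        rng, bathy.lats, bathy.lons)
    oxygen = (6.8 - 2.2 * np.exp(-((d - 700.0) / 500.0) ** 2)
              + 0.15 * _smooth_noise(rng, bathy.lats, bathy.lons))
    nitrate = (4.0 + 26.0 * (1 - np.exp(-d / 900.0)) + 0.08 * np.abs(la)
               + _smooth_noise(rng, bathy.lats, bathy.lons, amp=0.8))
    silicate = 1.9 * nitrate + _smooth_noise(rng, bathy.lats, bathy.lons, amp=3.0)
    fields = {"temperature": temperature, "salinity": salinity, "oxygen": oxygen,
              "nitrate": nitrate, "silicate": silicate, "npp": npp}
    for name, arr in fields.items():
        fields[name] = np.where(sea, arr, np.nan)
    return EnvFieldSet(bathy, fields, threshold_temp=thr)


# --------------------------------------------------------------------------- #
# assemblage
# --------------------------------------------------------------------------- #
def _bins_to_intervals(bins: np.ndarray) -> tuple:
    """Maximal runs of consecutive integer bins -> ((lo, hi), ...) degrees."""
    if bins.size == 0:
        return ()
    bins = np.sort(bins)
    breaks = np.nonzero(np.diff(bins) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [bins.size - 1]])
    return tuple((float(bins[s]), float(bins[e] + 1)) for s, e in zip(starts, ends))


def _draw_intervals(arch: SpeciesArchetype, rng, lat_lo: float, lat_hi: float):
    w = rng.uniform(0.4, 1.0) * arch.lat_spread
    if arch.antitropical_gap is not None:
        g0, g1 = arch.antitropical_gap
        cn = abs(arch.lat_center) + rng.normal(0, arch.lat_spread / 3)
        cs = -abs(arch.lat_center) + rng.normal(0, arch.lat_spread / 3)
        north = (max(g1, cn - w), min(lat_hi, max(g1 + 2, cn + w)))
        south = (max(lat_lo, min(g0 - 2, cs - w)), min(g0, cs + w))
        return [south, north]
    c = arch.lat_center + rng.normal(0, arch.lat_spread / 3)
    return [(max(lat_lo, c - w), min(lat_hi, c + w))]


def generate_assemblage(config: WorldConfig, bathy: BathymetryGrid
                        ) -> list[TrueSpecies]:
    """Draw the species assemblage and clip each range to habitable latitudes.

    A latitude bin is habitable for a species when the sea-floor envelope
    (over all longitudes) overlaps its bathymetric interval; anti-tropical
    archetypes produce two intervals flanking the gap.  A species whose range
    ends up empty is redrawn (warned after 100 retries).
    """
    rng = np.random.default_rng(config.seed + 2)
    env = CellEnvelopes.from_grid(bathy).latitude_envelope(None)
    lat_bins = config.lat_bins()
    env = env.reindex(lat_bins)
    names = sorted(config.mix)
    probs = np.array([config.mix[n] for n in names])
    out: list[TrueSpecies] = []
    for i in range(config.n_species):
        name = str(rng.choice(names, p=probs))
        arch = ARCHETYPES[name]
        sp = None
        for attempt in range(1000):
            dspan = arch.depth_max - arch.depth_min
            dmin = arch.depth_min + rng.uniform(0, 0.25 * dspan)
            dmax = arch.depth_max - rng.uniform(0, 0.25 * dspan)
            habitable = (env["has_sea"].to_numpy(bool)
                         & (env["min_depth_m"].to_numpy(float) <= dmax)
                         & (env["max_depth_m"].to_numpy(float) >= dmin))
            intervals = _draw_intervals(arch, rng, config.lat_min, config.lat_max)
            centres = lat_bins + 0.5
            in_range = np.zeros(lat_bins.size, dtype=bool)
            for lo, hi in intervals:
                in_range |= (centres >= lo) & (centres <= hi)
            bins = lat_bins[in_range & habitable]
            if bins.size:
                sp = TrueSpecies(
                    species_id=f"sp{i:04d}", archetype=name,
                    true_lat_intervals=_bins_to_intervals(bins),
                    true_depth_interval=(float(dmin), float(dmax)),
                    region_label=name)
                break
            if attempt == 100:
                log.warning("species %d (%s): 100 redraws without habitat", i, name)
        if sp is None:
            raise RuntimeError(f"no habitable range found for archetype {name}")
        out.append(sp)
    return out


# --------------------------------------------------------------------------- #
# occurrence sampling
# --------------------------------------------------------------------------- #
def _effort_weight(lat, depth, effort_bias: float):
    """Log-linear effort with a north-temperate shallow mode."""
    g = np.exp(-((np.asarray(lat, float) - 45.0) / 20.0) ** 2) \
        * np.exp(-np.asarray(depth, float) / 800.0)
    return np.exp(effort_bias * g)


def _species_node_masks(truth, bathy: BathymetryGrid):
    node_bins = lat_bin_of(bathy.lats)
    d = bathy.depth
    sea = d > 0
    for sp in truth:
        in_lat = np.isin(node_bins, list(sp.lat_bin_set()))
        lo, hi = sp.true_depth_interval
        yield sp, sea & in_lat[:, None] & (d >= lo) & (d <= hi)


def expected_effort(truth, bathy: BathymetryGrid, config: WorldConfig) -> np.ndarray:
    """Expected record count per bathymetry node; sums to ``total_samples``."""
    w = _effort_weight(bathy.lats[:, None] * np.ones_like(bathy.depth),
                       np.maximum(bathy.depth, 0), config.effort_bias)
    acc = np.zeros_like(bathy.depth)
    total_w = 0.0
    masks = []
    for _, mask in _species_node_masks(truth, bathy):
        masks.append(mask)
        total_w += float(w[mask].sum())
    for mask in masks:
        acc[mask] += w[mask]
    return config.total_samples * acc / total_w if total_w > 0 else acc


def sample_occurrences(truth, bathy: BathymetryGrid, config: WorldConfig,
                       rng=None) -> pd.DataFrame:
    """Effort-biased occurrence records drawn inside each species' true range.

    Records land on bathymetry nodes inside the species' latitudinal bins
    whose sea-floor depth falls in its bathymetric interval; coordinates are
    jittered within the node cell, the recorded depth is the node's sea-floor
    depth, and ``missing_depth_fraction`` of depths are withheld at random.
    """
    if not truth:
        raise ValueError("empty assemblage")
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    w = _effort_weight(bathy.lats[:, None] * np.ones_like(bathy.depth),
                       np.maximum(bathy.depth, 0), config.effort_bias)
    entries = [(sp, np.nonzero(mask)) for sp, mask in
               _species_node_masks(truth, bathy) if mask.any()]
    if not entries:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    weights = np.array([w[idx].sum() for _, idx in entries])
    counts = rng.multinomial(config.total_samples, weights / weights.sum())
    res = bathy.resolution
    frames = []
    for (sp, (ii, jj)), n in zip(entries, counts):
        if n == 0:
            continue
        p = w[ii, jj]
        pick = rng.choice(ii.size, size=n, p=p / p.sum())
        lat = bathy.lats[ii[pick]] + rng.uniform(-res / 2, res / 2, n) * 0.999
        lon = bathy.lons[jj[pick]] + rng.uniform(-res / 2, res / 2, n) * 0.999
        depth = bathy.depth[ii[pick], jj[pick]].astype(float)
        depth[rng.random(n) < config.missing_depth_fraction] = np.nan
        frames.append(pd.DataFrame({
            "species_id": sp.species_id, "decimalLatitude": lat,
            "decimalLongitude": lon, "depth_m": depth,
            "source": rng.choice(["obis", "gbif", "literature"], size=n,
                                 p=[0.60, 0.32, 0.08]),
        }))
    df = pd.concat(frames, ignore_index=True)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))
                     ).reset_index(drop=True)


# --------------------------------------------------------------------------- #
# truth export / catalogue
# --------------------------------------------------------------------------- #
def _intervals_str(iv) -> str:
    return ";".join(f"{lo!r}:{hi!r}" for lo, hi in iv)


def export_truth(truth, config: WorldConfig, out_dir) -> None:
    """Write truth CSV + config echo JSON; round-trips via :func:`load_truth`."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [{
        "species_id": sp.species_id, "archetype": sp.archetype,
        "lat_intervals": _intervals_str(sp.true_lat_intervals),
        "depth_min_m": sp.true_depth_interval[0],
        "depth_max_m": sp.true_depth_interval[1],
        "region_label": sp.region_label,
    } for sp in truth]
    pd.DataFrame(rows, columns=["species_id", "archetype", "lat_intervals",
                                "depth_min_m", "depth_max_m", "region_label"]
                 ).to_csv(out / "truth.csv", index=False)
    cfg = asdict(config)
    cfg["archetype_mix"] = dict(config.archetype_mix)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)


def load_truth(out_dir) -> tuple[list[TrueSpecies], WorldConfig]:
    from pathlib import Path
    out = Path(out_dir)
    df = pd.read_csv(out / "truth.csv", keep_default_na=False,
                     float_precision="round_trip")
    truth = []
    for row in df.itertuples(index=False):
        iv = tuple(tuple(float(x) for x in part.split(":"))
                   for part in str(row.lat_intervals).split(";") if part)
        truth.append(TrueSpecies(str(row.species_id), str(row.archetype), iv,
                                 (float(row.depth_min_m), float(row.depth_max_m)),
                                 str(row.region_label)))
    with open(out / "config.json") as fh:
        cfg = json.load(fh)
    cfg["archetype_mix"] = tuple(sorted(cfg["archetype_mix"].items()))
    cfg["flat_depth"] = cfg.get("flat_depth", None)
    return truth, WorldConfig(**cfg)


def catalogue_from_truth(truth, genus_size: int = 5, family_size: int = 25
                         ) -> Catalogue:
    """An exact descriptive catalogue for a synthetic assemblage: latitudinal
    limits spanning the true intervals, gaps as exclusion bands, true depth
    limits, and synthetic genus/family labels."""
    entries = []
    for i, sp in enumerate(truth):
        iv = sp.true_lat_intervals
        gaps = tuple((iv[k][1], iv[k + 1][0]) for k in range(len(iv) - 1))
        entries.append(CatalogueEntry(
            species_id=sp.species_id,
            genus=f"genus{i // genus_size:03d}",
            family=f"family{i // family_size:02d}",
            depth_min_m=sp.true_depth_interval[0],
            depth_max_m=sp.true_depth_interval[1],
            lat_min=iv[0][0], lat_max=iv[-1][1],
            regions=frozenset({"cross-regional"}),
            exclusion_bands=gaps,
        ))
    return Catalogue.from_entries(entries)


def plant_contaminants(truth, catalogue: Catalogue, bathy: BathymetryGrid,
                       rng, n_per_type: int = 10, n_hadal: int = 0
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Records that violate the catalogue in known ways, for cleaning tests.

    Returns the contaminant records and the rejection reason each should
    trigger (``outside_lat_range``, ``outside_depth_range``, ``on_land``);
    optional hadal records (> 6,000 m) carry the label ``hadal``.
    """
    rows, labels = [], []
    sids = list(catalogue)
    land = np.nonzero(bathy.depth <= 0)
    sea = np.nonzero(bathy.depth > 0)

    def base(sid):
        return {"species_id": sid, "source": "obis"}

    for _ in range(n_per_type):
        # latitude outside the catalogued limits
        for _try in range(200):
            e = catalogue[sids[rng.integers(len(sids))]]
            room_n = bathy.lat_max - e.lat_max
            room_s = e.lat_min - bathy.lat_min
            if max(room_n, room_s) > 1.5:
                if room_n >= room_s:
                    lat = e.lat_max + rng.uniform(1.0, min(room_n, 5.0))
                else:
                    lat = e.lat_min - rng.uniform(1.0, min(room_s, 5.0))
                rows.append({**base(e.species_id), "decimalLatitude": float(lat),
                             "decimalLongitude": float(rng.uniform(0, bathy.lon_max)),
                             "depth_m": np.nan})
                labels.append("outside_lat_range")
                break
    for _ in range(n_per_type):
        # depth outside the catalogued bathymetric limits
        for _try in range(200):
            e = catalogue[sids[rng.integers(len(sids))]]
            k = rng.integers(sea[0].size)
            la, lo = bathy.lats[sea[0][k]], bathy.lons[sea[1][k]]
            if e.lat_min <= la <= e.lat_max and not any(
                    b0 < la < b1 for b0, b1 in e.exclusion_bands):
                rows.append({**base(e.species_id), "decimalLatitude": float(la),
                             "decimalLongitude": float(lo),
                             "depth_m": float(e.depth_max_m + rng.uniform(200, 800))})
                labels.append("outside_depth_range")
                break
    for _ in range(n_per_type if land[0].size else 0):
        # coordinates on land
        for _try in range(200):
            e = catalogue[sids[rng.integers(len(sids))]]
            k = rng.integers(land[0].size)
            la, lo = bathy.lats[land[0][k]], bathy.lons[land[1][k]]
            if e.lat_min <= la <= e.lat_max and not any(
                    b0 < la < b1 for b0, b1 in e.exclusion_bands):
                rows.append({**base(e.species_id), "decimalLatitude": float(la),
                             "decimalLongitude": float(lo), "depth_m": np.nan})
                labels.append("on_land")
                break
    for _ in range(n_hadal):
        e = catalogue[sids[rng.integers(len(sids))]]
        la = np.clip(0.5 * (e.lat_min + e.lat_max), bathy.lat_min, bathy.lat_max - 1)
        rows.append({**base(e.species_id), "decimalLatitude": float(la),
                     "decimalLongitude": 1.0,
                     "depth_m": float(rng.uniform(6200, 8000))})
        labels.append("hadal")
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS) if rows else \
        pd.DataFrame(columns=RECORD_COLUMNS)
    return df, labels


# --------------------------------------------------------------------------- #
# assembled worlds and driver tables
# --------------------------------------------------------------------------- #
@dataclass
class World:
    config: WorldConfig
    bathy: BathymetryGrid
    env: EnvFieldSet
    truth: list
    catalogue: Catalogue
    records: pd.DataFrame


def make_world(config: WorldConfig | None = None, **overrides) -> World:
    """Generate a complete world (bathymetry, environment, assemblage, sample)."""
    config = config or WorldConfig(**overrides)
    bathy = generate_bathymetry(config)
    env = generate_environment(config, bathy)
    truth = generate_assemblage(config, bathy)
    records = sample_occurrences(truth, bathy, config)
    return World(config, bathy, env, truth, catalogue_from_truth(truth), records)


def synthesize_richness(table: pd.DataFrame, driver: str, rng,
                        threshold: float | None = None) -> pd.DataFrame:
    """Attach a Poisson richness response driven by a chosen mechanism.

    ``driver='temperature'`` / ``'poc'``: log-linear in the standardised
    driver.  ``driver='threshold'``: richness tracks POC flux only where
    temperature exceeds ``threshold`` (deg C), mimicking a cold-regime cap.
    """
    out = table.copy()

    def z(c):
        x = out[c].to_numpy(float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x * 0.0

    if driver == "temperature":
        mu = np.exp(2.2 + 0.8 * z("temperature"))
    elif driver == "poc":
        mu = np.exp(2.2 + 0.8 * z("poc_flux"))
    elif driver == "threshold":
        if threshold is None:
            raise ValueError("threshold driver needs a temperature threshold")
        p = out["poc_flux"].to_numpy(float)
        pn = (p - p.min()) / (p.max() - p.min() + 1e-12)
        mu = 2.0 + 28.0 * pn * (out["temperature"].to_numpy(float) > threshold)
    else:
        raise ValueError(f"unknown driver {driver!r}")
    out["richness"] = rng.poisson(mu)
    out["effort_offset"] = 0.0
    return out


def driver_cell_table(seed: int, threshold: float = 1.5,
                      config: WorldConfig | None = None) -> pd.DataFrame:
    """Environment cell table (1 deg x 100 m) of a fresh synthetic world."""
    config = config or WorldConfig(seed=seed, threshold_temp=threshold)
    if config.seed != seed or config.threshold_temp != threshold:
        config = WorldConfig(**{**asdict(config), "seed": seed,
                                "threshold_temp": threshold})
    bathy = generate_bathymetry(config)
    env = generate_environment(config, bathy)
    return grid_environment(env)


#: Predictor set used by the synthetic driver-recovery studies.
DRIVER_PREDICTORS = ["temperature", "poc_flux", "salinity", "oxygen", "nitrate"]


def stratum_driver_table(seed: int, threshold: float, stratum: str,
                         n_rows: int = 900) -> pd.DataFrame:
    """One stratum's cell table from a fresh world, capped at ``n_rows`` by an
    evenly spaced subset (keeps forest fits tractable without biasing the
    latitude/depth coverage)."""
    from .environment import stratum_of
    tab = driver_cell_table(seed, threshold)
    sub = tab[stratum_of(tab) == stratum].reset_index(drop=True)
    if len(sub) > n_rows:
        sub = sub.iloc[np.linspace(0, len(sub) - 1, n_rows).astype(int)]
        sub = sub.reset_index(drop=True)
    return sub


def recover_threshold(seed: int, threshold: float, n_rows: int = 900,
                      n_trees: int = 1000):
    """Full threshold-recovery trial: world -> abyssal cells -> threshold-driven
    richness -> forest -> temperature partial dependence -> breakpoint."""
    from .drivers import (partial_dependence, random_forest_importance,
                          threshold_estimate)
    rng = np.random.default_rng(seed + 7)
    tab = synthesize_richness(stratum_driver_table(seed, threshold, "abyssal",
                                                   n_rows),
                              "threshold", rng, threshold)
    forest = random_forest_importance(tab, "richness", DRIVER_PREDICTORS,
                                      n_trees=n_trees, seed=seed)
    curve = partial_dependence(forest.model, forest.X_train, "temperature",
                               step=0.1, sample_rows=250)
    return threshold_estimate(curve, n_boot=0)


def rank_drivers(seed: int, driver: str, stratum: str, n_rows: int = 900,
                 n_trees: int = 1000) -> pd.DataFrame:
    """Driver-ranking trial: world -> stratum cells -> driver-generated
    richness -> forest importance table (%IncMSE)."""
    from .drivers import random_forest_importance
    rng = np.random.default_rng(seed + 11)
    tab = synthesize_richness(stratum_driver_table(seed, 1.5, stratum, n_rows),
                              driver, rng)
    forest = random_forest_importance(tab, "richness", DRIVER_PREDICTORS,
                                      n_trees=n_trees, seed=seed)
    return forest.importance


# --------------------------------------------------------------------------- #
# small random worlds for oracle checks
# --------------------------------------------------------------------------- #
def random_interpolation_case(rng, max_species: int = 20, n_lat: int = 30,
                              n_depth: int = 20):
    """A random small interpolation problem: per-latitude envelopes plus
    species ranges with random observations, limits and disjunction bands.

    Returns ``(ranges, envelope_frame, depth_bins, lat_bins)`` suitable for
    :func:`benthos.interpolation.interpolate_species` and for a literal
    per-cell rule checker.
    """
    lat_bins = np.arange(n_lat)
    depth_bins = DepthBins(np.linspace(0, 6000, n_depth + 1))
    has_sea = rng.random(n_lat) < 0.9
    mn = rng.uniform(0, 2500, n_lat)
    mx = mn + rng.uniform(0, 3000, n_lat)
    env = pd.DataFrame({
        "min_depth_m": np.where(has_sea, mn, np.nan),
        "max_depth_m": np.where(has_sea, mx, np.nan),
        "has_sea": has_sea,
    }, index=pd.Index(lat_bins, name="lat_bin"))
    ranges = []
    n_species = int(rng.integers(1, max_species + 1))
    while len(ranges) < n_species:
        l0 = int(rng.integers(0, n_lat))
        l1 = int(rng.integers(l0, n_lat))
        dmin = float(rng.uniform(0, 3000))
        dmax = dmin + float(rng.uniform(100, 3000))
        bands = ()
        if l1 - l0 >= 4 and rng.random() < 0.5:
            b0 = float(rng.uniform(l0, l1 - 1))
            b1 = float(rng.uniform(b0 + 0.5, l1 + 1))
            bands = ((b0, b1),)
        allowed = [b for b in range(l0, l1 + 1)
                   if not any(g0 < b + 0.5 < g1 for g0, g1 in bands)]
        if not allowed:
            continue
        k = int(rng.integers(1, min(4, len(allowed)) + 1))
        obs = np.sort(rng.choice(allowed, size=k, replace=False))
        entry = CatalogueEntry(
            species_id=f"r{len(ranges):03d}", lat_min=float(l0),
            lat_max=float(l1 + 1), depth_min_m=dmin, depth_max_m=dmax,
            exclusion_bands=bands)
        ranges.append(SpeciesRange(entry.species_id, obs, (0.0, 1.0),
                                   None, entry))
    return ranges, env, depth_bins, lat_bins
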