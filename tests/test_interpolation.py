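import numpy as np
import pandas as pd
import pytest

from benthos import (Catalogue, CatalogueEntry, DepthBins, OccupancyCube,
                     SpeciesRange, clip_to_region, interpolate_species,
                     interpolated_cube_from_records, occupied_latitudes,
                     ranges_from_records, raw_occupancy)
from benthos.environment import RegionMask
from benthos.simulate import random_interpolation_case

from oracles import interpolation_oracle


def flat_env(lat_bins, depth=3000.0):
    return pd.DataFrame({"min_depth_m": depth, "max_depth_m": depth,
                         "has_sea": True},
                        index=pd.Index(lat_bins, name="lat_bin"))


def env_frame(lat_bins, mins, maxs, sea):
    return pd.DataFrame({"min_depth_m": mins, "max_depth_m": maxs, "has_sea": sea},
                        index=pd.Index(lat_bins, name="lat_bin"))


def species(obs, lat_min, lat_max, dmin, dmax, bands=()):
    entry = CatalogueEntry("sp", lat_min=lat_min, lat_max=lat_max,
                           depth_min_m=dmin, depth_max_m=dmax,
                           exclusion_bands=bands)
    return SpeciesRange("sp", np.asarray(obs, dtype=int), (0.0, 1.0), None, entry)


def test_gap_fill_between_observations():
    lat_bins = np.arange(0, 30)
    env = env_frame(lat_bins, 10.0, 500.0, True)
    sp = species([10, 20], 0, 30, 0, 400)
    occ = occupied_latitudes(sp, env)
    assert list(occ) == list(range(10, 21))


def test_blocking_latitude_splits_and_drops_unobserved_segment():
    lat_bins = np.arange(0, 30)
    mins = np.full(30, 10.0)
    maxs = np.full(30, 500.0)
    maxs[15] = 5.0          # no overlap with the species' 50-400 m interval
    mins[15] = 1.0
    env = env_frame(lat_bins, mins, maxs, True)
    sp = species([10, 20], 0, 30, 50, 400)
    occ = set(occupied_latitudes(sp, env))
    assert 15 not in occ
    assert occ == set(range(10, 15)) | set(range(16, 21))
    # without an observation beyond the block, the far segment disappears
    sp2 = species([10], 0, 30, 50, 400)
    assert set(occupied_latitudes(sp2, env)) == {10}


def test_antitropical_exclusion_band_is_never_filled():
    lat_bins = np.arange(-50, 51)
    env = env_frame(lat_bins, 10.0, 500.0, True)
    sp = species([-40, 40], -50, 51, 0, 400, bands=((-23.0, 23.0),))
    occ = occupied_latitudes(sp, env)
    assert not any(-23 < b + 0.5 < 23 for b in occ)
    assert -40 in occ and 40 in occ


def test_observation_outranks_the_envelope_gate():
    lat_bins = np.arange(0, 10)
    sea = np.ones(10, dtype=bool)
    sea[5] = False
    env = env_frame(lat_bins, 10.0, 500.0, sea)
    sp = species([5], 0, 10, 0, 100)
    assert list(occupied_latitudes(sp, env)) == [5]


def test_no_observations_is_an_error():
    env = flat_env(np.arange(3))
    sp = species([], 0, 3, 0, 100)
    with pytest.raises(ValueError):
        occupied_latitudes(sp, env)


def test_depth_bins_clip_to_envelope_maximum():
    lat_bins = np.arange(0, 3)
    db = DepthBins.uniform(10, 200)
    env = env_frame(lat_bins, 5.0, 45.0, True)
    sp = species([1], 0, 3, 0, 100)
    occ = interpolate_species(sp, env, db, lat_bins)
    # catalogued 0-100 m clipped at the 45 m envelope -> bins 0-40
    assert occ[1].sum() == 5
    assert not occ[0].any() and not occ[2].any()


def test_raw_occupancy_counts_and_brute_force(world, envelopes, strat_bins):
    records = world.records.dropna(subset=["depth_m"]).reset_index(drop=True)
    cube = raw_occupancy(records, world.catalogue, envelopes, strat_bins)
    # brute force per record: its species must occupy its latitude bin
    lindex = {b: i for i, b in enumerate(cube.lat_bins)}
    sindex = {s: i for i, s in enumerate(cube.species_ids)}
    for row in records.sample(200, random_state=0).itertuples():
        li = lindex[int(np.floor(row.decimalLatitude))]
        assert cube.presence[sindex[row.species_id], li].any()
    # no species occupies a latitude bin without a record there
    for sid, grp in records.groupby("species_id"):
        got = set(cube.lat_bins[cube.presence[sindex[sid]].any(axis=1)])
        assert got <= set(np.floor(grp["decimalLatitude"]).astype(int))


def test_zero_records_gives_empty_cube(world, envelopes, strat_bins):
    cube = raw_occupancy(world.records.iloc[:0], world.catalogue, envelopes,
                         strat_bins)
    assert cube.presence.size == 0 or not cube.presence.any()


def test_single_record_depth_span(envelopes, strat_bins):
    cat = Catalogue.from_entries([
        CatalogueEntry("spX", depth_min_m=0, depth_max_m=100,
                       lat_min=30, lat_max=60)])
    rec = pd.DataFrame({"species_id": ["spX"], "decimalLatitude": [40.5],
                        "decimalLongitude": [5.0], "depth_m": [50.0],
                        "source": ["obis"]})
    cube = raw_occupancy(rec, cat, envelopes, strat_bins)
    li = {b: i for i, b in enumerate(cube.lat_bins)}[40]
    assert cube.presence[0, li].sum() == 10     # ten 10-m bins over 0-100
    assert cube.presence[0].sum() == 10         # and nowhere else


def test_interpolated_contains_raw(world, envelopes, strat_bins):
    records = world.records.dropna(subset=["depth_m"]).reset_index(drop=True)
    raw = raw_occupancy(records, world.catalogue, envelopes, strat_bins)
    interp = interpolated_cube_from_records(records, world.catalogue, envelopes,
                                            strat_bins)
    assert raw.species_ids == interp.species_ids
    assert not (raw.presence & ~interp.presence).any()


def test_monotonicity_adding_a_record_never_removes_cells(world, envelopes,
                                                          strat_bins):
    records = world.records.dropna(subset=["depth_m"])
    sid = records["species_id"].value_counts().index[0]
    mine = records[records["species_id"] == sid].reset_index(drop=True)
    sub = mine.iloc[:len(mine) // 2]
    cube_small = interpolated_cube_from_records(sub, world.catalogue, envelopes,
                                                strat_bins)
    cube_big = interpolated_cube_from_records(mine, world.catalogue, envelopes,
                                              strat_bins)
    assert not (cube_small.presence & ~cube_big.presence).any()


def test_matches_literal_rule_oracle_on_random_worlds(rng):
    for _ in range(40):
        ranges, env, db, lat_bins = random_interpolation_case(rng)
        for sp in ranges:
            got = interpolate_species(sp, env, db, lat_bins)
            want = interpolation_oracle(sp, env, db, lat_bins)
            np.testing.assert_array_equal(got, want)


def test_flat_world_interpolation_is_interval_arithmetic(rng):
    # flat sea floor, no exclusions: occupancy = observed lat span x depth bins
    lat_bins = np.arange(0, 40)
    env = flat_env(lat_bins, 3000.0)
    db = DepthBins.uniform(100, 3000)
    for _ in range(20):
        obs = np.sort(rng.choice(40, size=rng.integers(1, 6), replace=False))
        sp = species(obs, 0, 40, 100, 3000)   # overlaps the 3000 m floor
        occ = interpolate_species(sp, env, db, lat_bins)
        span = np.zeros((40, len(db)), dtype=bool)
        span[obs.min():obs.max() + 1, db.interval_mask(100, 3000)] = True
        np.testing.assert_array_equal(occ, span)


def test_range_recovery_dense_and_sparse_sampling():
    from benthos import CellEnvelopes, make_world
    from benthos.interpolation import informed_interpolate
    w = make_world(seed=21, n_species=60)
    envs = CellEnvelopes.from_grid(w.bathy)
    db = DepthBins.stratified()
    # exhaustively observed species recover their true bin set exactly
    exact = 0
    for sp in w.truth:
        bins = np.array(sorted(sp.lat_bin_set()))
        r = SpeciesRange(sp.species_id, bins, (0.0, w.bathy.lon_max),
                         None, w.catalogue[sp.species_id])
        occ = informed_interpolate(r, envs, db, lon_range="all")
        got = set(envs.lat_bins[occ.any(axis=1)])
        if got == sp.lat_bin_set():
            exact += 1
    assert exact / len(w.truth) >= 0.99
    # sparse sampling: interpolated spans shrink but stay inside the truth
    w2 = make_world(seed=22, n_species=60, total_samples=150)
    envs2 = CellEnvelopes.from_grid(w2.bathy)
    records2 = w2.records.dropna(subset=["depth_m"])
    truth2 = {sp.species_id: sp for sp in w2.truth}
    for r in ranges_from_records(records2, w2.catalogue):
        occ = informed_interpolate(r, envs2, db)
        got = set(envs2.lat_bins[occ.any(axis=1)])
        assert got <= truth2[r.species_id].lat_bin_set()


def test_clip_to_region_membership_and_identity(world, envelopes, strat_bins):
    records = world.records.dropna(subset=["depth_m"]).reset_index(drop=True)
    cat = Catalogue.from_entries([
        CatalogueEntry(sid, depth_min_m=e.depth_min_m, depth_max_m=e.depth_max_m,
                       lat_min=e.lat_min, lat_max=e.lat_max,
                       exclusion_bands=e.exclusion_bands,
                       regions=frozenset({"Atlantic"}))
        for sid, e in world.catalogue.items()])
    mask_iwp = RegionMask("IWP", include=((-90.0, 90.0, 0.0, 36.0),))
    cube = clip_to_region(records, cat, "IWP", mask_iwp, envelopes, strat_bins)
    assert not cube.presence.any() or cube.presence.shape[0] == 0
    # full-domain clip with cross-regional membership reproduces the global cube
    full = clip_to_region(records, world.catalogue, "Atlantic",
                          RegionMask("all"), envelopes, strat_bins)
    ref = interpolated_cube_from_records(records, world.catalogue, envelopes,
                                         strat_bins)
    assert full.species_ids == ref.species_ids
    np.testing.assert_array_equal(full.presence, ref.presence)


def test_cube_triplet_round_trip(world, envelopes, strat_bins):
    records = world.records.dropna(subset=["depth_m"]).iloc[:500]
    cube = raw_occupancy(records, world.catalogue, envelopes, strat_bins)
    df = cube.to_triplets()
    back = OccupancyCube.from_triplets(df, cube.species_ids, cube.lat_bins,
                                       cube.depth_bins, cube.flavour)
    np.testing.assert_array_equal(cube.presence, back.presence)
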