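import numpy as np
import pandas as pd
import pytest
from scipy import stats

from benthos import (WorldConfig, expected_effort, export_truth,
                     generate_assemblage, generate_bathymetry,
                     generate_environment, load_truth, make_world,
                     sample_occurrences, seafloor_temperature)
from benthos.simulate import ARCHETYPES, DEFAULT_MIX


def test_config_invariants():
    with pytest.raises(ValueError):
        WorldConfig(lat_min=10, lat_max=-10)
    with pytest.raises(ValueError):
        WorldConfig(depth_max=-1)
    with pytest.raises(ValueError):
        WorldConfig(lon_count=0)
    with pytest.raises(ValueError):
        WorldConfig(archetype_mix=(("shallow_tropical", 0.5),))
    with pytest.raises(ValueError):
        WorldConfig(missing_depth_fraction=1.5)


def test_world_determinism():
    w1 = make_world(seed=3, n_species=30)
    w2 = make_world(seed=3, n_species=30)
    assert np.array_equal(w1.bathy.depth, w2.bathy.depth)
    assert w1.truth == w2.truth
    pd.testing.assert_frame_equal(w1.records, w2.records)
    for k, v in w1.env.fields.items():
        np.testing.assert_array_equal(v, w2.env.fields[k])


def test_environment_threshold_and_column_structure(world):
    cfg = world.config
    # surface is the warmest point of an equatorial column
    col = seafloor_temperature(0.0, np.arange(0, 6000, 100.0),
                               cfg.threshold_temp)
    assert col[0] == col.max()
    assert np.all(np.diff(col) <= 0)
    # polar deep water sits below the configured threshold
    assert seafloor_temperature(75.0, 4000.0, cfg.threshold_temp) \
        < cfg.threshold_temp
    assert seafloor_temperature(-75.0, 4000.0, cfg.threshold_temp) \
        < cfg.threshold_temp
    # floored at freezing seawater
    assert seafloor_temperature(89.0, 6000.0, 1.0) >= -1.9


def test_environment_rejects_unphysical_threshold(world):
    with pytest.raises(ValueError):
        generate_environment(world.config, world.bathy, threshold_temp=40.0)


def test_nitrate_silicate_collinearity(world):
    sea = world.bathy.depth > 0
    r = np.corrcoef(world.env.fields["nitrate"][sea],
                    world.env.fields["silicate"][sea])[0, 1]
    assert r > 0.7


def test_npp_peaks_at_temperate_latitudes(world):
    sea = world.bathy.depth > 0
    la = world.bathy.lats[:, None] * np.ones_like(world.bathy.depth)
    npp = world.env.fields["npp"]
    temperate = sea & (np.abs(la) > 35) & (np.abs(la) < 55)
    tropical = sea & (np.abs(la) < 15)
    assert np.nanmean(npp[temperate]) > np.nanmean(npp[tropical])


def test_assemblage_structure_and_antitropical_intervals():
    cfg = WorldConfig(seed=9, n_species=40,
                      archetype_mix=(("shallow_antitropical", 1.0),))
    bathy = generate_bathymetry(cfg)
    truth = generate_assemblage(cfg, bathy)
    assert len(truth) == 40
    for sp in truth:
        assert len(sp.true_lat_intervals) >= 2
        gap = ARCHETYPES["shallow_antitropical"].antitropical_gap
        for lo, hi in sp.true_lat_intervals:
            assert hi <= gap[0] or lo >= gap[1]
    empty = generate_assemblage(
        WorldConfig(seed=9, n_species=0), bathy)
    assert empty == []


def test_assemblage_mix_counts_within_binomial_band():
    cfg = WorldConfig(seed=17, n_species=300)
    bathy = generate_bathymetry(cfg)
    truth = generate_assemblage(cfg, bathy)
    counts = pd.Series([sp.archetype for sp in truth]).value_counts()
    for name, p in DEFAULT_MIX.items():
        lo, hi = stats.binom.ppf([0.005, 0.995], 300, p)
        assert lo <= counts.get(name, 0) <= hi


def test_every_occurrence_inside_true_range(world):
    truth = {sp.species_id: sp for sp in world.truth}
    lat_bin = np.floor(world.records["decimalLatitude"]).astype(int)
    for (sid, b), grp in world.records.groupby(["species_id", lat_bin]):
        assert b in truth[sid].lat_bin_set()
        d = grp["depth_m"].dropna()
        lo, hi = truth[sid].true_depth_interval
        assert ((d >= lo) & (d <= hi)).all()


def test_missing_depth_fraction_controls():
    w_all = make_world(seed=5, n_species=40, missing_depth_fraction=0.0)
    assert w_all.records["depth_m"].notna().all()
    cfg = WorldConfig(seed=6, n_species=60, total_samples=50000,
                      missing_depth_fraction=0.333)
    bathy = generate_bathymetry(cfg)
    truth = generate_assemblage(cfg, bathy)
    recs = sample_occurrences(truth, bathy, cfg)
    assert abs(recs["depth_m"].isna().mean() - 0.333) < 0.02


def test_uniform_sampling_when_effort_bias_is_zero():
    cfg = WorldConfig(seed=8, n_species=1, total_samples=10000, effort_bias=0.0,
                      archetype_mix=(("abyssal_cosmopolitan", 1.0),))
    bathy = generate_bathymetry(cfg)
    truth = generate_assemblage(cfg, bathy)
    recs = sample_occurrences(truth, bathy, cfg)
    # chi-square GOF against uniform occupancy over the species' cells
    sp = truth[0]
    node_bins = np.floor(bathy.lats).astype(int)
    in_lat = np.isin(node_bins, list(sp.lat_bin_set()))
    lo, hi = sp.true_depth_interval
    cells = in_lat[:, None] & (bathy.depth >= lo) & (bathy.depth <= hi)
    ii, jj = np.nonzero(cells)
    index = {(a, b): k for k, (a, b) in enumerate(zip(ii, jj))}
    counts = np.zeros(len(index))
    ri = np.floor((recs["decimalLatitude"] - bathy.lat_min)
                  / bathy.resolution).astype(int)
    rj = np.floor((recs["decimalLongitude"] - bathy.lon_min)
                  / bathy.resolution).astype(int)
    for a, b in zip(ri, rj):
        counts[index[(a, b)]] += 1
    _, p = stats.chisquare(counts)
    assert p > 0.01


def test_effort_field_integrates_to_total():
    cfg = WorldConfig(seed=4, n_species=50)
    bathy = generate_bathymetry(cfg)
    truth = generate_assemblage(cfg, bathy)
    field = expected_effort(truth, bathy, cfg)
    assert field.sum() == pytest.approx(cfg.total_samples, rel=0.01)


def test_effort_bias_favours_north_temperate_shallows():
    w = make_world(seed=13, n_species=80, effort_bias=3.0)
    lat = w.records["decimalLatitude"]
    north_temp = ((lat > 25) & (lat < 65)).mean()
    w0 = make_world(seed=13, n_species=80, effort_bias=0.0)
    lat0 = w0.records["decimalLatitude"]
    assert north_temp > ((lat0 > 25) & (lat0 < 65)).mean()


def test_truth_round_trip(tmp_path, world):
    export_truth(world.truth, world.config, tmp_path)
    truth, cfg = load_truth(tmp_path)
    assert truth == world.truth
    assert cfg == world.config
    n_lines = (tmp_path / "truth.csv").read_text().strip().count("\n") + 1
    assert n_lines == len(world.truth) + 1
    # empty assemblage still round-trips
    export_truth([], world.config, tmp_path / "empty")
    empty, _ = load_truth(tmp_path / "empty")
    assert empty == []
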