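import numpy as np
import pandas as pd
import pytest

from benthos import (DependenceSurface, ModelSpec, all_subsets_select,
                     fit_poisson, pairwise_interaction, partial_dependence,
                     random_forest_importance, threshold_estimate)


def poisson_table(rng, n=500, beta=0.5, offset=True):
    temp = rng.normal(0, 1, n)
    off = np.log1p(rng.integers(0, 20, n).astype(float)) if offset else np.zeros(n)
    mu = np.exp(1.0 + beta * temp + off)
    return pd.DataFrame({"richness": rng.poisson(mu), "temperature": temp,
                         "effort_offset": off, "lat_bin": np.arange(n)})


def test_poisson_recovers_known_slope(rng):
    tab = poisson_table(rng)
    fit = fit_poisson(tab, ModelSpec(predictors=("temperature",),
                                     offset="effort_offset"))
    assert fit.params["temperature"] == pytest.approx(0.5, abs=0.1)
    assert fit.pvalues["temperature"] < 1e-6
    assert np.isfinite(fit.aic) and 0 <= fit.r2 <= 1


def test_poisson_intercept_only_matches_sample_mean(rng):
    y = rng.poisson(7.0, 200)
    tab = pd.DataFrame({"richness": y, "lat_bin": np.arange(200)})
    fit = fit_poisson(tab, ModelSpec(predictors=()))
    assert np.exp(fit.params["const"]) == pytest.approx(y.mean(), rel=1e-6)


def test_zero_offset_equals_no_offset(rng):
    tab = poisson_table(rng, offset=False)
    a = fit_poisson(tab, ModelSpec(predictors=("temperature",)))
    b = fit_poisson(tab, ModelSpec(predictors=("temperature",),
                                   offset="effort_offset"))
    assert a.params["temperature"] == pytest.approx(b.params["temperature"])
    assert a.aic == pytest.approx(b.aic)


def test_ar1_adjustment_inflates_errors_under_autocorrelation(rng):
    n = 400
    lat = np.arange(n)
    smooth = np.cumsum(rng.normal(0, 0.3, n))  # strongly autocorrelated noise
    mu = np.exp(1.5 + 0.3 * np.sin(lat / 25) + 0.5 * (smooth - smooth.mean()))
    tab = pd.DataFrame({"richness": rng.poisson(mu),
                        "temperature": np.sin(lat / 25), "lat_bin": lat})
    plain = fit_poisson(tab, ModelSpec(predictors=("temperature",)))
    adj = fit_poisson(tab, ModelSpec(predictors=("temperature",),
                                     error_adjustment="ar1"))
    assert adj.ar1_rho is not None and adj.ar1_rho > 0.2
    assert adj.bse["temperature"] > plain.bse["temperature"]
    assert adj.pvalues["temperature"] >= plain.pvalues["temperature"]


def test_all_subsets_counts_and_true_model_wins(rng):
    tab = poisson_table(rng, n=800, beta=0.8)
    tab["noise1"] = rng.normal(size=800)
    tab["noise2"] = rng.normal(size=800)
    out = all_subsets_select(tab, ["temperature", "noise1", "noise2"],
                             ModelSpec(offset="effort_offset"))
    assert len(out) == 8
    assert "temperature" in out.loc[0, "predictors"]
    assert out["delta_aic"].iloc[0] == 0.0


def test_all_subsets_pure_noise_prefers_intercept():
    hits = 0
    runs = 50
    for s in range(runs):
        rng = np.random.default_rng(900 + s)
        n = 1000
        tab = pd.DataFrame({
            "richness": rng.poisson(5.0, n), "lat_bin": np.arange(n),
            "x1": rng.normal(size=n), "x2": rng.normal(size=n),
        })
        out = all_subsets_select(tab, ["x1", "x2"])
        inter = out[out["k"] == 0]["delta_aic"].iloc[0]
        hits += inter <= 2.0
    assert hits / runs >= 0.8


def test_forest_importance_ranks_true_driver(rng):
    n = 400
    tab = pd.DataFrame({
        "temperature": rng.uniform(-2, 25, n),
        "poc_flux": rng.uniform(0, 30, n),
        "salinity": rng.normal(34.5, 0.2, n),
    })
    tab["richness"] = rng.poisson(np.exp(1 + 0.12 * tab["temperature"]))
    res = random_forest_importance(tab, "richness",
                                   ["temperature", "poc_flux", "salinity"],
                                   n_trees=300, seed=0)
    assert res.importance.index[0] == "temperature"
    assert res.importance.loc["temperature", "rank"] == 1
    assert sorted(res.importance["rank"]) == [1, 2, 3]


def test_forest_importance_null_predictor_is_small():
    small = 0
    for s in range(10):
        rng = np.random.default_rng(100 + s)
        n = 500
        tab = pd.DataFrame({"x": rng.normal(size=n), "y": rng.normal(size=n)})
        tab["richness"] = rng.poisson(6.0, n)
        res = random_forest_importance(tab, "richness", ["x", "y"],
                                       n_trees=200, seed=s)
        small += (res.importance["inc_mse"] <= 5.0).all()
    assert small >= 9


def test_forest_deterministic_under_seed(rng):
    tab = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
    tab["richness"] = rng.poisson(4.0, 60)
    r1 = random_forest_importance(tab, "richness", ["a", "b"], n_trees=50, seed=7)
    r2 = random_forest_importance(tab, "richness", ["a", "b"], n_trees=50, seed=7)
    pd.testing.assert_frame_equal(r1.importance, r2.importance)


def test_mtry_clamped_to_predictor_count(rng):
    tab = pd.DataFrame({"a": rng.normal(size=40)})
    tab["richness"] = rng.poisson(3.0, 40)
    res = random_forest_importance(tab, "richness", ["a"], n_trees=20,
                                   mtry=3, seed=0)
    assert res.model.max_features == 1


def test_partial_dependence_linear_model_slope():
    X = pd.DataFrame({"a": np.linspace(0, 1, 50), "b": np.linspace(1, 2, 50)})
    model = lambda df: 2.0 * df["a"].to_numpy() + 3.0 * df["b"].to_numpy()
    pdp = partial_dependence(model, X, "a", grid=np.linspace(0, 1, 11))
    slopes = np.diff(pdp.values) / np.diff(pdp.grids[0])
    assert np.allclose(slopes, 2.0)
    flat = partial_dependence(lambda df: np.full(len(df), 4.0), X, "a")
    assert np.allclose(flat.values, 4.0)


def test_partial_dependence_matches_clamp_oracle(rng):
    n = 40
    tab = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    tab["richness"] = rng.poisson(np.exp(1 + tab["a"].clip(-1, 1)))
    res = random_forest_importance(tab, "richness", ["a", "b"], n_trees=60,
                                   seed=1)
    grid = np.linspace(tab["a"].min(), tab["a"].max(), 7)
    pdp = partial_dependence(res.model, res.X_train, "a", grid=grid)
    for g, v in zip(grid, pdp.values):
        Xc = res.X_train.copy()
        Xc["a"] = g
        assert v == pytest.approx(res.model.predict(Xc).mean())


def test_pairwise_interaction_additive_model_has_no_interaction():
    X = pd.DataFrame({"a": np.linspace(0, 1, 30), "b": np.linspace(0, 2, 30)})
    model = lambda df: 2.0 * df["a"].to_numpy() + 3.0 * df["b"].to_numpy()
    surf = pairwise_interaction(model, X, "a", "b",
                                grid1=np.linspace(0, 1, 5),
                                grid2=np.linspace(0, 2, 5))
    # rows differ by a constant: no interaction term
    diffs = surf.values - surf.values[0]
    assert np.allclose(diffs, diffs[:, :1])


def test_pairwise_interaction_ridge_for_multiplicative_response():
    X = pd.DataFrame({"a": np.linspace(0, 1, 30), "b": np.linspace(0, 1, 30)})
    model = lambda df: df["a"].to_numpy() * df["b"].to_numpy()
    surf = pairwise_interaction(model, X, "a", "b",
                                grid1=np.linspace(0, 1, 5),
                                grid2=np.linspace(0, 1, 5))
    assert surf.values[-1, -1] > surf.values[0, 0]
    assert surf.values[-1, -1] > surf.values[0, -1]
    interaction = (surf.values[-1, -1] - surf.values[0, -1]
                   - surf.values[-1, 0] + surf.values[0, 0])
    assert interaction > 0.5


def test_threshold_estimate_exact_hinge():
    t = np.arange(-1.0, 4.01, 0.1)
    surf = DependenceSurface(("temperature",), (t,),
                             np.maximum(t - 1.5, 0.0) * 3.0)
    fit = threshold_estimate(surf, n_boot=50, seed=0)
    assert fit.identified
    assert fit.breakpoint == pytest.approx(1.5, abs=0.1 + 1e-9)
    assert fit.ci is not None


def test_threshold_estimate_exact_step():
    t = np.arange(-1.0, 4.01, 0.1)
    surf = DependenceSurface(("temperature",), (t,),
                             np.where(t > 1.5, 10.0, 0.0))
    fit = threshold_estimate(surf, n_boot=0)
    assert fit.identified
    assert fit.breakpoint == pytest.approx(1.6, abs=0.1 + 1e-9)


def test_threshold_estimate_linear_curve_unidentified():
    t = np.arange(0, 5.01, 0.1)
    surf = DependenceSurface(("temperature",), (t,), 2.0 + 0.5 * t)
    fit = threshold_estimate(surf, n_boot=0)
    assert not fit.identified and fit.breakpoint is None
    flat = DependenceSurface(("temperature",), (t,), np.full_like(t, 3.0))
    assert not threshold_estimate(flat, n_boot=0).identified
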