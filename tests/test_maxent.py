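"""Maximum-entropy engine: features, fitting, prediction, interpretation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import spearmanr

from nichemap.grids import Grid, GridStack
from nichemap.maxent import (
    MaxentModel,
    _FeatureBuilder,
    jackknife_gain,
    percent_contribution,
    replicate_runs,
    response_curve,
    sample_background,
)
from nichemap.synthetic import WorldRecipe, make_layers, make_truth, sample_occurrences


def fit_simple(Xp, Xb, **kw):
    kw.setdefault("feature_classes", "lq")
    m = MaxentModel(**kw)
    X = pd.concat([Xp, Xb], ignore_index=True)
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
    return m.fit(X, y)


@pytest.fixture(scope="module")
def small_world():
    recipe = WorldRecipe(n_rows=50, n_cols=50, n_presences=300, seed=11, contamination_fraction=0.0)
    stack = make_layers(recipe)
    truth = make_truth(stack, recipe.truth_coefficients, recipe.truth_gain)
    occ = sample_occurrences(truth, recipe)
    return recipe, stack, truth, occ


class TestFeatures:
    def test_linear_only_count_and_endpoints(self):
        rng = np.random.default_rng(0)
        Xb = rng.uniform(2.0, 8.0, (100, 3))
        b = _FeatureBuilder("l", 5, 5).fit(Xb, ["a", "b", "c"])
        F = b.transform(Xb)
        assert F.shape[1] == 3
        at_min = b.transform(Xb.min(axis=0, keepdims=True))
        at_max = b.transform(Xb.max(axis=0, keepdims=True))
        assert np.allclose(at_min, 0.0) and np.allclose(at_max, 1.0)

    def test_combinatorial_feature_count(self):
        # 2 vars, L Q H P T with 5 hinge and 3 threshold knots:
        # 2L + 2Q + 1P + 10H + 6T = 21
        rng = np.random.default_rng(1)
        Xb = rng.uniform(0, 1, (50, 2))
        b = _FeatureBuilder("lqpht", 5, 3).fit(Xb, ["u", "v"])
        assert b.transform(Xb).shape[1] == 21
        assert len(b.feature_names_) == 21

    def test_projection_clamped_to_bounds(self):
        Xb = np.linspace(0, 1, 50)[:, None]
        b = _FeatureBuilder("l", 5, 5).fit(Xb, ["a"])
        out = b.transform(np.array([[5.0], [-5.0]]), clamp=True)
        assert out[0, 0] == 1.0 and out[1, 0] == 0.0


class TestFitting:
    def test_huge_rm_gives_uniform_model(self):
        rng = np.random.default_rng(2)
        Xp = pd.DataFrame({"a": rng.uniform(0.5, 1, 40)})
        Xb = pd.DataFrame({"a": rng.uniform(0, 1, 200)})
        m = fit_simple(Xp, Xb, rm=1e6)
        assert np.all(m.coef_ == 0.0)
        assert np.allclose(m.background_raw_, 1.0 / 200)
        # uniform raw => cloglog = 1 - e^{-1} exactly
        assert np.allclose(m.predict(Xb), 1 - np.exp(-1), atol=1e-9)

    def test_raw_normalizes_over_background(self, small_world):
        _, stack, _, occ = small_world
        Xp = pd.DataFrame(
            stack.values_at(occ["lon"].to_numpy()[:80], occ["lat"].to_numpy()[:80]), columns=stack.names
        ).dropna()
        bg = sample_background(occ, stack, buffer_km=3000, m=500, seed=0)
        m = fit_simple(Xp, bg.X)
        assert abs(m.background_raw_.sum() - 1.0) <= 1e-9
        assert 0 <= m.entropy_ <= np.log(m.n_background_) + 1e-12

    def test_constraint_matching_at_vanishing_rm(self):
        # single binary feature: fitted expectation matches the presence mean
        rng = np.random.default_rng(3)
        Xb = pd.DataFrame({"a": (rng.random(400) < 0.3).astype(float)})
        Xp = pd.DataFrame({"a": (rng.random(80) < 0.7).astype(float)})
        m = fit_simple(Xp, Xb, feature_classes="l", rm=1e-8, tol=1e-11)
        F = m.builder_.transform(Xb.to_numpy(), clamp=False)
        model_expectation = m.background_raw_ @ F
        presence_mean = m.builder_.transform(Xp.to_numpy()).mean(axis=0)
        assert np.all(np.abs(model_expectation - presence_mean) <= 1e-3)

    def test_objective_matches_generic_optimizer(self):
        # independent oracle: L-BFGS-B on the split-sign formulation of the
        # same penalized likelihood
        rng = np.random.default_rng(4)
        Xp = pd.DataFrame(rng.uniform(0.3, 1.0, (50, 2)), columns=["a", "b"])
        Xb = pd.DataFrame(rng.uniform(0.0, 1.0, (500, 2)), columns=["a", "b"])
        m = fit_simple(Xp, Xb, rm=1.0, tol=1e-10)
        Fp = m.builder_.transform(Xp.to_numpy())
        Fb = m.builder_.transform(Xb.to_numpy(), clamp=False)
        beta = m.beta_
        k = Fb.shape[1]

        def objective(uv):
            lam = uv[:k] - uv[k:]
            return logsumexp(Fb @ lam) - Fp.mean(0) @ lam + beta @ (uv[:k] + uv[k:])

        res = minimize(objective, np.zeros(2 * k), method="L-BFGS-B",
                       bounds=[(0, None)] * 2 * k, options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 5000})
        mine = logsumexp(Fb @ m.coef_) - Fp.mean(0) @ m.coef_ + beta @ np.abs(m.coef_)
        assert mine <= res.fun + 1e-4

    def test_sparsity_nonincreasing_in_rm(self):
        rng = np.random.default_rng(5)
        Xp = pd.DataFrame(rng.uniform(0.4, 1, (60, 3)), columns=list("abc"))
        Xb = pd.DataFrame(rng.uniform(0, 1, (300, 3)), columns=list("abc"))
        nnz = []
        for rm in [0.1, 0.5, 1.0, 2.0, 5.0]:
            m = fit_simple(Xp, Xb, feature_classes="lqh", hinge_knots=8, rm=rm)
            nnz.append(int(np.sum(m.coef_ != 0)))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_input_validation(self):
        m = MaxentModel()
        with pytest.raises(ValueError):
            m.fit(np.zeros((4, 2)), np.array([0, 1, 2, 1]))
        with pytest.raises(ValueError):
            m.fit(np.zeros((3, 2)), np.array([1, 0, 0]))  # a single presence


class TestPrediction:
    def test_cumulative_definition(self):
        rng = np.random.default_rng(6)
        Xp = pd.DataFrame({"a": rng.uniform(0.5, 1, 30)})
        Xb = pd.DataFrame({"a": rng.uniform(0, 1, 100)})
        m = fit_simple(Xp, Xb)
        cum = m.predict(Xb, output="cumulative")
        raw = m.predict(Xb, output="raw")
        # cell with the largest raw has cumulative 100
        assert np.isclose(cum[np.argmax(raw)], 100.0)
        # direct-sum oracle on a few cells
        for i in [0, 17, 63]:
            assert np.isclose(cum[i], 100 * raw[raw <= raw[i]].sum(), atol=1e-9)

    def test_cloglog_formula_oracle(self):
        rng = np.random.default_rng(7)
        Xp = pd.DataFrame({"a": rng.uniform(0.5, 1, 20)})
        Xb = pd.DataFrame({"a": rng.uniform(0, 1, 10)})
        m = fit_simple(Xp, Xb, rm=0.5)
        raw = m.predict(Xb, output="raw")
        oracle = 1 - np.exp(-np.exp(m.entropy_) * raw)
        assert np.allclose(m.predict(Xb, output="cloglog"), oracle, atol=1e-12)

    def test_unknown_output_mode(self):
        rng = np.random.default_rng(8)
        m = fit_simple(pd.DataFrame({"a": rng.random(10)}), pd.DataFrame({"a": rng.random(20)}))
        with pytest.raises(ValueError):
            m.predict(pd.DataFrame({"a": [0.5]}), output="logistic")


class TestBackground:
    def test_buffer_covering_grid_and_determinism(self, small_world):
        _, stack, _, occ = small_world
        b1 = sample_background(occ, stack, buffer_km=1e6, m=300, seed=5)
        b2 = sample_background(occ, stack, buffer_km=1e6, m=300, seed=5)
        assert np.array_equal(b1.rows, b2.rows) and np.array_equal(b1.cols, b2.cols)
        assert len(b1.X) == 300

    def test_all_within_buffer_distance_oracle(self, small_world):
        _, stack, _, occ = small_world
        one = occ.iloc[:1]
        with pytest.warns(UserWarning):
            b = sample_background(one, stack, buffer_km=300, m=10000, seed=0)
        # independent haversine check
        lat0, lon0 = np.deg2rad(one["lat"].iloc[0]), np.deg2rad(one["lon"].iloc[0])
        lat, lon = np.deg2rad(b.lat), np.deg2rad(b.lon)
        h = np.sin((lat - lat0) / 2) ** 2 + np.cos(lat0) * np.cos(lat) * np.sin((lon - lon0) / 2) ** 2
        d = 2 * 6371.0088 * np.arcsin(np.sqrt(h))
        assert (d <= 300 + 1e-6).all()


class TestInterpretation:
    def test_flat_and_monotone_response(self):
        rng = np.random.default_rng(9)
        Xb = pd.DataFrame({"a": rng.uniform(0, 1, 300), "b": rng.uniform(0, 1, 300)})
        Xp = pd.DataFrame({"a": rng.uniform(0.6, 1, 60), "b": rng.uniform(0, 1, 60)})
        m = fit_simple(Xp, Xb, feature_classes="l")
        xa, ya = response_curve(m, "a")
        assert np.all(np.diff(ya) >= -1e-12)  # presences at high a -> nondecreasing
        # variable with ~no signal after a huge-rm fit is flat
        m0 = fit_simple(Xp, Xb, feature_classes="l", rm=1e6)
        _, yb = response_curve(m0, "b")
        assert np.allclose(yb, yb[0])

    def test_quadratic_truth_recovers_interior_optimum(self):
        rng = np.random.default_rng(10)
        xb = rng.uniform(-1, 1, 2000)
        # presence density peaks at x = 0.2
        weight = np.exp(-((xb - 0.2) ** 2) / (2 * 0.15**2))
        keep = rng.random(2000) < weight / weight.max()
        Xp = pd.DataFrame({"x": xb[keep][:200]})
        Xb = pd.DataFrame({"x": xb})
        m = fit_simple(Xp, Xb, feature_classes="lq", rm=0.5)
        xs, ys = response_curve(m, "x", n_points=201)
        opt = xs[np.argmax(ys)]
        assert abs(opt - 0.2) < 0.1
        assert 0 < np.argmax(ys) < len(xs) - 1  # interior maximum

    def test_contributions_single_variable_and_sum(self):
        rng = np.random.default_rng(11)
        Xb = pd.DataFrame({"a": rng.uniform(0, 1, 300), "b": rng.uniform(0, 1, 300)})
        Xp = pd.DataFrame({"a": rng.uniform(0.7, 1, 50), "b": rng.uniform(0, 1, 50)})
        m = fit_simple(Xp, Xb, feature_classes="l")
        c = percent_contribution(m, Xp, Xb, seed=0)
        assert abs(c.sum() - 100.0) <= 0.1
        assert c["a"] > 90.0

    def test_contributions_symmetric_pair(self):
        rng = np.random.default_rng(12)
        Xb = pd.DataFrame({"a": rng.uniform(0, 1, 500), "b": rng.uniform(0, 1, 500)})
        # exchangeable truth: both variables matter equally
        w = Xb["a"] + Xb["b"]
        idx = rng.choice(500, size=120, p=(w / w.sum()).to_numpy())
        Xp = Xb.iloc[idx].reset_index(drop=True)
        m = fit_simple(Xp, Xb, feature_classes="l", rm=0.5)
        c = percent_contribution(m, Xp, Xb, seed=1, n_repeats=5)
        assert abs(c["a"] - 50) < 10 and abs(c["b"] - 50) < 10

    def test_jackknife_identifies_dominant_variable(self):
        rng = np.random.default_rng(13)
        Xb = pd.DataFrame(
            {"sig": rng.uniform(0, 1, 400), "noise": rng.uniform(0, 1, 400)}
        )
        w = np.exp(3 * Xb["sig"])
        idx = rng.choice(400, size=100, p=(w / w.sum()).to_numpy())
        Xp = Xb.iloc[idx].reset_index(drop=True)
        m = fit_simple(Xp, Xb, feature_classes="lq", rm=1.0)
        jk = jackknife_gain(m, Xp, Xb)
        assert jk["with_only"].idxmax() == "sig"
        assert jk["without"].idxmin() == "noise" or jk.loc["sig", "without"] <= jk.loc["noise", "without"]
        assert jk.loc["noise", "with_only"] < 0.05
        # full model gains at least as much as any reduced model (tolerance)
        assert jk.attrs["full_gain"] >= jk["without"].max() - 1e-3


class TestReplicates:
    def test_single_rep_sd_zero_and_determinism(self, small_world):
        _, stack, _, occ = small_world
        from nichemap.occurrences import dedupe_to_cells

        rec = dedupe_to_cells(occ, stack.template)
        bg = sample_background(rec, stack, buffer_km=3000, m=400, seed=1)
        Xp = pd.DataFrame(
            stack.values_at(rec["lon"].to_numpy(), rec["lat"].to_numpy()), columns=stack.names
        )
        m = MaxentModel(feature_classes="lq")
        r1 = replicate_runs(m, Xp, bg, stack, n_reps=1, base_seed=3)
        assert np.nanmax(r1.sd_grid.values) == 0.0
        r2 = replicate_runs(m, Xp, bg, stack, n_reps=2, base_seed=3)
        r3 = replicate_runs(m, Xp, bg, stack, n_reps=2, base_seed=3)
        assert np.array_equal(r2.mean_grid.values, r3.mean_grid.values, equal_nan=True)

    def test_mean_grid_at_least_as_good_as_worst_replicate(self, small_world):
        _, stack, truth, occ = small_world
        from nichemap.occurrences import dedupe_to_cells

        rec = dedupe_to_cells(occ, stack.template)
        bg = sample_background(rec, stack, buffer_km=3000, m=400, seed=2)
        Xp = pd.DataFrame(
            stack.values_at(rec["lon"].to_numpy(), rec["lat"].to_numpy()), columns=stack.names
        )
        res = replicate_runs(MaxentModel(feature_classes="lq"), Xp, bg, stack, n_reps=5, base_seed=7)
        ok = ~stack.mask
        rhos = [spearmanr(g.values[ok], truth.values[ok])[0] for g in res.grids]
        rho_mean = spearmanr(res.mean_grid.values[ok], truth.values[ok])[0]
        assert rho_mean >= min(rhos)
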