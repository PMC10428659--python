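"""The maximum-entropy model: features, fitting, normalization, projection."""

import numpy as np
import pandas as pd
import pytest

from tickdist.env_layers import EnvLayer, EnvStack, GridGeometry
from tickdist.maxent import (
    FeatureSet,
    FitConfig,
    FitError,
    MaxEntModel,
    build_features,
    fit_from_tables,
    fit_maxent,
    predict,
    sample_background,
    score_points,
)


class TestSampleBackground:
    def test_small_grid_exhausted(self, small_stack):
        n_valid = int(small_stack.mask.sum())
        bg = sample_background(small_stack, n=10_000, seed=0)
        assert len(bg) == n_valid

    def test_same_seed_identical(self, small_stack):
        a = sample_background(small_stack, n=500, seed=9)
        b = sample_background(small_stack, n=500, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self, small_stack):
        a = sample_background(small_stack, n=500, seed=1)
        b = sample_background(small_stack, n=500, seed=2)
        assert not a.equals(b)


class TestFeatures:
    def fit_spec(self, classes, table, knots=1):
        fs = FeatureSet(classes=classes, hinge_knots=knots)
        return fs.fit(table)

    def test_linear_only_is_rescaled_x(self, make_table):
        t = make_table(x=[0.0, 5.0, 10.0])
        fs = self.fit_spec(("linear",), t)
        design = build_features(t, fs)
        np.testing.assert_allclose(design[:, 0], [0.0, 0.5, 1.0])

    def test_two_vars_with_products_column_count(self, make_table):
        t = make_table(x=[0.0, 1.0, 2.0], y=[1.0, 3.0, 5.0])
        fs = self.fit_spec(("linear", "quadratic", "product"), t)
        design = build_features(t, fs)
        assert design.shape[1] == 5  # 2 linear + 2 quadratic + 1 product

    def test_hinge_value_at_midpoint_knot(self, make_table):
        t = make_table(x=[0.0, 0.75, 1.0])
        fs = self.fit_spec(("hinge",), t, knots=1)  # single knot at 0.5
        design = build_features(t, fs)
        forward = [f.direction for f in fs.features].index("forward")
        np.testing.assert_allclose(design[1, forward], 0.5)

    def test_constant_variable_drops_nonlinear_features(self, make_table):
        t = make_table(x=[1.0, 2.0, 3.0], c=[7.0, 7.0, 7.0])
        with pytest.warns(UserWarning, match="constant"):
            fs = FeatureSet(classes=("linear", "quadratic", "hinge"),
                            hinge_knots=2).fit(t)
        kinds = [(f.kind, f.variables[0]) for f in fs.features]
        assert ("quadratic", "c") not in kinds
        assert all(not (k == "hinge" and v == "c") for k, v in kinds)

    def test_features_in_unit_interval_on_training_data(self, small_tables):
        presence, background = small_tables
        fs = FeatureSet().fit(pd.concat([presence, background], ignore_index=True))
        for table in (presence, background):
            d = fs.transform(table)
            assert d.min() >= 0.0 and d.max() <= 1.0 + 1e-12


def design_1d(x):
    t = pd.DataFrame({"x": np.asarray(x, dtype=float)})
    return t


class TestFit:
    def test_normalization_over_background(self, small_model, small_tables):
        _, background = small_tables
        B = small_model.features.transform(background)
        raw = np.exp(B @ small_model.beta - small_model.log_z)
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_gain_trace_monotone(self, small_model):
        assert np.all(np.diff(small_model.gain_trace) >= -1e-9)

    def test_uniform_presence_gives_zero_gain(self):
        # presence feature distribution identical to background: the
        # gradient vanishes at beta = 0 and the null model stands
        x = np.linspace(0, 1, 40)
        fs = FeatureSet(classes=("linear", "quadratic"), hinge_knots=1)
        t = design_1d(x)
        fs.fit(t)
        D = fs.transform(t)
        model = fit_maxent(D, D, FitConfig(), fs)
        assert model.gain == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(model.beta, 0.0)

    def test_presence_at_high_x_gives_positive_slope(self):
        x = np.linspace(0, 1, 20)
        fs = FeatureSet(classes=("linear",))
        bg = design_1d(x)
        fs.fit(bg)
        B = fs.transform(bg)
        P = fs.transform(design_1d([0.8, 0.85, 0.9, 0.95, 1.0]))
        model = fit_maxent(P, B, FitConfig(), fs)
        assert model.beta[0] > 0

    def test_matches_entropy_maximization_oracle(self):
        # independent oracle: maximize entropy of p over 20 cells subject
        # to matching the presence feature means, solved directly on the
        # primal probabilities with SLSQP
        from scipy.optimize import minimize

        rng = np.random.default_rng(11)
        x = np.linspace(0, 1, 20)
        bg_t = design_1d(x)
        fs = FeatureSet(classes=("linear", "quadratic"))
        fs.fit(bg_t)
        B = fs.transform(bg_t)
        pres_cells = rng.choice(20, size=60, replace=True, p=np.linspace(0.5, 1.5, 20) / 20)
        P = B[pres_cells]
        f_bar = P.mean(axis=0)

        def neg_entropy(p):
            return float(np.sum(p * np.log(np.maximum(p, 1e-300))))

        cons = [{"type": "eq", "fun": lambda p: p.sum() - 1.0}]
        for j in range(B.shape[1]):
            cons.append({"type": "eq", "fun": lambda p, j=j: p @ B[:, j] - f_bar[j]})
        res = minimize(neg_entropy, np.full(20, 1 / 20), method="SLSQP",
                       bounds=[(1e-12, 1.0)] * 20, constraints=cons,
                       options={"maxiter": 2000, "ftol": 1e-14})
        assert res.success
        cfg = FitConfig(reg_multiplier=1e-8, convergence_tol=1e-12, max_iter=5000)
        model = fit_maxent(P, B, cfg, fs)
        q = np.exp(B @ model.beta - model.log_z)
        assert np.abs(q - res.x).sum() <= 1e-3

    def test_degenerate_presence_fatal(self):
        x = np.linspace(0, 1, 10)
        fs = FeatureSet(classes=("linear",))
        bg = design_1d(x)
        fs.fit(bg)
        B = fs.transform(bg)
        P = np.tile(B[3], (6, 1))
        with pytest.raises(FitError, match="degenerate"):
            fit_maxent(P, B, FitConfig(), fs)

    def test_too_few_presences_fatal(self):
        x = np.linspace(0, 1, 10)
        fs = FeatureSet(classes=("linear",))
        bg = design_1d(x)
        fs.fit(bg)
        B = fs.transform(bg)
        with pytest.raises(FitError, match="at least 5"):
            fit_maxent(B[:3], B, FitConfig(), fs)

    def test_save_load_roundtrip(self, tmp_path, small_model, small_tables):
        _, background = small_tables
        f = tmp_path / "model.json"
        small_model.save(f)
        back = MaxEntModel.load(f)
        a = score_points(small_model, background, transform="cloglog")
        b = score_points(back, background, transform="cloglog")
        np.testing.assert_allclose(a, b)
        assert back.features.variables == small_model.features.variables


def constant_stack(names, geometry, value=1.0):
    layers = [
        EnvLayer(name=n, geometry=geometry,
                 values=np.full((geometry.n_rows, geometry.n_cols), value * (i + 1)))
        for i, n in enumerate(names)
    ]
    return EnvStack(layers=layers)


class TestPredict:
    def test_raw_sums_to_one_over_training_background(self, small_model, small_stack, small_tables):
        _, background = small_tables
        smap = predict(small_model, small_stack, transform="raw")
        rr, cc = background.attrs["rows"], background.attrs["cols"]
        assert smap.continuous[rr, cc].sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_environment_gives_constant_cloglog(self, small_model):
        geom = GridGeometry(n_rows=5, n_cols=5, x_min=97.0, y_max=53.0,
                            cell_size=5 / 60)
        stack = constant_stack(small_model.features.variables, geom)
        smap = predict(small_model, stack, transform="cloglog")
        vals = smap.continuous[stack.mask]
        assert np.allclose(vals, vals[0])

    def test_clamping_truncates_to_training_bounds(self, small_model):
        v = small_model.features.variables[0]
        lo, hi = small_model.features.bounds[v]
        base = {w: np.array([small_model.features.means[w]])
                for w in small_model.features.variables}
        beyond = dict(base)
        beyond[v] = np.array([hi + 10 * (hi - lo)])
        at_max = dict(base)
        at_max[v] = np.array([hi])
        s_beyond = score_points(small_model, pd.DataFrame(beyond), clamp=True)
        s_at_max = score_points(small_model, pd.DataFrame(at_max), clamp=True)
        np.testing.assert_allclose(s_beyond, s_at_max)

    def test_cloglog_strictly_in_unit_interval(self, small_model, small_stack):
        smap = predict(small_model, small_stack, transform="cloglog")
        vals = smap.continuous[small_stack.mask]
        assert np.all(vals > 0.0) and np.all(vals < 1.0)

    def test_missing_variable_fatal_names_it(self, small_model, small_stack):
        missing = small_model.features.variables[0]
        rest = [n for n in small_stack.names if n != missing]
        from tickdist.env_layers import LayerError

        with pytest.raises(LayerError, match=missing):
            predict(small_model, small_stack.subset(rest))

    def test_masked_cells_stay_masked(self, small_model, small_stack):
        smap = predict(small_model, small_stack)
        assert np.all(np.isnan(smap.continuous[~small_stack.mask]))
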