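"""Maximum-entropy fitting: closed forms, normalization, shrinkage,
background sampling, contributions, jackknife and response curves."""

import numpy as np
import pandas as pd
import pytest

from maxenm import (
    build_features,
    fit_maxent,
    jackknife_auc,
    predict,
    response_curve,
    sample_background,
    variable_contribution,
)
from maxenm.maxent import MaxentModel, stack_table

LN4 = np.log(4.0)
TWO_CELL_GAIN = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)  # 0.19274...


@pytest.fixture()
def two_cell_fit():
    """Single binary feature, background {0,1}, presence mean 0.8, beta=0."""
    P = np.array([[1.0]] * 4 + [[0.0]])
    B = np.array([[0.0], [1.0]])
    return fit_maxent(P, B, reg_multiplier=0.0, tol=1e-12), P, B


class TestClosedForms:
    def test_moment_matching_lambda(self, two_cell_fit):
        model, _, _ = two_cell_fit
        assert model.lambdas[0] == pytest.approx(LN4, abs=1e-4)

    def test_raw_distribution(self, two_cell_fit):
        model, _, B = two_cell_fit
        np.testing.assert_allclose(predict(model, B, output="raw"), [0.2, 0.8], atol=1e-4)

    def test_gain(self, two_cell_fit):
        model, _, _ = two_cell_fit
        assert model.reg_gain == pytest.approx(TWO_CELL_GAIN, abs=1e-4)

    def test_logistic_monotone_in_feature(self, two_cell_fit):
        model, _, _ = two_cell_fit
        f = np.linspace(0, 1, 11)[:, None]
        out = predict(model, f, output="logistic")
        assert np.all(np.diff(out) > 0)

    def test_matched_moments_give_zero_lambda_and_gain(self):
        B = np.array([[0.0], [0.5], [1.0]])
        P = np.array([[0.5], [0.5]])  # presence mean equals background mean
        model = fit_maxent(P, B, reg_multiplier=2.0, tol=1e-12)
        np.testing.assert_allclose(model.lambdas, 0.0, atol=1e-6)
        assert model.reg_gain == pytest.approx(0.0, abs=1e-8)

    def test_uniform_model_logistic_half(self):
        B = np.full((5, 1), 0.3)
        P = np.full((2, 1), 0.3)
        model = fit_maxent(P, B, reg_multiplier=0.0)
        np.testing.assert_allclose(predict(model, B, output="logistic"), 0.5, atol=1e-10)
        assert model.entropy_H == pytest.approx(np.log(5))


class TestFitProperties:
    def test_raw_sums_to_one_over_background(self, small_dataset, small_thinned):
        stack = small_dataset.stack
        xy = small_thinned.xy
        r, c = stack.spec.index_of(xy[:, 0], xy[:, 1])
        bg = sample_background(stack, n=1500, seed=0)
        exp = build_features(bg.table, n_presences=len(small_thinned), hinge_knots=10)
        B = exp.transform(bg.table)
        P = exp.transform(stack_table(stack, r, c))
        model = fit_maxent(P, B, expansion=exp)
        assert predict(model, B, output="raw").sum() == pytest.approx(1.0, abs=1e-8)

    def test_concavity_objective_independent_of_init(self):
        rng = np.random.default_rng(4)
        B = rng.uniform(size=(200, 5))
        P = rng.uniform(size=(30, 5)) ** 2
        gains = []
        for i in range(5):
            init = rng.normal(scale=0.5, size=5)
            m = fit_maxent(P, B, tol=1e-14, init=init, max_iter=5000)
            gains.append(m.reg_gain)
        assert max(gains) - min(gains) < 1e-6

    def test_l1_shrinkage_monotone_in_multiplier(self):
        rng = np.random.default_rng(5)
        for trial in range(5):
            B = rng.uniform(size=(150, 4))
            P = rng.uniform(size=(25, 4)) ** 2
            norms = []
            for r in [0.25, 0.5, 1.0, 2.0, 4.0]:
                m = fit_maxent(P, B, reg_multiplier=r, tol=1e-12)
                norms.append(np.abs(m.lambdas).sum())
            assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_gain_never_decreases_with_less_penalty(self):
        rng = np.random.default_rng(6)
        B = rng.uniform(size=(150, 4))
        P = rng.uniform(size=(25, 4)) ** 2
        g_strong = fit_maxent(P, B, reg_multiplier=2.0, tol=1e-12).reg_gain
        g_weak = fit_maxent(P, B, reg_multiplier=0.5, tol=1e-12).reg_gain
        assert g_weak >= g_strong - 1e-9

    def test_model_json_round_trip_reproduces_predictions(self, tmp_path):
        rng = np.random.default_rng(7)
        bg = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
        exp = build_features(bg, n_presences=20, hinge_knots=6)
        B = exp.transform(bg)
        P = B[:40]
        model = fit_maxent(P, B, expansion=exp)
        path = tmp_path / "model.json"
        model.save(path)
        clone = MaxentModel.load(path)
        x = {"a": np.linspace(-2, 2, 9), "b": np.linspace(2, -2, 9)}
        np.testing.assert_allclose(
            predict(model, exp.transform(x)), predict(clone, clone.expansion.transform(x)), atol=1e-12
        )


class TestBackgroundSampling:
    def test_exhaustion_returns_all_unmasked(self, constant_stack):
        bg = sample_background(constant_stack, n=10000, seed=0)
        assert bg.m == 80

    def test_same_seed_same_sample(self, small_dataset):
        a = sample_background(small_dataset.stack, n=500, seed=9)
        b = sample_background(small_dataset.stack, n=500, seed=9)
        np.testing.assert_array_equal(a.cell_rows, b.cell_rows)
        np.testing.assert_array_equal(a.cell_cols, b.cell_cols)

    def test_uniform_inclusion_rate(self, unit_spec):
        import maxenm

        layer = maxenm.Layer("z", np.ma.asarray(np.zeros((8, 10))))
        stack = maxenm.RasterStack(unit_spec, [layer])
        counts = np.zeros((8, 10))
        n_seeds = 200
        for seed in range(n_seeds):
            bg = sample_background(stack, n=8, seed=seed)
            counts[bg.cell_rows, bg.cell_cols] += 1
        rate = counts / n_seeds  # expected 8/80 = 0.1
        se = np.sqrt(0.1 * 0.9 / n_seeds)
        assert np.all(np.abs(rate - 0.1) < 5 * se)

    def test_fully_masked_stack_rejected(self, unit_spec):
        import maxenm

        vals = np.ma.masked_all((8, 10))
        stack = maxenm.RasterStack(unit_spec, [maxenm.Layer("m", vals)])
        with pytest.raises(ValueError):
            sample_background(stack, n=10, seed=0)


def _symmetric_two_var_data(seed=0, n_bg=2000, n_pres=300):
    """Two independent, identically informative variables."""
    rng = np.random.default_rng(seed)
    bg = pd.DataFrame({"u": rng.normal(size=n_bg), "v": rng.normal(size=n_bg)})
    w = np.exp(-(bg["u"] ** 2) / 0.5) * np.exp(-(bg["v"] ** 2) / 0.5)
    idx = rng.choice(n_bg, size=n_pres, p=w / w.sum())
    pres = bg.iloc[idx].reset_index(drop=True)
    return bg, pres


class TestContributions:
    def test_single_variable_is_100(self):
        rng = np.random.default_rng(8)
        bg = pd.DataFrame({"only": rng.normal(size=300)})
        w = np.exp(-((bg["only"] - 0.3) ** 2))
        pres = bg.iloc[rng.choice(300, size=30, p=w / w.sum())]
        exp = build_features(bg, n_presences=30, hinge_knots=5)
        B, P = exp.transform(bg), exp.transform(pres)
        model = fit_maxent(P, B, expansion=exp)
        assert variable_contribution(model, P, B) == {"only": 100.0}

    def test_symmetric_variables_split_evenly(self):
        bg, pres = _symmetric_two_var_data()
        exp = build_features(bg, n_presences=len(pres), hinge_knots=10)
        B, P = exp.transform(bg), exp.transform(pres)
        model = fit_maxent(P, B, expansion=exp)
        contrib = variable_contribution(model, P, B)
        assert contrib["u"] == pytest.approx(50.0, abs=5.0)
        assert contrib["v"] == pytest.approx(50.0, abs=5.0)

    def test_exact_duplicate_contributes_nothing(self):
        bg, pres = _symmetric_two_var_data(seed=1)
        bg["u_dup"] = bg["u"]
        pres["u_dup"] = pres["u"]
        exp = build_features(bg, n_presences=len(pres), hinge_knots=10)
        B, P = exp.transform(bg), exp.transform(pres)
        model = fit_maxent(P, B, expansion=exp)
        contrib = variable_contribution(model, P, B)
        # the twin compensates: removing either copy costs (almost) no gain
        assert min(contrib["u"], contrib["u_dup"]) < 2.0


class TestJackknife:
    def test_informative_variable_beats_noise(self):
        rng = np.random.default_rng(9)
        bg = pd.DataFrame({"signal": rng.normal(size=1500), "noise": rng.normal(size=1500)})
        w = np.exp(-((bg["signal"] - 0.5) ** 2) / 0.125)
        idx = rng.choice(1500, size=150, p=w / w.sum())
        pres = bg.iloc[idx].reset_index(drop=True)
        exp = build_features(bg, n_presences=150, hinge_knots=10)
        aucs = jackknife_auc(exp.transform(pres), exp.transform(bg), exp)
        assert aucs["signal"] > aucs["noise"]
        assert aucs["signal"] > 0.7

    def test_affine_recoding_gives_equal_auc(self):
        rng = np.random.default_rng(10)
        bg = pd.DataFrame({"x": rng.normal(size=800)})
        bg["x_scaled"] = 3.0 * bg["x"] - 7.0
        w = np.exp(-(bg["x"] ** 2))
        idx = rng.choice(800, size=100, p=w / w.sum())
        pres = bg.iloc[idx].reset_index(drop=True)
        exp = build_features(bg, n_presences=100, hinge_knots=8)
        aucs = jackknife_auc(exp.transform(pres), exp.transform(bg), exp)
        assert aucs["x"] == pytest.approx(aucs["x_scaled"], abs=1e-6)


class TestResponseCurves:
    def test_uniform_model_flat_at_half(self):
        rng = np.random.default_rng(11)
        bg = pd.DataFrame({"a": rng.normal(size=200)})
        exp = build_features(bg, n_presences=5)
        B = exp.transform(bg)
        model = fit_maxent(B[:10], B, expansion=exp, reg_multiplier=0.0)
        model.lambdas[:] = 0.0
        model.log_normalizer = np.log(len(bg))
        model.entropy_H = np.log(len(bg))
        curve = response_curve(model, "a")
        np.testing.assert_allclose(curve.mean, 0.5, atol=1e-12)

    def test_curve_values_within_unit_interval(self, small_dataset, small_thinned):
        stack = small_dataset.stack
        xy = small_thinned.xy
        r, c = stack.spec.index_of(xy[:, 0], xy[:, 1])
        bg = sample_background(stack, n=1000, seed=1)
        exp = build_features(bg.table, n_presences=len(small_thinned), hinge_knots=10)
        model = fit_maxent(
            exp.transform(stack_table(stack, r, c)), exp.transform(bg.table), expansion=exp
        )
        for v in ("clim_a", "clim_b"):
            curve = response_curve(model, v)
            assert np.all((curve.mean >= 0) & (curve.mean <= 1))

    def test_unknown_variable_rejected(self, small_dataset):
        bg = sample_background(small_dataset.stack, n=200, seed=2)
        exp = build_features(bg.table, n_presences=20, hinge_knots=4)
        B = exp.transform(bg.table)
        model = fit_maxent(B[:20], B, expansion=exp)
        with pytest.raises(KeyError):
            response_curve(model, "no_such_layer")
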