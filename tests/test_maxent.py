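"""Penalized maximum-entropy model: features, fit, prediction, evaluation.

The fit is checked against three independent oracles: a closed-form moment
condition on a two-cell background, a generic scipy optimizer on the same
objective, and the defining moment-matching / KKT identities of penalized
maximum entropy.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import spearmanr

import invasionrisk as ir
from invasionrisk.maxent import FeatureSet, _objective


def _linear_fs(names):
    return FeatureSet(definitions=[],
                      clamp={n: (0.0, 1.0) for n in names},
                      scale=[], means={n: 0.5 for n in names})


def fit_matrices(f_pres, f_bg, lam=0.0, **kw):
    """Fit directly from feature matrices, with a placeholder feature set."""
    fs = _linear_fs([f"v{j}" for j in range(f_pres.shape[1])])
    return ir.fit(np.asarray(f_pres, float), np.asarray(f_bg, float), fs,
                  lam=lam, **kw)


# ---------------------------------------------------------------------------
# Feature expansion
# ---------------------------------------------------------------------------

class TestBuildFeatures:
    def test_linear_features_are_affine_rescales(self):
        table = pd.DataFrame({"x": [0.0, 5.0, 10.0], "y": [2.0, 3.0, 4.0]})
        fs, mat = ir.build_features(table, classes=("linear",))
        assert mat.shape == (3, 2)
        assert np.allclose(mat[:, 0], [0.0, 0.5, 1.0])
        assert np.allclose(mat[:, 1], [0.0, 0.5, 1.0])

    def test_quadratic_is_square_of_raw_rescaled(self):
        table = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        fs, mat = ir.build_features(table, classes=("linear", "quadratic"))
        assert mat.shape == (3, 2)
        # raw quadratic is x^2 in {0,1,4}, rescaled to [0,1]
        assert np.allclose(mat[:, 1], [0.0, 0.25, 1.0])

    def test_hinge_basis_matches_hand_computation(self):
        table = pd.DataFrame({"x": np.arange(11, dtype=float)})
        fs, mat = ir.build_features(table, classes=("hinge",), n_hinge_knots=3)
        assert mat.shape == (11, 6)
        # knots at 2.5, 5, 7.5; probe x = 6
        probe = fs.evaluate(pd.DataFrame({"x": [6.0]}))
        expected = []
        for knot in (2.5, 5.0, 7.5):
            for orient in (+1, -1):
                raw = max(0.0, orient * (6.0 - knot))
                lo = 0.0
                hi = max(max(0.0, orient * (x - knot)) for x in range(11))
                expected.append((raw - lo) / (hi - lo))
        assert np.allclose(np.sort(probe.ravel()), np.sort(expected))

    def test_constant_variable_drops_nonlinear_features(self, caplog):
        table = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [0.0, 1.0, 2.0]})
        with caplog.at_level("WARNING"):
            fs, mat = ir.build_features(table, classes=("linear", "quadratic"))
        assert "constant" in caplog.text
        kinds = [(d.kind, d.variables[0]) for d in fs.definitions]
        assert ("quadratic", "x") not in kinds
        assert ("quadratic", "y") in kinds


# ---------------------------------------------------------------------------
# Background sampling
# ---------------------------------------------------------------------------

class TestSampleBackground:
    def test_cap_binds_only_above_cell_count(self, landscape):
        stack, _ = landscape  # 30x30, fully valid
        bg = ir.sample_background(stack, n=10_000, seed=0)
        assert len(bg) == 900
        bg5 = ir.sample_background(stack, n=5, seed=0)
        assert len(bg5) == 5
        assert not bg5.duplicated(subset=["_row", "_col"]).any()

    def test_seeded_determinism_and_presence_flagging(self, landscape):
        stack, truth = landscape
        occ = ir.sample_occurrences(truth, stack, 20, seed=1)
        a = ir.sample_background(stack, n=50, seed=3, presences=occ)
        b = ir.sample_background(stack, n=50, seed=3, presences=occ)
        assert a.equals(b)
        assert (a["is_presence"] == 1).sum() == 20


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFit:
    def test_closed_form_two_cell_background(self):
        # single linear feature, background {0,1}, presence mean 0.7:
        # the moment condition e^b/(1+e^b) = 0.7 gives b = ln(7/3)
        f_bg = np.array([[0.0], [1.0]])
        f_pres = np.array([[0.7]])
        model = fit_matrices(f_pres, f_bg, lam=0.0)
        assert model.beta[0] == pytest.approx(np.log(7 / 3), abs=1e-6)
        # independent grid-search oracle over beta
        grid = np.linspace(-3, 3, 200_001)
        obj = 0.7 * grid - np.logaddexp(0.0, grid)
        assert grid[np.argmax(obj)] == pytest.approx(model.beta[0], abs=1e-4)

    def test_symmetric_data_gives_zero_beta(self):
        rng = np.random.default_rng(0)
        f_bg = rng.random((200, 3))
        # presences drawn uniformly from the background rows: no signal
        f_pres = f_bg[rng.choice(200, size=200, replace=False)]
        model = fit_matrices(f_pres, f_bg, lam=0.0)
        assert np.allclose(model.beta, 0.0, atol=1e-4)

    def test_huge_penalty_zeroes_all_coefficients_exactly(self):
        rng = np.random.default_rng(1)
        f_bg = rng.random((100, 4))
        f_pres = rng.random((30, 4)) ** 2
        model = fit_matrices(f_pres, f_bg, lam=1e6)
        assert np.array_equal(model.beta, np.zeros(4))

    def test_moment_matching_identity_unpenalized(self):
        rng = np.random.default_rng(2)
        f_bg = rng.random((300, 4))
        weights = np.exp(f_bg @ np.array([2.0, -1.0, 0.5, 0.0]))
        idx = rng.choice(300, size=150, p=weights / weights.sum())
        f_pres = f_bg[idx]
        model = fit_matrices(f_pres, f_bg, lam=0.0)
        p = np.exp(f_bg @ model.beta - model.log_z)
        gap = np.abs(p @ f_bg - f_pres.mean(axis=0))
        assert gap.max() < 1e-6

    def test_kkt_box_under_penalty(self):
        rng = np.random.default_rng(3)
        f_bg = rng.random((300, 4))
        weights = np.exp(f_bg @ np.array([2.0, -1.0, 0.5, 0.0]))
        f_pres = f_bg[rng.choice(300, size=150, p=weights / weights.sum())]
        lam = np.array([0.01, 0.05, 0.1, 0.2])
        model = fit_matrices(f_pres, f_bg, lam=lam)
        p = np.exp(f_bg @ model.beta - model.log_z)
        gap = np.abs(p @ f_bg - f_pres.mean(axis=0))
        assert (gap <= lam + 1e-6).all()

    def test_agrees_with_generic_optimizer(self):
        rng = np.random.default_rng(4)
        f_bg = rng.random((150, 3))
        weights = np.exp(f_bg @ np.array([1.5, -2.0, 0.0]))
        f_pres = f_bg[rng.choice(150, size=80, p=weights / weights.sum())]
        model = fit_matrices(f_pres, f_bg, lam=0.0)
        res = minimize(lambda b: -_objective(b, f_pres, f_bg, np.zeros(3)),
                       np.zeros(3), method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        p_mine = np.exp(f_bg @ model.beta - model.log_z)
        eta_o = f_bg @ res.x
        p_oracle = np.exp(eta_o - eta_o.max())
        p_oracle /= p_oracle.sum()
        kl = float(np.sum(p_mine * np.log(p_mine / p_oracle)))
        assert abs(kl) < 1e-6

    def test_nonfinite_features_rejected(self):
        f_bg = np.array([[0.0], [np.inf]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_matrices(np.array([[0.5]]), f_bg)

    def test_raw_background_distribution_sums_to_one(self):
        rng = np.random.default_rng(5)
        f_bg = rng.random((120, 2))
        f_pres = rng.random((40, 2)) ** 0.5
        model = fit_matrices(f_pres, f_bg, lam=0.01)
        raw = np.exp(f_bg @ model.beta - model.log_z)
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)
        assert model.entropy >= 0


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

class TestPredict:
    def _uniform_model(self, n_bg=25):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"x": rng.random(n_bg), "y": rng.random(n_bg)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:5], mat, fs, lam=1e9)  # forces beta = 0
        return model, table

    def test_uniform_model_closed_form(self):
        model, table = self._uniform_model(25)
        raw = ir.predict_raw(model, table)
        assert np.allclose(raw, 1 / 25)
        assert model.entropy == pytest.approx(np.log(25))
        clog = ir.predict_cloglog(model, table)
        assert np.allclose(clog, 1 - np.exp(-1.0))

    def test_cloglog_strictly_increasing_in_eta(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({"x": rng.random(50), "y": rng.random(50)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:10] ** 2, mat, fs, lam=0.0)
        eta = model.eta(table)
        clog = ir.predict_cloglog(model, table)
        order = np.argsort(eta)
        d_eta = np.diff(eta[order])
        d_clog = np.diff(clog[order])
        assert (d_clog[d_eta > 1e-12] > 0).all()
        assert ((clog > 0) & (clog < 1)).all()

    def test_out_of_range_probe_is_clamped(self):
        model, table = self._uniform_model()
        rng = np.random.default_rng(8)
        t2 = pd.DataFrame({"x": rng.random(30), "y": rng.random(30)})
        fs, mat = ir.build_features(pd.concat([table, t2], ignore_index=True)[:25],
                                    classes=("linear", "quadratic"))
        m = ir.fit(mat[:6], mat, fs, lam=0.0)
        lo, hi = m.features.clamp["x"]
        probe = pd.DataFrame({"x": [hi + 5.0], "y": [0.5]})
        at_edge = pd.DataFrame({"x": [hi], "y": [0.5]})
        assert ir.predict_cloglog(m, probe) == pytest.approx(
            ir.predict_cloglog(m, at_edge))

    def test_unknown_variable_errors(self):
        model, _ = self._uniform_model()
        with pytest.raises(KeyError):
            ir.predict_cloglog(model, pd.DataFrame({"x": [0.1]}))  # 'y' missing


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def auc_bruteforce(pres, bg):
    wins = sum((1.0 if p > b else 0.5 if p == b else 0.0)
               for p in pres for b in bg)
    return wins / (len(pres) * len(bg))


class TestAuc:
    def test_perfect_separation(self):
        assert ir.auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_all_ties(self):
        assert ir.auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_hand_fixture_by_pair_enumeration(self):
        pres, bg = [0.9, 0.4], [0.5, 0.3, 0.4]
        expected = auc_bruteforce(pres, bg)  # = (1+1+1+0+1+0.5)/6
        assert expected == pytest.approx(4.5 / 6)
        assert ir.auc(pres, bg) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        pres = np.round(rng.random(rng.integers(1, 60)), 2)  # rounding forces ties
        bg = np.round(rng.random(rng.integers(1, 60)), 2)
        assert ir.auc(pres, bg) == pytest.approx(auc_bruteforce(pres, bg), abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ir.auc([], [0.5])


# ---------------------------------------------------------------------------
# Cross-validation, ensembles, importance, response curves
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted_landscape():
    stack, truth = ir.make_landscape(seed=21, rows=30, cols=30, n_predictors=4,
                                     null_fraction=0.5, beta_scale=2.0)
    occ = ir.sample_occurrences(truth, stack, 150, seed=22)
    stack = stack.subset(truth.predictor_names)
    bg = ir.sample_background(stack, 10_000, seed=23, presences=occ)
    pres = (bg[bg["is_presence"] == 1].drop(columns="is_presence")
            .reset_index(drop=True))
    joint = pd.concat([pres, bg], ignore_index=True)
    fs, mat = ir.build_features(joint, classes=("linear", "quadratic"))
    lam = ir.default_lambdas(fs, mat[: len(pres)])
    model = ir.fit(mat[: len(pres)], mat[len(pres):], fs, lam=lam)
    return stack, truth, occ, bg, pres, model


class TestKfold:
    def test_partition_arithmetic_and_consistency(self, fitted_landscape):
        stack, truth, occ, bg, pres, _ = fitted_landscape
        report, models = ir.kfold_evaluate(pres.iloc[:4], bg,
                                           features_kw={"classes": ("linear",)},
                                           k=2, seed=1)
        assert report.fold_sizes == [2, 2]
        assert len(report.fold_aucs) == 2
        assert report.mean_auc == pytest.approx(np.mean(report.fold_aucs))
        assert report.sd_auc == pytest.approx(np.std(report.fold_aucs))

    def test_k_larger_than_presences_rejected(self, fitted_landscape):
        _, _, _, bg, pres, _ = fitted_landscape
        with pytest.raises(ValueError):
            ir.kfold_evaluate(pres.iloc[:3], bg, k=5)

    def test_informative_truth_scores_high_null_truth_scores_half(self):
        stack, truth = ir.make_landscape(seed=31, rows=40, cols=40,
                                         n_predictors=3, null_fraction=0.0,
                                         beta_scale=2.5)
        occ = ir.sample_occurrences(truth, stack, 200, seed=32)
        bg = ir.sample_background(stack, 10_000, seed=33, presences=occ)
        pres = (bg[bg["is_presence"] == 1].drop(columns="is_presence")
                .reset_index(drop=True))
        rep, _ = ir.kfold_evaluate(pres, bg, features_kw={"classes": ("linear",)},
                                   k=5, seed=34)
        assert rep.mean_auc >= 0.9

        flat = ir.LandscapeTruth(predictor_names=truth.predictor_names,
                                 true_coefficients=np.zeros(3),
                                 intercept=0.0, grid=truth.grid)
        occ0 = ir.sample_occurrences(flat, stack, 200, seed=35)
        bg0 = ir.sample_background(stack, 10_000, seed=36, presences=occ0)
        pres0 = (bg0[bg0["is_presence"] == 1].drop(columns="is_presence")
                 .reset_index(drop=True))
        rep0, _ = ir.kfold_evaluate(pres0, bg0,
                                    features_kw={"classes": ("linear",)},
                                    k=5, seed=37)
        assert 0.4 <= rep0.mean_auc <= 0.6


class TestEnsemble:
    def test_identical_models_have_zero_sd(self, fitted_landscape):
        stack, _, _, _, _, model = fitted_landscape
        mean_r, sd_r = ir.ensemble_predict([model, model, model], stack)
        v = sd_r.values[np.isfinite(sd_r.values)]
        assert np.allclose(v, 0.0)
        mv = mean_r.values[np.isfinite(mean_r.values)]
        assert ((mv > 0) & (mv < 1)).all()

    def test_two_constant_models_average_closed_forms(self):
        # two featureless models over backgrounds of different size N have
        # constant cloglog 1 - e^-1; their mean is hand-computable
        rng = np.random.default_rng(9)
        vals = rng.random((10, 10))
        h = ir.GridHeader(ncols=10, nrows=10, xllcorner=0, yllcorner=0,
                          cellsize=0.1)
        stack = ir.RasterStack({"x": ir.Raster(values=vals, header=h, name="x")})
        models = []
        for n_bg in (25, 64):
            table = pd.DataFrame({"x": rng.random(n_bg)})
            fs, mat = ir.build_features(table, classes=("linear",))
            models.append(ir.fit(mat[:5], mat, fs, lam=1e9))
        mean_r, _ = ir.ensemble_predict(models, stack)
        assert np.allclose(mean_r.values, 1 - np.exp(-1.0))

    def test_empty_model_list_rejected(self, fitted_landscape):
        stack = fitted_landscape[0]
        with pytest.raises(ValueError):
            ir.ensemble_predict([], stack)


class TestPermutationImportance:
    def test_percentages_sum_to_100_and_nulls_rank_low(self, fitted_landscape):
        stack, truth, occ, bg, pres, model = fitted_landscape
        imp = ir.permutation_importance(model, pres, bg, seed=1, n_repeats=3)
        assert sum(imp.importance.values()) == pytest.approx(100.0, abs=0.1)
        informative = [n for n, b in zip(truth.predictor_names,
                                         truth.true_coefficients) if b != 0]
        top = max(imp.importance, key=imp.importance.get)
        assert top in informative

    def test_single_variable_model_gets_all_importance(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame({"x": rng.random(200)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:50] ** 2, mat, fs, lam=0.0)
        imp = ir.permutation_importance(model, table.iloc[:50], table, seed=2)
        assert imp.importance["x"] == pytest.approx(100.0)

    def test_ignored_variable_has_zero_importance(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame({"x": rng.random(200), "z": rng.random(200)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:50], mat, fs, lam=0.0)
        model.beta[1] = 0.0  # force the model to ignore z
        model.beta[0] = 2.0
        imp = ir.permutation_importance(model, table.iloc[:50], table, seed=3)
        assert imp.importance["z"] == 0.0


class TestResponseCurve:
    def test_positive_linear_coefficient_monotone_curve(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame({"x": rng.random(100), "y": rng.random(100)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:30], mat, fs, lam=0.0)
        model.beta[:] = [2.0, 0.0]
        xs, ys = ir.response_curve(model, "x", n_points=50)
        assert (np.diff(ys) > 0).all()

    def test_flat_for_featureless_model(self):
        rng = np.random.default_rng(13)
        table = pd.DataFrame({"x": rng.random(50)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:10], mat, fs, lam=1e9)
        _, ys = ir.response_curve(model, "x")
        assert np.allclose(ys, 1 - np.exp(-1.0))

    def test_concave_quadratic_peaks_at_analytic_vertex(self):
        table = pd.DataFrame({"x": np.linspace(0, 10, 101)})
        fs, mat = ir.build_features(table, classes=("linear", "quadratic"))
        model = ir.fit(mat[:20], mat, fs, lam=0.0)
        # eta = b1*(x/10) + b2*(x^2/100): vertex at x = -50*b1/(10*b2)
        model.beta[:] = [4.0, -4.0]
        xs, ys = ir.response_curve(model, "x", n_points=501)
        vertex = -model.beta[0] / 10.0 / (2 * model.beta[1] / 100.0)
        assert xs[np.argmax(ys)] == pytest.approx(vertex, abs=0.05)

    def test_unknown_variable_rejected(self):
        table = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        fs, mat = ir.build_features(table, classes=("linear",))
        model = ir.fit(mat[:5], mat, fs, lam=0.0)
        with pytest.raises(KeyError):
            ir.response_curve(model, "nope")


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, fitted_landscape, tmp_path):
        stack, _, _, bg, pres, model = fitted_landscape
        p = tmp_path / "model.json"
        model.to_json(p)
        back = ir.MaxentModel.from_json(p)
        assert np.allclose(ir.predict_cloglog(back, pres),
                           ir.predict_cloglog(model, pres))


class TestParameterRecovery:
    def test_spearman_between_true_and_estimated_eta(self):
        stack, truth = ir.make_landscape(seed=41, rows=60, cols=60,
                                         n_predictors=4, null_fraction=0.5,
                                         beta_scale=2.0)
        occ = ir.sample_occurrences(truth, stack, 400, seed=42)
        bg = ir.sample_background(stack, 10_000, seed=43, presences=occ)
        pres = (bg[bg["is_presence"] == 1].drop(columns="is_presence")
                .reset_index(drop=True))
        joint = pd.concat([pres, bg], ignore_index=True)
        fs, mat = ir.build_features(joint, classes=("linear",))
        model = ir.fit(mat[: len(pres)], mat[len(pres):], fs, lam=0.0)
        rows, cols = np.nonzero(stack.valid_mask())
        cell_table = stack.table(rows, cols)
        eta_hat = model.eta(cell_table)
        eta_true = truth.eta(stack)[rows, cols]
        rho = spearmanr(eta_true, eta_hat).statistic
        assert rho >= 0.9
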