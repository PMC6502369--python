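import numpy as np
import pandas as pd
import pytest

from hissbrn.paths import (
    MatrixError,
    PathModel,
    compare_models,
    default_models,
    fit_over_posterior,
    fit_path_model,
    nest_success_stage,
)
from hissbrn.traits import TRAIT_ORDER


def closed_form_coefficients(s, model):
    """Independent oracle: per-equation least-squares partial coefficients."""
    idx = {v: i for i, v in enumerate(model.variables)}
    out = {}
    for child in model.endogenous:
        parents = [a for a, b in model.edges if b == child]
        pi = [idx[p] for p in parents]
        b = np.linalg.solve(s[np.ix_(pi, pi)], s[pi, idx[child]])
        for p, coef in zip(parents, b):
            out[(p, child)] = coef
    return out


def random_pd_correlation(rng, p=5, n=40):
    a = rng.standard_normal((p, n))
    return np.corrcoef(a)


class TestPathModel:
    def test_free_parameter_count(self):
        m0, m1, m2, m3 = default_models()
        assert m0.n_free == 5
        assert m1.n_free == 10
        assert m2.n_free == 11
        assert m3.n_free == 12
        assert m0.edges == ()

    def test_cyclic_model_rejected(self):
        with pytest.raises(ValueError):
            PathModel(
                "cyc",
                (("lay_date", "clutch_size"), ("clutch_size", "lay_date")),
            )

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError):
            PathModel("bad", (("lay_date", "egg_colour"),))


class TestFitPathModel:
    def test_identity_matrix_gives_zero_coefficients(self):
        fit = fit_path_model(np.eye(5), default_models()[3], 77)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-10)
        assert all(abs(c) < 1e-6 for c in fit.coefficients.values())

    def test_chain_construction_recovers_weights(self):
        s = np.array([[1, 0.5, 0.25], [0.5, 1, 0.5], [0.25, 0.5, 1.0]])
        model = PathModel("chain", (("x", "y"), ("y", "z")), ("x", "y", "z"))
        fit = fit_path_model(s, model, 77)
        assert fit.coefficients[("x", "y")] == pytest.approx(0.5, abs=1e-6)
        assert fit.coefficients[("y", "z")] == pytest.approx(0.5, abs=1e-6)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("model_index", [1, 2, 3])
    @pytest.mark.parametrize("matrix_seed", [0, 1, 2])
    def test_ml_equals_least_squares_partials(self, model_index, matrix_seed):
        rng = np.random.default_rng(matrix_seed)
        s = random_pd_correlation(rng)
        model = default_models()[model_index]
        fit = fit_path_model(s, model, 77)
        oracle = closed_form_coefficients(s, model)
        for edge, expected in oracle.items():
            assert fit.coefficients[edge] == pytest.approx(expected, abs=1e-6)

    def test_saturated_model_reproduces_the_matrix(self, rng):
        s = random_pd_correlation(rng)
        edges = tuple(
            (TRAIT_ORDER[i], TRAIT_ORDER[j])
            for j in range(5)
            for i in range(j)
        )
        model = PathModel("saturated", edges)
        fit = fit_path_model(s, model, 77)
        assert fit.f_ml == pytest.approx(0.0, abs=1e-9)
        oracle = closed_form_coefficients(s, model)
        for edge, expected in oracle.items():
            assert fit.coefficients[edge] == pytest.approx(expected, abs=1e-6)

    def test_adding_an_edge_never_increases_chi_square(self, rng):
        for _ in range(3):
            s = random_pd_correlation(rng)
            _, m1, m2, m3 = default_models()
            chi = [fit_path_model(s, m, 77).chi2 for m in (m1, m2, m3)]
            assert chi[2] <= chi[1] + 1e-6
            assert chi[1] <= chi[0] + 1e-6

    def test_non_pd_input_rejected(self):
        bad = np.ones((5, 5))
        with pytest.raises(MatrixError):
            fit_path_model(bad, default_models()[0], 77)
        with pytest.raises(MatrixError):
            fit_path_model(np.eye(4), default_models()[0], 77)


class TestFitOverPosterior:
    def test_degenerate_posterior_has_zero_width(self, rng):
        s = random_pd_correlation(rng)
        mats = np.repeat(s[None], 100, axis=0)
        fit = fit_over_posterior(mats, default_models()[3], 77)
        widths = fit.coefficients["upper95"] - fit.coefficients["lower95"]
        assert np.all(widths < 1e-8)
        assert fit.mean_aic == pytest.approx(fit.aic_samples[0])

    def test_too_few_samples_rejected(self, rng):
        mats = np.repeat(random_pd_correlation(rng)[None], 50, axis=0)
        with pytest.raises(ValueError):
            fit_over_posterior(mats, default_models()[0], 77)

    def test_excess_flagged_samples_abort(self, rng):
        good = np.repeat(random_pd_correlation(rng)[None], 85, axis=0)
        bad = np.repeat(np.ones((5, 5))[None], 15, axis=0)
        mats = np.concatenate([good, bad])
        with pytest.raises(RuntimeError):
            fit_over_posterior(mats, default_models()[0], 77)


class TestCompareModels:
    def test_single_model_has_zero_delta(self, rng):
        mats = np.stack([random_pd_correlation(rng) for _ in range(100)])
        res = compare_models([default_models()[0]], mats, 77)
        assert res.table["delta_aic"].tolist() == [0.0]

    def test_duplicate_names_rejected(self, rng):
        mats = np.stack([random_pd_correlation(rng) for _ in range(100)])
        models = [default_models()[0], default_models()[0]]
        with pytest.raises(ValueError):
            compare_models(models, mats, 77)

    def test_ordering_invariant_to_evaluation_order(self, rng):
        mats = np.stack([random_pd_correlation(rng) for _ in range(100)])
        res_a = compare_models(default_models(), mats, 77)
        res_b = compare_models(default_models()[::-1], mats, 77)
        a = res_a.table.set_index("model")["mean_aic"]
        b = res_b.table.set_index("model")["mean_aic"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


def _success_data(rng, n=300, clutch_effect=0.0):
    females = pd.DataFrame(
        {
            "female_id": [f"F{i}" for i in range(n)],
            "lay_date": rng.standard_normal(n),
            "clutch_size": rng.standard_normal(n),
            "nest_success": 0,
            "n_fledged": np.nan,
            "mean_fledgling_mass": np.nan,
        }
    )
    effects = pd.DataFrame(
        {
            "female_id": females["female_id"],
            "intercept_dev": rng.standard_normal(n),
            "slope_dev": 0.0,
        }
    )
    eta = 1.0 + clutch_effect * females["clutch_size"].to_numpy()
    females["nest_success"] = (
        rng.random(n) < 1 / (1 + np.exp(-eta))
    ).astype(int)
    return females, effects


class TestNestSuccessStage:
    def test_strong_clutch_effect_detected(self, rng):
        females, effects = _success_data(rng, n=400, clutch_effect=1.5)
        table = nest_success_stage(females, effects)
        row = table[table["term"] == "clutch_size"].iloc[0]
        assert row["supported"]
        assert row["estimate"] > 0

    def test_single_class_rejected(self, rng):
        females, effects = _success_data(rng)
        females["nest_success"] = 1
        with pytest.raises(ValueError):
            nest_success_stage(females, effects)

    def test_separation_falls_back_to_penalized_fit(self, rng):
        females, effects = _success_data(rng, n=40)
        # success perfectly determined by clutch size -> separation
        females["nest_success"] = (females["clutch_size"] > 0).astype(int)
        table = nest_success_stage(females, effects)
        assert (table["method"] == "firth").all()
        assert np.isfinite(table[["estimate", "lower95", "upper95"]]).all().all()
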