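import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hissbrn.design import build_design
from hissbrn.simulate import (
    CausalScenario,
    CountCalibration,
    ParameterError,
    ReactionNormParams,
    SCENARIOS,
    counts_from_latent,
    couple_intercepts,
    simulate_brn,
    simulate_reproduction,
)


class TestReactionNormParams:
    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ParameterError):
            ReactionNormParams(var_intercept=0.1, var_slope=0.001, cov_int_slope=0.5)

    def test_negative_variance_rejected(self):
        with pytest.raises(ParameterError):
            ReactionNormParams(var_intercept=-1.0)


class TestSimulateBrn:
    def test_degenerate_generator_is_all_zero(self):
        design = build_design(5, {5: 5})
        params = ReactionNormParams(
            beta0=0, beta_day=0, beta_julian=0, beta_time_mean=0,
            beta_time_dev=0, beta_age_adult=0, beta_age_unknown=0,
            var_intercept=0, var_slope=0, cov_int_slope=0, var_resid=0,
        )
        trials = simulate_brn(design, params, seed=1)
        assert np.allclose(trials["hiss_std"], 0.0)

    def test_intercept_variance_moment(self):
        # with no noise, slopes or covariate effects, the variance of
        # per-female means is the configured among-individual variance
        design = build_design(8000, {5: 8000})
        params = ReactionNormParams(
            beta0=0, beta_day=0, beta_julian=0, beta_time_mean=0,
            beta_time_dev=0, beta_age_adult=0, beta_age_unknown=0,
            var_intercept=0.85, var_slope=0, cov_int_slope=0, var_resid=0,
        )
        trials = simulate_brn(design, params, seed=2)
        means = trials.groupby("female_id")["hiss_std"].mean()
        assert means.var(ddof=1) == pytest.approx(0.85, rel=0.05)

    def test_population_slope_recovered_by_ols(self):
        design = build_design(4000, {5: 4000})
        params = ReactionNormParams(
            beta_day=0.02, var_slope=0, cov_int_slope=0,
        )
        trials = simulate_brn(design, params, seed=3)
        x = trials["day_centred"].to_numpy()
        y = trials["hiss_std"].to_numpy()
        # within-female centring removes the intercept heterogeneity
        yc = y - trials.groupby("female_id")["hiss_std"].transform("mean")
        xc = x - trials.groupby("female_id")["day_centred"].transform("mean")
        slope = (xc @ yc) / (xc @ xc)
        assert slope == pytest.approx(0.02, abs=0.005)

    def test_defaults_give_roughly_standardized_response(self, paper_trials):
        assert abs(paper_trials["hiss_std"].mean()) < 0.25
        assert 0.75 < paper_trials["hiss_std"].var(ddof=1) < 1.4

    def test_time_columns_reconstruct_raw_time(self, paper_trials):
        raw = paper_trials["time_mean"] + paper_trials["time_dev"]
        per_female = raw.groupby(paper_trials["female_id"]).mean()
        recon = paper_trials["female_id"].map(per_female)
        assert np.allclose(recon, paper_trials["time_mean"])

    def test_mismatched_intercept_dev_rejected(self):
        design = build_design(5, {5: 5})
        with pytest.raises(ParameterError):
            simulate_brn(
                design, ReactionNormParams(), seed=1, intercept_dev=np.zeros(3)
            )


class TestCountsFromLatent:
    @pytest.mark.parametrize(
        "latent, expected", [(0.0, 13), (-5.0, 0), (5.0, 43)]
    )
    def test_calibration_examples(self, latent, expected):
        assert counts_from_latent(latent) == expected

    def test_bad_scale_rejected(self):
        with pytest.raises(ParameterError):
            CountCalibration(scale=0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50))
    def test_counts_always_within_bounds(self, latent):
        c = counts_from_latent(latent)
        assert 0 <= c <= 43


class TestSimulateReproduction:
    def test_independence_gives_null_correlations(self):
        ids = [f"F{i}" for i in range(50_000)]
        df = simulate_reproduction(CausalScenario(success_prob=1.0), ids, seed=4)
        sub = df[["nest_defence", "lay_date", "clutch_size", "n_fledged",
                  "mean_fledgling_mass"]]
        corr = sub.corr().to_numpy()
        off = corr[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.03

    def test_chain_correlation_follows_path_tracing(self):
        scen = CausalScenario(
            edges={
                ("lay_date", "clutch_size"): -0.8,
                ("clutch_size", "fledgling_number"): 0.7,
            },
            success_prob=1.0,
        )
        implied = scen.implied_correlation()
        assert implied.loc["lay_date", "fledgling_number"] == pytest.approx(-0.56)
        df = simulate_reproduction(scen, [f"F{i}" for i in range(100_000)], seed=5)
        r = np.corrcoef(df["lay_date"], df["n_fledged"])[0, 1]
        assert r == pytest.approx(-0.56, abs=0.02)

    def test_success_count_can_be_fixed(self):
        df = simulate_reproduction(
            CausalScenario(n_success=77), [f"F{i}" for i in range(104)], seed=6
        )
        assert df["nest_success"].sum() == 77
        failed = df[df["nest_success"] == 0]
        assert failed["n_fledged"].isna().all()
        assert failed["mean_fledgling_mass"].isna().all()

    def test_bernoulli_success_expectation(self):
        df = simulate_reproduction(
            CausalScenario(success_prob=0.74), [f"F{i}" for i in range(5000)], seed=7
        )
        assert df["nest_success"].mean() == pytest.approx(0.74, abs=0.03)

    def test_cyclic_dag_rejected(self):
        with pytest.raises(ParameterError):
            CausalScenario(
                edges={
                    ("lay_date", "clutch_size"): 0.5,
                    ("clutch_size", "lay_date"): 0.5,
                }
            )

    def test_overloaded_weights_rejected(self):
        scen = CausalScenario(
            edges={
                ("lay_date", "clutch_size"): 0.9,
                ("nest_defence", "clutch_size"): 0.9,
            }
        )
        with pytest.raises(ParameterError):
            scen.implied_correlation()

    def test_model3_implied_matrix_is_positive_definite(self):
        sigma = SCENARIOS["model3_strong"].implied_correlation().to_numpy()
        assert np.all(np.linalg.eigvalsh(sigma) > 0)
        assert np.allclose(np.diag(sigma), 1.0)


class TestCoupling:
    def test_noiseless_coupling_recovers_latent_intercepts(self):
        design = build_design(300, {5: 300})
        params = ReactionNormParams(
            beta_julian=0, beta_time_mean=0, beta_time_dev=0,
            beta_age_adult=0, beta_age_unknown=0,
            var_resid=1e-6, var_slope=0, cov_int_slope=0,
        )
        repro = simulate_reproduction(
            CausalScenario(success_prob=1.0), design.females, seed=8
        )
        trials = simulate_brn(
            design, params, seed=9, intercept_dev=couple_intercepts(repro, params)
        )
        means = trials.groupby("female_id", sort=False)["hiss_std"].mean()
        means = means.loc[repro["female_id"]]
        r = np.corrcoef(means.to_numpy(), repro["nest_defence"].to_numpy())[0, 1]
        assert r > 0.99
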