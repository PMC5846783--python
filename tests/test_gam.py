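import numpy as np
import pandas as pd
import pytest

from rarethin import synthetic as syn
from rarethin.gam import CountGAM, CountGAMResults, ModelSpec, gcv_score
from rarethin.grids import PredictionGrid, average_predictions, uncertainty_cv

FAMILIES = ["negbin", "tweedie", "zip"]


def _intercept_model(y, family):
    return CountGAM(np.asarray(y, float), pd.DataFrame(index=range(len(y))),
                    ModelSpec(family=family, variables=()))


class TestFitting:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_intercept_only_fits_sample_mean(self, family):
        """With unit effort the fitted density solves the mean score
        equation: exp-intercept (or pi*lambda for ZIP) equals y-bar."""
        res = _intercept_model([0, 2, 4], family).fit()
        assert res.fittedvalues[0] == pytest.approx(2.0, rel=1e-5)

    def test_all_zero_response_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            _intercept_model([0, 0, 0], "negbin")

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        cov = pd.DataFrame({"a": x, "b": 2.0 * x + 3.0})
        y = rng.poisson(2.0, size=60).astype(float)
        with pytest.raises(ValueError, match="rank-deficient"):
            CountGAM(y, cov, ModelSpec(family="negbin", variables=("a", "b")))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_offset_contract_halves_density(self, family):
        """Doubling every searched area at fixed counts halves the fitted
        per-km2 densities on the training segments."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=300)
        y = rng.poisson(np.exp(0.5 + 0.6 * x)).astype(float)
        cov = pd.DataFrame({"x": x})
        off1 = np.zeros(300)
        off2 = np.full(300, np.log(2.0))
        spec = ModelSpec(family=family, variables=("x",))
        r1 = CountGAM(y, cov, spec, log_offset=off1).fit()
        r2 = CountGAM(y, cov, spec, log_offset=off2).fit()
        d1 = r1.fittedvalues / np.exp(off1)
        d2 = r2.fittedvalues / np.exp(off2)
        assert np.allclose(d2, d1 / 2.0, rtol=1e-2)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_loglik_beats_null(self, family):
        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        y = rng.poisson(np.exp(0.3 + 0.8 * np.sin(x))).astype(float)
        cov = pd.DataFrame({"x": x})
        full = CountGAM(y, cov, ModelSpec(family=family, variables=("x",))).fit()
        null = CountGAM(y, cov, ModelSpec(family=family, variables=())).fit()
        assert full.loglike >= null.loglike - 1e-6

    def test_negbin_matches_statsmodels(self):
        """NB2 coefficients and size agree with the statsmodels ML fit on
        the same fixed design (independent implementation)."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.discrete_model import NegativeBinomial

        rng = np.random.default_rng(5)
        x = rng.uniform(-2, 2, 1500)
        mu = np.exp(0.4 + 0.7 * np.sin(x))
        y = rng.poisson(rng.gamma(2.0, mu / 2.0)).astype(float)
        cov = pd.DataFrame({"x": x})
        mine = CountGAM(y, cov, ModelSpec(family="negbin", variables=("x",))).fit()
        ref = NegativeBinomial(y, mine.model.X).fit(disp=0)
        assert np.allclose(mine.params, ref.params[:-1], atol=2e-3)
        assert mine.family_params["theta"] == pytest.approx(
            1.0 / ref.params[-1], rel=1e-3
        )

    def test_single_smooth_curve_recovery(self):
        """A smooth dome the 3-df basis can represent is recovered almost
        exactly from NB counts (n = 1,000)."""
        rng = np.random.default_rng(6)
        n = 1000
        x = rng.uniform(-2, 2, n)
        f = 1.2 * np.sin((x + 2.0) * np.pi / 4.0)  # half-sine dome
        y = rng.poisson(rng.gamma(3.0, np.exp(0.2 + f) / 3.0)).astype(float)
        res = CountGAM(y, pd.DataFrame({"x": x}),
                       ModelSpec(family="negbin", variables=("x",))).fit()
        grid = np.linspace(-1.9, 1.9, 60)
        fitted = res.model.terms[0].design(grid) @ res.params[1:4]
        true = 1.2 * np.sin((grid + 2.0) * np.pi / 4.0)
        assert np.corrcoef(fitted, true)[0, 1] >= 0.95

    @pytest.mark.parametrize("family", ["negbin", "tweedie"])
    def test_predict_density_consistent_with_fittedvalues(self, family, small_scenario):
        s = small_scenario
        res = CountGAM.from_survey(
            s.dataset, s.taxon_name, family, ("depth", "sst_mean")
        ).fit()
        area = s.dataset.effort_area_km2().to_numpy()
        dens = res.predict_density(
            {v: s.dataset.segments[v].to_numpy() for v in ("depth", "sst_mean")}
        )
        assert np.allclose(dens * area, res.fittedvalues, rtol=1e-10)


class TestGCV:
    def test_closed_formula(self):
        assert gcv_score(10.0, 100, 5) == pytest.approx(1000.0 / 9025.0)

    def test_monotone_in_deviance(self):
        assert gcv_score(11.0, 100, 5) > gcv_score(10.0, 100, 5)

    def test_edf_at_n_rejected(self):
        with pytest.raises(ValueError):
            gcv_score(10.0, 50, 50)


def _toy_grid(vals_by_day, covname="x"):
    days = np.arange(len(vals_by_day))
    n = len(vals_by_day[0])
    return PredictionGrid(
        cell_ids=np.array([f"c{i}" for i in range(n)]),
        lon=np.arange(n, dtype=float),
        lat=np.zeros(n),
        days=days,
        covariates={covname: np.asarray(vals_by_day, dtype=float)},
    )


class TestPrediction:
    @pytest.fixture(scope="class")
    def fit_1d(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.0, 10.0, 500)
        y = rng.poisson(np.exp(0.1 + 0.15 * x)).astype(float)
        return CountGAM(y, pd.DataFrame({"x": x}),
                        ModelSpec(family="negbin", variables=("x",))).fit()

    def test_extrapolation_masked(self, fit_1d):
        grid = _toy_grid([[5.0, 9.0, 25.0]])  # 25 above the training max
        daily = fit_1d.predict_daily(grid)
        assert daily.valid[0, 0] and daily.valid[0, 1]
        assert not daily.valid[0, 2]

    def test_zero_cov_gives_zero_variance(self, fit_1d):
        fit_1d.__dict__["cov_params"] = np.zeros(
            (fit_1d.edf, fit_1d.edf)
        )  # inject degenerate covariance
        daily = fit_1d.predict_daily(_toy_grid([[2.0, 5.0]]))
        assert np.all(daily.variance == 0.0)
        del fit_1d.__dict__["cov_params"]

    def test_missing_grid_covariate_rejected(self, fit_1d):
        grid = _toy_grid([[1.0, 2.0]], covname="other")
        with pytest.raises(ValueError, match="missing"):
            fit_1d.predict_daily(grid)

    def test_intercept_only_constant_map(self):
        res = _intercept_model([1, 2, 3], "negbin").fit()
        daily = res.predict_daily(_toy_grid([[0.0, 1.0, 2.0]]))
        assert np.allclose(daily.density, daily.density[0, 0])
        assert daily.density[0, 0] > 0


class TestAveragingAndCV:
    def test_average_is_cellwise_mean(self):
        from rarethin.grids import DailyPredictions

        grid = _toy_grid([[1.0, 1.0], [1.0, 1.0]])
        daily = DailyPredictions(
            grid=grid,
            density=np.array([[1.0, 4.0], [3.0, 4.0]]),
            valid=np.ones((2, 2), bool),
            variance=np.zeros((2, 2)),
        )
        avg = average_predictions(daily)
        assert np.allclose(avg.values, [2.0, 4.0])

    def test_cell_masked_any_day_is_masked_in_average(self):
        from rarethin.grids import DailyPredictions

        valid = np.ones((5, 2), bool)
        valid[3, 1] = False
        daily = DailyPredictions(
            grid=_toy_grid([[0, 0]] * 5),
            density=np.ones((5, 2)),
            valid=valid,
            variance=np.zeros((5, 2)),
        )
        avg = average_predictions(daily)
        assert avg.valid[0] and not avg.valid[1]

    def test_cv_conventions(self):
        from rarethin.grids import DailyPredictions

        # daily means 2 and 6: population variance 4, period mean 4
        daily = DailyPredictions(
            grid=_toy_grid([[0], [0]]),
            density=np.array([[2.0], [6.0]]),
            valid=np.ones((2, 1), bool),
            variance=np.zeros((2, 1)),
        )
        assert uncertainty_cv(daily).values[0] == pytest.approx(50.0)
        assert uncertainty_cv(daily, sqrt_convention=False).values[0] == pytest.approx(100.0)

    def test_cv_zero_when_constant(self):
        from rarethin.grids import DailyPredictions

        daily = DailyPredictions(
            grid=_toy_grid([[0], [0], [0]]),
            density=np.full((3, 1), 2.0),
            valid=np.ones((3, 1), bool),
            variance=np.zeros((3, 1)),
        )
        assert uncertainty_cv(daily).values[0] == pytest.approx(0.0)

    def test_cv_combines_within_day_variance(self):
        from rarethin.grids import DailyPredictions

        # constant mean 2, mean daily variance 1 -> CV = 100*sqrt(1)/2
        daily = DailyPredictions(
            grid=_toy_grid([[0], [0]]),
            density=np.full((2, 1), 2.0),
            valid=np.ones((2, 1), bool),
            variance=np.full((2, 1), 1.0),
        )
        assert uncertainty_cv(daily).values[0] == pytest.approx(50.0)


class TestParameterRecovery:
    """Quick matched-family checks; the full 20-seed sweep runs in the
    acceptance suite."""

    @pytest.fixture(scope="class")
    def design(self):
        env = syn.make_environment(resolution=0.25, days=(0, 6, 180, 186), seed=3)
        seg = syn.make_survey_design(env, n_segments=2000)
        tax = syn.build_virtual_taxon("broad")
        # truth restricted to the fitted variables: a correctly specified model
        tax.responses = {
            v: tax.responses[v] for v in ("sst_mean", "ssh_mean")
        }
        return seg, tax

    def test_negbin_theta(self, design):
        seg, tax = design
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(20 + seed)
            y, mu, _ = syn.simulate_counts(seg, tax, "negbin", rng, mean_scale=20.0, theta=2.5)
            res = CountGAM(
                y.astype(float), seg,
                ModelSpec(family="negbin", variables=("sst_mean", "ssh_mean")),
                log_offset=np.log(seg.length_km * 2 * seg.half_width_km).to_numpy(),
            ).fit()
            hits += abs(res.family_params["theta"] - 2.5) / 2.5 <= 0.15
        assert hits >= 2

    def test_tweedie_p_and_phi(self, design):
        seg, tax = design
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(30 + seed)
            y, mu, _ = syn.simulate_counts(
                seg, tax, "tweedie", rng, mean_scale=20.0, power_p=1.5, phi=2.0
            )
            res = CountGAM(
                y, seg,
                ModelSpec(family="tweedie", variables=("sst_mean", "ssh_mean")),
                log_offset=np.log(seg.length_km * 2 * seg.half_width_km).to_numpy(),
            ).fit()
            hits += (
                abs(res.family_params["p"] - 1.5) <= 0.1
                and abs(res.family_params["phi"] - 2.0) / 2.0 <= 0.15
            )
        assert hits >= 2


def test_cov_params_psd(small_scenario):
    s = small_scenario
    for family in FAMILIES:
        res = CountGAM.from_survey(
            s.dataset, s.taxon_name, family, ("depth", "sst_mean")
        ).fit()
        cov = res.cov_params
        assert np.allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10


def test_summary_renders(small_scenario):
    s = small_scenario
    res = CountGAM.from_survey(s.dataset, s.taxon_name, "negbin", ("depth",)).fit()
    text = res.summary()
    assert "negbin" in text and "GCV" in text and "s(depth).1" in text
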