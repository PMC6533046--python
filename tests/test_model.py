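"""Attribution model: response curve, prediction, least-squares fit,
peak boosting and the effectiveness report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import recruitflow as rf
from recruitflow import (
    ActivityRecord,
    FitOptions,
    InputError,
    ModelParams,
    RegistrationSeries,
)


def one_activity(start=0, hours=5.0, boost=1.0, category="x", act_id="a1"):
    return ActivityRecord("city", category, act_id, start, hours, boost)


def unit_params(mu=1.0, sigma=0.8, e=100.0, category="x", act_id="a1"):
    return ModelParams(
        mu=mu, sigma=sigma,
        effectiveness={category: e},
        intensity={(category, act_id): 1.0},
    )


class TestLognormalResponse:
    def test_zero_for_nonpositive_elapsed_time(self):
        assert rf.lognormal_response(0.0, 1.0, 0.8) == 0.0
        assert rf.lognormal_response(-3.0, 1.0, 0.8) == 0.0

    def test_mode_matches_closed_form_by_grid_search(self):
        # brute-force grid oracle for the argmax
        grid = np.arange(0.001, 100, 0.001)
        vals = rf.lognormal_response(grid, 1.0, 0.8)
        assert grid[np.argmax(vals)] == pytest.approx(np.exp(1 - 0.8**2), abs=2e-3)

    def test_is_a_normalised_density(self):
        total, _ = integrate.quad(
            lambda d: rf.lognormal_response(d, 1.0, 0.8), 0, 1000, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_invalid_sigma_raises(self):
        with pytest.raises(InputError):
            rf.lognormal_response(1.0, 1.0, 0.0)


class TestPredictDaily:
    def test_no_activities_means_no_signal(self):
        series = rf.predict_daily([], unit_params(), range(10))
        assert np.all(series.counts == 0)

    def test_total_attributed_mass_equals_effectiveness(self):
        # density normalisation: one activity with e*i*boost = 100
        series = rf.predict_daily([one_activity()], unit_params(), range(0, 1500))
        assert series.total == pytest.approx(100.0, abs=0.1)

    def test_additive_in_activities(self):
        acts = [one_activity(act_id="a1"), one_activity(act_id="a2")]
        params = ModelParams(
            mu=1.0, sigma=0.8, effectiveness={"x": 100.0},
            intensity={("x", "a1"): 1.0, ("x", "a2"): 1.0},
        )
        single = rf.predict_daily([acts[0]], params, range(200))
        double = rf.predict_daily(acts, params, range(200))
        np.testing.assert_allclose(double.counts, 2 * single.counts)

    def test_unknown_category_is_a_consistency_error(self):
        with pytest.raises(rf.ConsistencyError):
            rf.predict_daily([one_activity(category="y")], unit_params(), range(10))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        mu=st.floats(-0.5, 2.5),
        sigma=st.floats(0.2, 1.5),
        e=st.floats(1.0, 500.0),
        boost=st.floats(0.5, 5.0),
    )
    def test_mass_conservation_for_any_parameters(self, mu, sigma, e, boost):
        """Infinite-horizon predicted total equals e_c * i_ca * boost."""
        act = one_activity(boost=boost)
        series = rf.predict_daily([act], unit_params(mu=mu, sigma=sigma, e=e),
                                  range(0, 20000))
        assert series.total == pytest.approx(e * boost, rel=1e-4)


class TestFitModel:
    def make_truth_and_data(self, seed=11, noise=None):
        cfg = rf.ScenarioConfig(seed=seed)
        acts = rf.generate_activity_log(cfg)
        truth = rf.true_params(acts, cfg)
        if noise is None:
            obs = rf.predict_daily(acts, truth, range(cfg.study_days))
        else:
            obs = rf.generate_registrations(acts, truth, cfg)[0]
        return cfg, acts, truth, obs

    def test_noiseless_data_recovers_the_generating_truth(self):
        cfg, acts, truth, obs = self.make_truth_and_data()
        fit = rf.fit_model(acts, obs, FitOptions(seed=1))
        assert fit.converged
        assert fit.params.mu == pytest.approx(truth.mu, abs=1e-3)
        assert fit.params.sigma == pytest.approx(truth.sigma, abs=1e-3)
        for cat, e_true in truth.effectiveness.items():
            assert fit.params.effectiveness[cat] == pytest.approx(e_true, rel=1e-3)
        assert fit.pseudo_r2 >= 0.999

    def test_refit_of_own_prediction_is_a_fixed_point(self):
        cfg, acts, truth, obs = self.make_truth_and_data()
        fit = rf.fit_model(acts, obs, FitOptions(seed=1))
        refit = rf.fit_model(acts, fit.predicted, FitOptions(seed=1))
        assert refit.params.mu == pytest.approx(fit.params.mu, abs=1e-6)
        assert refit.params.sigma == pytest.approx(fit.params.sigma, abs=1e-6)

    def test_constant_series_cannot_beat_the_mean(self):
        obs = RegistrationSeries.from_counts(np.full(300, 5.0), city="city")
        fit = rf.fit_model([one_activity()], obs, FitOptions(seed=1))
        assert fit.pseudo_r2 <= 1e-6

    def test_invariants_of_the_fit_result(self):
        cfg, acts, truth, obs = self.make_truth_and_data(noise="poisson")
        fit = rf.fit_model(acts, obs, FitOptions(seed=1))
        C = len(truth.effectiveness)
        assert fit.df == len(obs) - (2 + C)
        assert all(v >= 0 for v in fit.per_category_predicted.values())
        # per-category totals sum to the unbounded-horizon predicted mass
        horizon = rf.predict_daily(acts, fit.params, range(0, 20000))
        assert sum(fit.per_category_predicted.values()) == pytest.approx(
            horizon.total, rel=1e-4
        )

    def test_df_must_be_positive(self):
        obs = RegistrationSeries.from_counts([1.0, 2.0, 1.0])
        with pytest.raises(InputError):
            rf.fit_model([one_activity()], obs)


@pytest.fixture(scope="module")
def planted():
    cfg = rf.ScenarioConfig(
        seed=7,
        hours_distribution=rf.HoursDistribution(kind="degenerate", a=2.0),
    )
    target = rf.pick_isolated_activity(rf.generate_activity_log(cfg), "facebook")
    cfg = cfg.model_copy(update={"planted_boosts": {target: 5.0}})
    ds = rf.generate_dataset(cfg)
    plain = [a.with_boost(1.0) for a in ds.activities]
    fit = rf.fit_model(plain, ds.registrations[0], FitOptions(seed=1))
    return plain, ds.registrations[0], fit, target


class TestPeakBoost:
    def test_planted_peak_is_uniquely_recovered(self, planted):
        plain, obs, fit, target = planted
        boosted = rf.apply_peak_boost(plain, obs, fit, threshold=4.0)
        changed = [b for a, b in zip(plain, boosted) if b.boost != a.boost]
        assert [b.activity_id for b in changed] == [target]
        assert changed[0].boost > 1.0

    def test_idempotent_at_the_same_threshold(self, planted):
        plain, obs, fit, _ = planted
        once = rf.apply_peak_boost(plain, obs, fit, threshold=4.0)
        twice = rf.apply_peak_boost(once, obs, fit, threshold=4.0)
        assert [a.boost for a in once] == [a.boost for a in twice]

    def test_infinite_threshold_changes_nothing(self, planted):
        plain, obs, fit, _ = planted
        out = rf.apply_peak_boost(plain, obs, fit, threshold=np.inf)
        assert [a.boost for a in out] == [a.boost for a in plain]

    def test_quiet_residuals_change_nothing(self):
        cfg = rf.ScenarioConfig(seed=3, study_days=300, activities_per_category=4)
        acts = rf.generate_activity_log(cfg)
        truth = rf.true_params(acts, cfg)
        obs = rf.predict_daily(acts, truth, range(cfg.study_days))
        fit = rf.fit_model(acts, obs, FitOptions(seed=1))
        out = rf.apply_peak_boost(acts, obs, fit, threshold=4.0)
        assert [a.boost for a in out] == [a.boost for a in acts]


class TestCategoryEffectiveness:
    def test_mean_one_intensities_make_totals_additive(self):
        # two activities with hours 1 and 3 -> intensities 0.5 and 1.5
        acts = [
            one_activity(hours=1.0, act_id="a1"),
            one_activity(hours=3.0, act_id="a2", start=50),
        ]
        truth = ModelParams(
            mu=1.0, sigma=0.8, effectiveness={"x": 100.0},
            intensity=rf.intensities_from_hours(acts),
        )
        obs = rf.predict_daily(acts, truth, range(1500))
        fit = rf.fit_model(acts, obs, FitOptions(seed=1))
        table = rf.category_effectiveness(fit)
        assert table.loc[0, "predicted_participants"] == pytest.approx(200.0, rel=1e-3)

    def test_report_carries_inference_and_flags_zero_categories(self):
        cfg = rf.ScenarioConfig(
            seed=5, study_days=250, activities_per_category=3,
            categories={"live": 50.0, "dead": 0.0},
        )
        acts = rf.generate_activity_log(cfg)
        truth = rf.true_params(acts, cfg)
        obs = rf.generate_registrations(acts, truth, cfg)[0]
        fit = rf.fit_model(acts, obs, FitOptions(seed=1))
        table = rf.category_effectiveness(fit).set_index("category")
        assert table.loc["dead", "predicted_participants"] == pytest.approx(0.0, abs=0.5)
        assert bool(table.loc["live", "effective"])
        assert table.loc["live", "t"] == pytest.approx(
            fit.params.effectiveness["live"] / fit.stderr["live"]
        )


class TestParameterRecoveryStatistics:
    def test_effectiveness_is_unbiased_with_calibrated_intervals(self):
        """Over Poisson-noise replicates, mean relative error of each e_c is
        small and +/- 2 SE intervals cover the truth most of the time."""
        n_rep = 20
        cfg0 = rf.ScenarioConfig(seed=0)
        cats = list(cfg0.categories)
        rel_err = {c: [] for c in cats}
        covered = {c: 0 for c in cats}
        for rep in range(n_rep):
            cfg = rf.ScenarioConfig(seed=1000 + rep)
            acts = rf.generate_activity_log(cfg)
            truth = rf.true_params(acts, cfg)
            obs = rf.generate_registrations(acts, truth, cfg)[0]
            fit = rf.fit_model(acts, obs, FitOptions(seed=rep))
            for c in cats:
                e_hat, e_true = fit.params.effectiveness[c], truth.effectiveness[c]
                rel_err[c].append((e_hat - e_true) / e_true)
                if abs(e_hat - e_true) <= 2 * fit.stderr[c]:
                    covered[c] += 1
        for c in cats:
            assert abs(np.mean(rel_err[c])) < 0.05, f"bias in {c}"
            assert covered[c] / n_rep >= 0.80, f"undercoverage for {c}"
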