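"""Sliding windows, temperature measures and candidate-model machinery."""

import numpy as np
import pandas as pd
import pytest

import broodsync as bs
from broodsync import cues, glmm, synthetic

from conftest import behaviours_from_truth


class TestWindowDates:
    def test_laying_period_window(self):
        assert cues.window_dates(100, 110, None, 1) == (100, 110)

    def test_window_eight_starts_seven_days_before_laying(self):
        assert cues.window_dates(100, 110, None, 8) == (93, 110)

    def test_window_twelve_spans_incubation(self):
        assert cues.window_dates(100, 110, 122, 12) == (110, 122)

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cues.window_dates(100, 98, None, 1)

    def test_nesting_monotonicity(self):
        spans = [cues.window_dates(100, 110, None, w) for w in range(1, 12)]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 <= s1 and e2 == e1


def _stats_from(rows):
    df = pd.DataFrame(rows, columns=["logger_id", "day", "minute", "temp"])
    df["x"] = 0.0
    df["y"] = 0.0
    return cues.daily_ambient_stats(df)


class TestWindowTemperature:
    def test_constant_series(self):
        rows = [("L", d, m, 10.0) for d in (100, 101) for m in (0, 360, 720)]
        stats = _stats_from(rows)
        for measure, expected in [("mean", 10.0), ("mmin", 10.0),
                                  ("mmax", 10.0), ("trange", 0.0)]:
            assert cues.window_temperature(stats, "L", 100, 101, measure) \
                == expected

    def test_two_day_hand_arithmetic(self):
        # day 1 readings {4, 14}, day 2 readings {6, 10}
        rows = [("L", 100, 0, 4.0), ("L", 100, 720, 14.0),
                ("L", 101, 0, 6.0), ("L", 101, 720, 10.0)]
        stats = _stats_from(rows)
        assert cues.window_temperature(stats, "L", 100, 101, "mmin") == 5.0
        assert cues.window_temperature(stats, "L", 100, 101, "mmax") == 12.0
        assert cues.window_temperature(stats, "L", 100, 101, "trange") == 7.0
        assert cues.window_temperature(stats, "L", 100, 101, "mean") \
            == pytest.approx(np.mean([4, 14, 6, 10]))

    def test_single_day_equals_daily_stats(self):
        rows = [("L", 100, 0, 4.0), ("L", 100, 720, 14.0)]
        stats = _stats_from(rows)
        assert cues.window_temperature(stats, "L", 100, 100, "mean") == 9.0
        assert cues.window_temperature(stats, "L", 100, 100, "trange") == 10.0

    def test_missing_day_named_in_error(self):
        rows = [("L", 100, 0, 4.0)]
        stats = _stats_from(rows)
        with pytest.raises(ValueError, match="101"):
            cues.window_temperature(stats, "L", 100, 101, "mean")


@pytest.fixture(scope="module")
def small_candidates():
    cfg = bs.GeneratorConfig(n_nests=40, n_loggers=6, seed=31,
                             season_start=95, season_end=168)
    grid = synthetic.generate_ambient_grid(cfg)
    records, truth = synthetic.generate_nests(cfg, grid)
    behav = behaviours_from_truth(records, truth)
    stats = cues.daily_ambient_stats(grid.df)
    tvars = cues.temperature_variables(behav, stats)
    return behav, tvars


class TestCandidateSets:
    def test_onset_candidate_count(self, small_candidates):
        behav, tvars = small_candidates
        ranked = cues.fit_onset_candidates(behav, tvars)
        # 44 variables x 4 configurations + 2 nulls
        assert len(ranked) == 178
        assert (ranked["config"].str.startswith("null")).sum() == 2

    def test_duration_candidate_count(self, small_candidates):
        behav, tvars = small_candidates
        ranked = cues.fit_duration_candidates(behav, tvars)
        # 176 + 4 window-12 temperature models + 2 nulls
        assert len(ranked) == 182
        assert (~ranked["config"].str.startswith("null")).sum() == 180
        # relative onset enters every candidate, nulls included
        assert all("relative_onset" in c for c in ranked["coefficients"])

    def test_delta_aic_invariants(self, small_candidates):
        behav, tvars = small_candidates
        ranked = cues.fit_onset_candidates(behav, tvars)
        assert ranked["delta_aic"].iloc[0] == 0.0
        assert (ranked["delta_aic"] >= 0).all()
        assert ranked["delta_aic"].is_monotonic_increasing
        assert ranked["equivalent"].iloc[0]

    def test_ranking_invariant_to_input_order(self, small_candidates):
        behav, tvars = small_candidates
        shuffled = tvars.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = cues.fit_onset_candidates(behav, tvars)
        b = cues.fit_onset_candidates(behav, shuffled)
        pd.testing.assert_frame_equal(
            a[["config", "window", "measure", "aic"]],
            b[["config", "window", "measure", "aic"]],
        )

    def test_interaction_centring_leaves_aic_unchanged(self, small_candidates):
        """The Txinit AIC equals a statsmodels fit of the uncentred model."""
        import statsmodels.formula.api as smf
        behav, tvars = small_candidates
        ranked = cues.fit_onset_candidates(behav, tvars)
        row = ranked[(ranked["window"] == 8) & (ranked["measure"] == "mean")
                     & (ranked["config"] == "Txinit")].iloc[0]
        wide = tvars.pivot_table(index="nest_id",
                                 columns=["window", "measure"],
                                 values="value")
        df = behav.set_index("nest_id").copy()
        df["T"] = wide[(8, "mean")]
        ref = smf.ols("relative_onset ~ T * initiation_date", data=df).fit()
        # our AIC counts the error variance as a parameter (R's convention);
        # statsmodels does not, a constant +2 on every model
        assert row["aic"] == pytest.approx(ref.aic + 2.0, abs=1e-6)
        assert row["llf"] == pytest.approx(ref.llf, abs=1e-6)


class TestIntensityCandidates:
    def test_candidate_count_and_ranking(self):
        cfg = bs.GeneratorConfig(n_nests=20, n_loggers=4, seed=37,
                                 season_start=95, season_end=168)
        daily = synthetic.generate_intensity_counts(cfg)
        ranked, fits = cues.fit_intensity_candidates(daily, n_quad=9)
        assert len(ranked) == 17
        assert ranked["delta_aic"].iloc[0] == 0.0
        assert len(fits) == 17

    def test_degenerate_random_effect_matches_plain_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(41)
        n = 300
        daily = pd.DataFrame({
            "nest_id": [f"n{i % 30}" for i in range(n)],
            "incubation_day": rng.integers(1, 12, n).astype(float),
            "dmax": rng.normal(15, 2, n),
            "n_active": 36,
        })
        # no group effect at all
        from scipy.special import expit
        p = expit(-1.0 + 0.2 * daily["incubation_day"] + 0.05 * daily["dmax"])
        daily["n_incubating"] = rng.binomial(36, p)
        X = cues._intensity_design(daily, "day+T", "mmax")
        res = glmm.fit_binomial_glmm(daily["n_incubating"], daily["n_active"],
                                     X, daily["nest_id"])
        ref = sm.GLM(
            np.column_stack([daily["n_incubating"],
                             daily["n_active"] - daily["n_incubating"]]),
            X, family=sm.families.Binomial()).fit()
        for name in X.columns:
            assert res.params[name] == pytest.approx(ref.params[name], abs=1e-3)

    def test_marginal_effects_at_means(self):
        cfg = bs.GeneratorConfig(n_nests=60, seed=43)
        daily = synthetic.generate_intensity_counts(cfg)
        X = cues._intensity_design(daily, "dayxT", "mmax")
        res = glmm.fit_binomial_glmm(daily["n_incubating"], daily["n_active"],
                                     X, daily["nest_id"])
        me = cues.intensity_marginal_effects(res, daily, "mmax")
        assert 0.3 <= me["p_at_means"] <= 0.95
        # hand-recomputed from the fitted coefficients
        day_bar = daily["incubation_day"].mean()
        t_bar = daily["dmax"].mean()
        eta = (res.params["const"] + res.params["incubation_day"] * day_bar
               + res.params["temperature"] * t_bar
               + res.params["day:temperature"] * day_bar * t_bar)
        p = 1 / (1 + np.exp(-eta))
        expected = p * (1 - p) * (res.params["incubation_day"]
                                  + res.params["day:temperature"] * t_bar)
        assert me["marginal_per_day"] == pytest.approx(expected)
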