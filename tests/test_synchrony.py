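"""Synchrony indices, null expectations, variance tests, fitness surface."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import broodsync as bs
from broodsync import synchrony, synthetic


def _one_nest(hatch=150, completion=140, rel=4, duration=6, cat=160,
              year=2014):
    records = pd.DataFrame({
        "nest_id": ["n1"], "year": [year], "initiation_date": [completion - 7],
        "clutch_size": [8], "completion_date": [completion],
        "hatch_date": [hatch], "fledglings": [6], "section": [1],
    })
    behav = pd.DataFrame({
        "nest_id": ["n1"], "relative_onset": [rel], "duration": [duration],
    })
    cater = pd.DataFrame({"year": [year], "peak_date": [cat]})
    return records, behav, cater


class TestBuildSynchrony:
    def test_index_arithmetic(self):
        records, behav, cater = _one_nest(hatch=150, cat=160)
        out = synchrony.build_synchrony(records, cater, behav, offset=13)
        assert out["raw_synchrony"].iloc[0] == -10
        assert out["index"].iloc[0] == 3
        assert out["index_squared"].iloc[0] == 9

    def test_longterm_null(self):
        records, behav, cater = _one_nest(completion=140, cat=160)
        out = synchrony.build_synchrony(records, cater, behav, offset=13)
        # completion + 14 - caterpillar + offset = 140 + 14 - 160 + 13 = 7
        assert out["null_longterm"].iloc[0] == 7

    def test_no_duration_null(self):
        records, behav, cater = _one_nest(completion=140, rel=4, cat=160)
        out = synchrony.build_synchrony(records, cater, behav,
                                        mean_duration_focal=12)
        # completion + rel + 12 - caterpillar = 140 + 4 + 12 - 160 = -4
        assert out["null_no_duration"].iloc[0] == -4

    def test_no_onset_null_conservation(self, dataset, behaviours_table):
        """observed raw synchrony - no-onset null = relative onset, per nest."""
        out = synchrony.build_synchrony(
            dataset.records, dataset.caterpillar, behaviours_table)
        got = out.dropna(subset=["null_no_onset"])
        assert len(got) > 0
        np.testing.assert_allclose(
            got["raw_synchrony"] - got["null_no_onset"], got["relative_onset"])

    def test_missing_year_raises(self):
        records, behav, cater = _one_nest()
        cater["year"] = 1999
        with pytest.raises(ValueError, match="2014"):
            synchrony.build_synchrony(records, cater, behav)

    def test_squaring_preserves_absolute_ranking(self):
        idx = np.array([-7, -2, 0, 3, 9])
        sq = idx ** 2
        assert (np.argsort(np.abs(idx)) == np.argsort(sq)).all()


class TestVarianceAnova:
    @staticmethod
    def _records(rows):
        df = pd.DataFrame(rows, columns=[
            "year", "initiation_date", "clutch_size", "hatch_date"])
        df["completion_date"] = df["initiation_date"] + df["clutch_size"] - 1
        df["nest_id"] = [f"n{i}" for i in range(len(df))]
        df["fledglings"] = 5
        df["section"] = 1
        return df

    def test_identical_event_dates_give_zero_differences(self):
        rows = []
        for year in (2000, 2001):
            for init in (100, 104, 108):
                rows.append((year, init, 1, init))  # clutch 1: all dates equal
        rec = self._records(rows)
        out = synchrony.variance_anova(rec)
        for pair in out["pairwise"].values():
            assert pair["difference"] == pytest.approx(0.0, abs=1e-10)

    def test_two_year_toy_matches_hand_anova(self):
        # initiation variances: 2000 -> var([100,104,108]) = 16
        #                       2001 -> var([110,116,122]) = 36
        # clutch constant 5 -> completion variance identical to initiation
        # hatch dates chosen with variance 4 and 9
        rows = [
            (2000, 100, 5, 120), (2000, 104, 5, 122), (2000, 108, 5, 124),
            (2001, 110, 5, 130), (2001, 116, 5, 133), (2001, 122, 5, 136),
        ]
        rec = self._records(rows)
        out = synchrony.variance_anova(rec)
        per = out["per_year"].pivot(index="year", columns="event",
                                    values="variance")
        assert per.loc[2000, "initiation"] == pytest.approx(16.0)
        assert per.loc[2001, "initiation"] == pytest.approx(36.0)
        assert per.loc[2000, "hatch"] == pytest.approx(4.0)
        assert per.loc[2001, "hatch"] == pytest.approx(9.0)
        # balanced two-way layout: effect = difference of event means
        exp_hc = np.mean([4, 9]) - np.mean([16, 36])
        assert out["pairwise"]["hatch-initiation"]["difference"] \
            == pytest.approx(exp_hc)
        assert out["pairwise"]["completion-initiation"]["difference"] \
            == pytest.approx(0.0, abs=1e-10)

    def test_single_year_rejected(self):
        rows = [(2000, 100, 5, 120), (2000, 104, 5, 122)]
        with pytest.raises(ValueError, match="2 years"):
            synchrony.variance_anova(self._records(rows))

    def test_longterm_variance_ordering(self):
        """Compensatory incubation: var(hatch) < var(completion) < var(init)."""
        cfg = bs.GeneratorConfig(seed=47, years=(1990, 2009),
                                 nests_per_year=120)
        records, _ = synthetic.generate_longterm(cfg)
        out = synchrony.variance_anova(records)
        mv = out["mean_variance"]
        assert mv["hatch"] < mv["completion"] < mv["initiation"]
        for pair in out["pairwise"].values():
            assert pair["p"] < 0.05


class TestPairedImprovement:
    def test_identical_vectors(self):
        out = synchrony.paired_improvement_test([1, 2, 3], [1, 2, 3])
        assert out["mean_difference"] == 0.0
        assert np.isnan(out["t"]) or out["t"] == 0.0

    def test_three_pair_hand_computation(self):
        out = synchrony.paired_improvement_test([4, 1, 0], [9, 4, 1])
        # differences -5, -3, -1: mean -3, sd 2, t = -3 / (2 / sqrt(3))
        assert out["mean_difference"] == pytest.approx(-3.0)
        assert out["t"] == pytest.approx(-3.0 / (2.0 / np.sqrt(3.0)))
        assert out["df"] == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            synchrony.paired_improvement_test([1, 2], [1, 2, 3])

    def test_observed_beats_null_on_longterm_synthetic(self):
        cfg = bs.GeneratorConfig(seed=53, years=(1990, 2009),
                                 nests_per_year=120)
        records, cater = synthetic.generate_longterm(cfg)
        sync = synchrony.build_synchrony(records, cater)
        out = synchrony.paired_improvement_test(
            sync["index_squared"], sync["null_longterm_squared"])
        assert out["mean_difference"] < 0
        assert out["p"] < 0.05


class TestVarianceRatio:
    def test_identical_vectors_ratio_one(self):
        out = synchrony.variance_ratio_test([1, 5, 3, 2], [1, 5, 3, 2])
        assert out["ratio"] == pytest.approx(1.0)

    def test_hand_ratio(self):
        obs = [0, 2, 4]   # variance 4
        nul = [0, 4, 8]   # variance 16
        out = synchrony.variance_ratio_test(obs, nul)
        assert out["ratio"] == pytest.approx(4.0)
        assert out["df"] == (2, 2)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            synchrony.variance_ratio_test([1, 1, 1], [1, 2, 3])


class TestFitness:
    def test_vertex_of_reported_coefficients(self):
        # quadratic vertex: -b1 / (2 b2) for (-0.074, -0.0017)
        assert -(-0.074) / (2 * -0.0017) == pytest.approx(-21.76, abs=0.01)

    def test_recovers_generating_surface(self):
        cfg = bs.GeneratorConfig(seed=59)
        records, cater = synthetic.generate_longterm(cfg)
        sync = synchrony.build_synchrony(records, cater)
        fit = synchrony.fit_fitness_model(sync)
        fp = cfg.fitness_params
        assert fit["params"]["sync"] == pytest.approx(
            fp["synchrony"], abs=2 * fit["bse"]["sync"])
        assert fit["params"]["sync2"] == pytest.approx(
            fp["synchrony2"], abs=2 * fit["bse"]["sync2"])
        assert fit["optimum_synchrony"] is not None
        assert fit["optimum_synchrony"] == pytest.approx(
            -fp["synchrony"] / (2 * fp["synchrony2"]), abs=6.0)

    def test_positive_quadratic_gives_no_optimum(self):
        rng = np.random.default_rng(61)
        n = 400
        raw = rng.integers(-20, 5, n).astype(float)
        isync = raw - 20
        lam = np.exp(1.0 + 0.002 * raw ** 2)  # convex surface
        df = pd.DataFrame({
            "raw_synchrony": raw, "init_synchrony": isync,
            "clutch_size": rng.integers(6, 11, n),
            "fledglings": rng.poisson(lam),
            "section": rng.integers(1, 4, n),
        })
        fit = synchrony.fit_fitness_model(df)
        assert fit["optimum_synchrony"] is None

    def test_non_integer_counts_rejected(self):
        records, behav, cater = _one_nest()
        sync = synchrony.build_synchrony(records, cater, behav)
        sync["fledglings"] = [2.5]
        with pytest.raises(ValueError, match="integer"):
            synchrony.fit_fitness_model(sync)
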