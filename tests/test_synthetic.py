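"""Generator contracts: determinism, shapes, ground-truth invariants."""

import numpy as np
import pandas as pd
import pytest

import broodsync as bs
from broodsync import synthetic

from conftest import run_detection


def test_seeded_determinism(tiny_cfg):
    a = bs.generate_dataset(tiny_cfg)
    b = bs.generate_dataset(tiny_cfg)
    pd.testing.assert_frame_equal(a.grid.df, b.grid.df)
    pd.testing.assert_frame_equal(a.traces, b.traces)
    pd.testing.assert_frame_equal(a.records, b.records)
    pd.testing.assert_frame_equal(a.truth.nests, b.truth.nests)


def test_ambient_reading_count():
    cfg = bs.GeneratorConfig(n_loggers=10, season_start=100, season_end=129,
                             seed=1)
    grid = synthetic.generate_ambient_grid(cfg)
    # 10 loggers x 30 days x 48 readings/day at 30-min spacing
    assert len(grid.df) == 10 * 30 * 48
    counts = grid.df.groupby("logger_id").size()
    assert (counts == 30 * 48).all()


def test_flat_field_daily_range_equals_amplitude():
    cfg = bs.GeneratorConfig(
        n_loggers=4, seed=2, season_start=100, season_end=110,
        noise_sd_ambient=0.0, anomaly_sd=0.0, amplitude_sd=0.0,
        amplitude_logger_sd=0.0, logger_anomaly_sd=0.0,
    )
    grid = synthetic.generate_ambient_grid(cfg)
    rng = grid.df.groupby(["logger_id", "day"])["temp"].agg(lambda s: s.max() - s.min())
    np.testing.assert_allclose(rng, cfg.diurnal_amplitude, atol=1e-9)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="cutoff"):
        bs.GeneratorConfig(incubation_contrast=3.0)
    with pytest.raises(ValueError, match="span"):
        bs.GeneratorConfig(season_start=150, season_end=100)
    with pytest.raises(ValueError, match="empty"):
        bs.GeneratorConfig(onset_range=(5, -5))
    with pytest.raises(ValueError, match="divide"):
        bs.GeneratorConfig(sampling_interval_nest=25)


def test_ground_truth_invariants(dataset):
    t = dataset.truth.nests
    r = dataset.records
    lo, hi = dataset.config.onset_range
    dlo, dhi = dataset.config.duration_range
    assert (t["true_relative_onset"].between(lo, hi)).all()
    assert (t["true_duration"].between(dlo, dhi)).all()
    assert (t["true_onset_date"] >= r["initiation_date"]).all()
    assert (r["completion_date"] == r["initiation_date"] + r["clutch_size"] - 1).all()
    # conservation: completion + relative onset + duration = hatch
    assert (
        r["completion_date"] + t["true_relative_onset"] + t["true_duration"]
        == r["hatch_date"]
    ).all()
    daily = dataset.truth.daily
    assert daily["true_intensity"].between(0, 1).all()
    # the onset day satisfies the 50% rule
    on = daily[daily["incubation_day"] == 1]
    assert (on["true_intensity"] >= 0.5).all()
    # transition days stay below it
    pre = daily[daily["incubation_day"] < 1]
    assert (pre["true_intensity"] < 0.5).all()


def test_degenerate_zero_slope_gives_constant_onset():
    cfg = bs.GeneratorConfig(
        n_nests=15, n_loggers=4, seed=3, season_start=95, season_end=168,
        onset_temp_slope=0.0, onset_initiation_interaction=0.0,
        onset_sd=1e-9, onset_mean=4.0,
    )
    grid = synthetic.generate_ambient_grid(cfg)
    _, truth = synthetic.generate_nests(cfg, grid)
    assert (truth.nests["true_relative_onset"] == 4).all()


def test_empirical_means_near_configured(tiny_cfg):
    cfg = bs.GeneratorConfig(n_nests=300, seed=21)
    grid = synthetic.generate_ambient_grid(cfg)
    records, truth = synthetic.generate_nests(cfg, grid)
    assert truth.nests["true_relative_onset"].mean() == pytest.approx(
        cfg.onset_mean, abs=0.8)
    assert truth.nests["true_duration"].mean() == pytest.approx(
        cfg.duration_baseline, abs=0.8)
    post = truth.daily[truth.daily["incubation_day"] >= 1]
    # the onset-anchored ramp runs somewhat above the latent 70% mean
    assert post["true_intensity"].mean() == pytest.approx(0.72, abs=0.06)


def test_truncation_empty_support_raises():
    cfg = bs.GeneratorConfig(n_nests=10, n_loggers=4, seed=4,
                             season_start=95, season_end=168)
    object.__setattr__(cfg, "onset_range", (5, 5))  # bypass post-init check
    grid = synthetic.generate_ambient_grid(cfg)
    with pytest.raises(ValueError, match="empties the support"):
        synthetic.generate_nests(cfg, grid)


class TestTraces:
    def test_incubated_slots_exceed_daily_ambient_by_contrast(
            self, noisefree_dataset):
        """Incubated readings sit at least the incubation contrast above the
        day's ambient level; the remaining readings stay near ambient."""
        ds = noisefree_dataset
        c = ds.config
        row = ds.truth.daily.loc[ds.truth.daily["true_intensity"].idxmax()]
        li = int(ds.truth.nests.set_index("nest_id").loc[
            row["nest_id"], "logger_index"])
        level = float(ds.grid.daily_level(li, int(row["day"])))
        tr = ds.traces[(ds.traces["nest_id"] == row["nest_id"])
                       & (ds.traces["day"] == row["day"])
                       & (ds.traces["minute"] >= c.active_day[0])
                       & (ds.traces["minute"] < c.active_day[1])]
        assert len(tr) == c.n_active_slots
        tr = tr.sort_values("minute")
        k = int(row["n_hot"])  # hot slots fill from the start of the day
        assert (tr["temp"].iloc[:k] >= level + c.incubation_contrast).all()
        assert (tr["temp"].iloc[k:] < level + 4.0).all()

    def test_hot_slot_count_matches_truth(self, noisefree_dataset):
        """A day with intensity p carries round(p * 36) contiguous hot slots."""
        ds = noisefree_dataset
        c = ds.config
        truth_daily = ds.truth.daily.set_index(["nest_id", "day"])
        nest = ds.truth.nests.iloc[0]
        onset = int(nest["true_onset_date"])
        for day in range(onset, onset + 3):
            row = truth_daily.loc[(nest["nest_id"], day)]
            li = int(nest["logger_index"])
            level = float(ds.grid.daily_level(li, day))
            tr = ds.traces[(ds.traces["nest_id"] == nest["nest_id"])
                           & (ds.traces["day"] == day)
                           & (ds.traces["minute"] >= c.active_day[0])
                           & (ds.traces["minute"] < c.active_day[1])]
            hot = (tr["temp"] > level + 4.0).sum()
            assert hot == row["n_hot"]

    def test_preonset_day_tracks_ambient_within_one_degree(
            self, noisefree_dataset):
        """Before any daytime incubation the nest reads local ambient to
        within 1 degC over the active day."""
        ds = noisefree_dataset
        _, paired, _ = run_detection(ds)
        t = ds.truth.nests.iloc[0]
        ramp_start = int(t["ramp_start"])
        c = ds.config
        pre = paired[(paired["nest_id"] == t["nest_id"])
                     & (paired["day"] < ramp_start)
                     & (paired["minute"] >= c.active_day[0])
                     & (paired["minute"] < c.active_day[1])]
        assert len(pre) > 0
        assert pre["delta"].abs().max() < 1.0


def test_longterm_mode_shapes_and_tracking():
    cfg = bs.GeneratorConfig(seed=5, years=(2000, 2009), nests_per_year=50)
    records, cat = synthetic.generate_longterm(cfg)
    assert len(records) == 10 * 50
    assert set(cat["year"]) == set(range(2000, 2010))
    assert (records["completion_date"]
            == records["initiation_date"] + records["clutch_size"] - 1).all()
    # laying tracks the caterpillar peak across years
    ann = records.groupby("year")["hatch_date"].mean()
    peaks = cat.set_index("year")["peak_date"]
    assert np.corrcoef(ann, peaks.loc[ann.index])[0, 1] > 0.9


def test_intensity_counts_dataset_shape():
    cfg = bs.GeneratorConfig(n_nests=10, n_loggers=4, seed=6,
                             season_start=95, season_end=168)
    daily = synthetic.generate_intensity_counts(cfg)
    assert set(daily.columns) >= {
        "nest_id", "incubation_day", "n_incubating", "n_active",
        "dmean", "dmin", "dmax", "drange"}
    assert (daily["n_incubating"] <= daily["n_active"]).all()
    assert (daily["incubation_day"] >= 1).all()
    assert daily["nest_id"].nunique() == 10
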