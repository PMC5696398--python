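"""Shared fixtures: small synthetic worlds and derived pipeline products."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import broodsync as bs
from broodsync import behaviour, cues, detection, field_io

warnings.filterwarnings("ignore", category=FutureWarning)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cfg() -> bs.GeneratorConfig:
    return bs.GeneratorConfig(
        n_nests=14, n_loggers=6, seed=11, season_start=95, season_end=168
    )


@pytest.fixture(scope="session")
def dataset(tiny_cfg) -> bs.SyntheticDataset:
    return bs.generate_dataset(tiny_cfg)


@pytest.fixture(scope="session")
def noisefree_dataset() -> bs.SyntheticDataset:
    cfg = bs.GeneratorConfig(
        n_nests=20, n_loggers=6, seed=13, season_start=95, season_end=168,
        noise_sd_nest=0.0, noise_sd_ambient=0.0,
    )
    return bs.generate_dataset(cfg)


def run_detection(ds: bs.SyntheticDataset, config=None):
    """Pair, align and detect for a generated dataset."""
    config = config or detection.DetectionConfig()
    loggers = field_io.logger_positions(ds.grid.df)
    nests = ds.traces.groupby("nest_id", as_index=False).first()
    pairing = pd.Series(
        field_io.pair_all_nests(nests, loggers).to_numpy(),
        index=nests["nest_id"],
    )
    paired = field_io.align_all(ds.traces, ds.grid.df, pairing)
    placements = nests.set_index("nest_id")["placement_date"]
    profiles = detection.detect_all(paired, placements, config)
    return pairing, paired, profiles


@pytest.fixture(scope="session")
def detected(dataset):
    pairing, paired, profiles = run_detection(dataset)
    return {"pairing": pairing, "paired": paired, "profiles": profiles}


@pytest.fixture(scope="session")
def behaviours_table(dataset, detected) -> pd.DataFrame:
    table = behaviour.compute_behaviours(detected["profiles"], dataset.records)
    table["logger_id"] = table["nest_id"].map(detected["pairing"])
    return table


@pytest.fixture(scope="session")
def daily_stats(dataset) -> pd.DataFrame:
    return cues.daily_ambient_stats(dataset.grid.df)


def behaviours_from_truth(records, truth) -> pd.DataFrame:
    """Behaviour table built from generator ground truth (no detector)."""
    return pd.DataFrame({
        "nest_id": records["nest_id"],
        "logger_id": truth.nests["logger_id"],
        "initiation_date": records["initiation_date"],
        "clutch_size": records["clutch_size"],
        "completion_date": records["completion_date"],
        "onset_date": truth.nests["true_onset_date"],
        "hatch_date": records["hatch_date"],
        "relative_onset": truth.nests["true_relative_onset"],
        "duration": truth.nests["true_duration"],
    })
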