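"""Daily-calibrated threshold detection of incubation from nest traces.

The detector works on a nest trace paired with same-hour ambient readings
(:func:`broodsync.field_io.align_hourly`).  Each night (c. 19:00-24:00 of
day ``d - 1``) the readings more than ``delta_cutoff`` (default 4 degC)
above ambient are taken as incubating temperatures; their minimum is the
nest's incubation threshold for the following active day ``d`` (07:00 to
19:00).  Active-day readings strictly above that threshold count as
incubating; the day's intensity is the incubating fraction of active-day
readings, and the onset of full daytime incubation is the first day with
intensity at or above ``onset_fraction`` (default 50%).  The nightly
recalibration absorbs day-to-day changes in logger position and burial.

Nests qualify for analysis only if at least one clean non-incubating day
(no nocturnal incubation, intensity below the onset fraction) falls
strictly between logger placement and the detected onset; otherwise the
placement may have missed the start of incubation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DetectionConfig:
    delta_cutoff: float = 4.0
    night_window: tuple[int, int] = (1140, 1440)  # 19:00-24:00, half-open
    active_day: tuple[int, int] = (420, 1140)     # 07:00-19:00, half-open
    onset_fraction: float = 0.5
    min_preonset_days: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.onset_fraction <= 1:
            raise ValueError("onset_fraction must be in (0, 1]")
        a0, a1 = self.active_day
        n0, n1 = self.night_window
        if max(a0, n0) < min(a1, n1):
            raise ValueError("active_day and night_window must be disjoint")


DAILY_COLUMNS = [
    "day", "night_threshold", "night_has_data", "n_active",
    "n_incubating", "intensity", "classified",
]


@dataclass
class IncubationProfile:
    """Detector output for one nest."""

    nest_id: str
    daily: pd.DataFrame = field(repr=False)  # DAILY_COLUMNS
    onset_date: int | None = None
    included: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# Single-day operations (reference semantics; the batch path mirrors them)
# ---------------------------------------------------------------------------

def nightly_threshold(paired: pd.DataFrame, day: int,
                      config: DetectionConfig = DetectionConfig()) -> float | None:
    """Threshold for active day ``day`` from the night of ``day - 1``.

    Among the night readings whose excess over ambient exceeds
    ``delta_cutoff``, returns the minimum in-nest temperature; ``None``
    when no reading qualifies (no nocturnal incubation yet) or the night
    has no data at all.
    """
    n0, n1 = config.night_window
    night = paired[
        (paired["day"] == day - 1)
        & (paired["minute"] >= n0) & (paired["minute"] < n1)
    ]
    night = night.dropna(subset=["delta"])
    if night.empty:
        return None
    hot = night[night["delta"] > config.delta_cutoff]
    if hot.empty:
        return None
    return float(hot["temp"].min())


def classify_day(paired: pd.DataFrame, day: int, threshold: float | None,
                 config: DetectionConfig = DetectionConfig()
                 ) -> tuple[int, int, float]:
    """Count active-day readings strictly above the nightly threshold.

    Returns ``(n_active, n_incubating, intensity)``.  An undefined
    threshold means no nocturnal incubation was recorded, so the day's
    intensity is 0 by convention.
    """
    a0, a1 = config.active_day
    active = paired[
        (paired["day"] == day)
        & (paired["minute"] >= a0) & (paired["minute"] < a1)
    ]
    active = active.dropna(subset=["temp"])
    n_active = len(active)
    if n_active == 0:
        raise ValueError(f"day {day}: no active-day readings")
    if threshold is None:
        return n_active, 0, 0.0
    n_inc = int((active["temp"] > threshold).sum())
    return n_active, n_inc, n_inc / n_active


def detect_onset(daily: pd.DataFrame,
                 config: DetectionConfig = DetectionConfig()) -> int | None:
    """First calendar day whose intensity reaches the onset fraction."""
    ok = daily[daily["classified"] & (daily["intensity"] >= config.onset_fraction)]
    if ok.empty:
        return None
    return int(ok["day"].iloc[ok["day"].to_numpy().argmin()])


def validate_nest(daily: pd.DataFrame, onset_date: int | None,
                  placement_date: int,
                  config: DetectionConfig = DetectionConfig()
                  ) -> tuple[bool, str]:
    """Exclusion rule: require clean non-incubating day(s) before onset.

    A clean day lies strictly after placement and before the onset, was
    classified, shows no nocturnal incubation (undefined threshold despite
    night data) and intensity below the onset fraction.
    """
    if onset_date is None:
        return False, "no onset detected"
    pre = daily[
        (daily["day"] > placement_date) & (daily["day"] < onset_date)
        & daily["classified"]
        & daily["night_has_data"]
        & daily["night_threshold"].isna()
        & (daily["intensity"] < config.onset_fraction)
    ]
    if onset_date <= placement_date:
        return False, "no pre-onset day"
    if len(pre) < config.min_preonset_days:
        return False, "no pre-onset day"
    return True, "ok"


# ---------------------------------------------------------------------------
# Batch path
# ---------------------------------------------------------------------------

def daily_table(paired: pd.DataFrame,
                config: DetectionConfig = DetectionConfig()) -> pd.DataFrame:
    """Vectorised per-nest-day classification for many nests at once.

    ``paired`` needs columns nest_id, day, minute, temp, delta.  Returns
    one row per nest-day with DAILY_COLUMNS plus nest_id.  Days without a
    usable preceding night (no data) are flagged unclassified.
    """
    n0, n1 = config.night_window
    a0, a1 = config.active_day
    df = paired.dropna(subset=["temp", "delta"])

    night = df[(df["minute"] >= n0) & (df["minute"] < n1)]
    night_any = night.groupby(["nest_id", "day"]).size().rename("n_night")
    hot = night[night["delta"] > config.delta_cutoff]
    thr = hot.groupby(["nest_id", "day"])["temp"].min().rename("thr")

    active = df[(df["minute"] >= a0) & (df["minute"] < a1)].copy()
    grp = active.groupby(["nest_id", "day"])
    out = grp.size().rename("n_active").reset_index()
    # night of day d-1 calibrates day d
    prev = out[["nest_id", "day"]].copy()
    prev["prev_day"] = prev["day"] - 1
    prev = prev.merge(
        thr.reset_index().rename(columns={"day": "prev_day"}),
        on=["nest_id", "prev_day"], how="left",
    ).merge(
        night_any.reset_index().rename(columns={"day": "prev_day"}),
        on=["nest_id", "prev_day"], how="left",
    )
    out["night_threshold"] = prev["thr"].to_numpy()
    out["night_has_data"] = prev["n_night"].fillna(0).to_numpy() > 0

    active = active.merge(
        out[["nest_id", "day", "night_threshold"]], on=["nest_id", "day"],
        how="left",
    )
    inc = (
        (active["temp"] > active["night_threshold"])
        .fillna(False)
        .groupby([active["nest_id"], active["day"]])
        .sum()
        .rename("n_incubating")
        .reset_index()
    )
    out = out.merge(inc, on=["nest_id", "day"], how="left")
    out["n_incubating"] = out["n_incubating"].fillna(0).astype(int)
    # a day is classifiable if it has active readings and its preceding
    # night has data (threshold may still be undefined = no incubation)
    out["classified"] = (out["n_active"] > 0) & out["night_has_data"]
    out["intensity"] = np.where(
        out["night_threshold"].notna(),
        out["n_incubating"] / out["n_active"].clip(lower=1),
        0.0,
    )
    return out[["nest_id"] + DAILY_COLUMNS]


def build_profile(paired: pd.DataFrame, placement_date: int,
                  config: DetectionConfig = DetectionConfig()
                  ) -> IncubationProfile:
    """Full detector for a single nest's paired trace."""
    nest_id = str(paired["nest_id"].iloc[0]) if "nest_id" in paired else "nest"
    daily = daily_table(paired.assign(nest_id=nest_id), config)
    daily = daily.drop(columns=["nest_id"]).sort_values("day").reset_index(drop=True)
    onset = detect_onset(daily, config)
    included, reason = validate_nest(daily, onset, placement_date, config)
    return IncubationProfile(
        nest_id=nest_id, daily=daily, onset_date=onset,
        included=included, reason=reason,
    )


def detect_all(paired: pd.DataFrame, placements: pd.Series | dict,
               config: DetectionConfig = DetectionConfig()
               ) -> dict[str, IncubationProfile]:
    """Detector over a multi-nest paired table; placements map nest_id->day."""
    placements = pd.Series(placements)
    daily_all = daily_table(paired, config)
    profiles: dict[str, IncubationProfile] = {}
    for nid, daily in daily_all.groupby("nest_id", sort=True):
        daily = daily.drop(columns=["nest_id"]).sort_values("day")
        daily = daily.reset_index(drop=True)
        onset = detect_onset(daily, config)
        included, reason = validate_nest(daily, onset, int(placements[nid]), config)
        profiles[str(nid)] = IncubationProfile(
            nest_id=str(nid), daily=daily, onset_date=onset,
            included=included, reason=reason,
        )
    return profiles


def profiles_summary(profiles: dict[str, IncubationProfile]) -> pd.DataFrame:
    """Nest-level summary table (onset, inclusion flag, reason)."""
    return pd.DataFrame([
        {
            "nest_id": p.nest_id,
            "onset_date": p.onset_date,
            "included": p.included,
            "reason": p.reason,
        }
        for p in profiles.values()
    ])
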