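"""Nest-level incubation behaviour traits and their inter-relationships.

Three traits per nest:

* relative onset — detected onset of full daytime incubation minus clutch
  completion date (days; negative when incubation starts before the clutch
  is complete);
* duration — observed hatch date minus onset (days);
* mean intensity — the mean daily proportion of active-day readings classed
  as incubating, over the days from onset to the day before hatching (the
  hatch day is excluded: loggers come out of the nest then).

``relative_onset + duration = hatch - completion`` holds by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detection import IncubationProfile


def compute_behaviours(profiles: dict[str, IncubationProfile],
                       records: pd.DataFrame) -> pd.DataFrame:
    """Behaviour table for nests that passed validation and hatched.

    Returns one row per usable nest: nest_id, onset_date, relative_onset,
    duration, mean_intensity, n_incubating_slots, n_active_slots (summed
    over full-incubation days), clutch_size, initiation_date, plus the
    record's hatch/completion dates for downstream joins.
    """
    rec = records.set_index("nest_id")
    rows = []
    for nid, prof in profiles.items():
        if not prof.included:
            continue
        if nid not in rec.index or pd.isna(rec.loc[nid, "hatch_date"]):
            continue
        hatch = int(rec.loc[nid, "hatch_date"])
        completion = int(rec.loc[nid, "completion_date"])
        onset = int(prof.onset_date)
        days = prof.daily[
            (prof.daily["day"] >= onset) & (prof.daily["day"] < hatch)
            & prof.daily["classified"]
        ]
        rows.append({
            "nest_id": nid,
            "onset_date": onset,
            "relative_onset": onset - completion,
            "duration": hatch - onset,
            "mean_intensity": float(days["intensity"].mean()),
            "n_incubating_slots": int(days["n_incubating"].sum()),
            "n_active_slots": int(days["n_active"].sum()),
            "clutch_size": int(rec.loc[nid, "clutch_size"]),
            "initiation_date": int(rec.loc[nid, "initiation_date"]),
            "completion_date": completion,
            "hatch_date": hatch,
        })
    return pd.DataFrame(rows)


def max_alteration(onset_range: tuple[float, float],
                   duration_range: tuple[float, float],
                   expected_duration: float) -> tuple[float, float]:
    """Maximum possible advance and delay of hatch date (days).

    The baseline is incubation starting at clutch completion and lasting
    the expected duration.  Assuming onset and duration vary independently,
    the earliest possible hatch combines the minimum onset with the
    minimum duration, and the latest the two maxima:

    ``advance = expected - (onset_min + duration_min)``
    ``delay   = (onset_max + duration_max) - expected``
    """
    omin, omax = onset_range
    dmin, dmax = duration_range
    if omin > omax or dmin > dmax:
        raise ValueError("ranges must be ordered (min, max)")
    advance = expected_duration - (omin + dmin)
    delay = (omax + dmax) - expected_duration
    return advance, delay


def fit_intensity_model(table: pd.DataFrame):
    """Binomial GLM of mean incubation intensity on relative onset.

    Covariates: clutch size and clutch initiation date.  Fitted on the
    aggregated per-nest counts (incubating slots, total active slots),
    which carries the per-nest information a plain proportion loses.
    Returns the fitted statsmodels results object.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 nests to fit the intensity model")
    X = sm.add_constant(
        table[["relative_onset", "clutch_size", "initiation_date"]].astype(float)
    )
    endog = np.column_stack([
        table["n_incubating_slots"].to_numpy(),
        table["n_active_slots"].to_numpy() - table["n_incubating_slots"].to_numpy(),
    ])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    if not np.isfinite(res.bse).all():
        raise ValueError("intensity model is separated or singular")
    return res


def fit_duration_model(table: pd.DataFrame):
    """OLS of incubation duration on intensity, relative onset, clutch size."""
    if len(table) < 10:
        raise ValueError("need at least 10 nests to fit the duration model")
    X = sm.add_constant(
        table[["mean_intensity", "relative_onset", "clutch_size"]].astype(float)
    )
    res = sm.OLS(table["duration"].astype(float), X).fit()
    if not np.isfinite(res.bse).all():
        raise ValueError("duration model design is singular")
    return res
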