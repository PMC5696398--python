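"""Sliding temperature windows and candidate cue-model selection.

Twelve windows index the period over which a temperature cue might act.
Window 1 (the "laying period") runs from clutch initiation to the onset of
full incubation and is nest-specific; windows 2-11 extend the start back
1-10 days before initiation; window 12 runs from the onset to hatching and
enters only the duration analysis.  Within a window, four temperature
measures are computed from the nest's paired ambient logger: the mean
temperature, and the means of the daily minima (MMin), daily maxima
(MMax) and daily ranges (Trange).

Candidate linear models for relative onset combine each of the 44
window-measure variables (4 measures x windows 1-11) with four fixed-effect
configurations, plus two temperature-free null models — 178 fits.  The
duration candidates add relative onset to every model (nulls included) and
the four window-12 measures in the temperature-only configuration — 182
fits.  Daily-intensity candidates are binomial mixed models (nest random
intercept) of per-day incubating slot counts on incubation day and one
daily temperature variable in four configurations, plus one null — 17
fits.  Models are ranked by AIC; models within 2 AIC units of the best
form the equivalence set.  Ties at machine precision break by (window,
measure, configuration) order.
"""

from __future__ import annotations

import itertools
import json

import numpy as np
import pandas as pd

from .glmm import GLMMResult, fit_binomial_glmm

MEASURES = ("mean", "mmin", "mmax", "trange")
ONSET_WINDOWS = tuple(range(1, 12))
DURATION_WINDOWS = tuple(range(1, 13))
ONSET_CONFIGS = ("T", "T+init", "Txinit", "T+clutch")
NULL_CONFIGS = ("null:init", "null:init+clutch")
INTENSITY_CONFIGS = ("day+T", "day+T+init", "dayxT", "day+T+clutch")
AIC_EQUIVALENCE = 2.0


# ---------------------------------------------------------------------------
# Windows and temperature measures
# ---------------------------------------------------------------------------

def window_dates(initiation: int, onset: int, hatch: int | None,
                 index: int) -> tuple[int, int]:
    """Inclusive day interval of window ``index`` for one nest.

    Windows 1-11 end at the onset of full incubation; window ``1 + k``
    starts ``k`` days before clutch initiation.  Window 12 spans onset to
    hatch.
    """
    if index == 12:
        if hatch is None:
            raise ValueError("window 12 requires a hatch date")
        return int(onset), int(hatch)
    if not 1 <= index <= 11:
        raise ValueError(f"window index {index} out of range 1..12")
    start = int(initiation) - (index - 1)
    end = int(onset)
    if end < start:
        raise ValueError(
            f"window {index} is empty: onset {onset} before start {start}"
        )
    return start, end


def daily_ambient_stats(ambient: pd.DataFrame) -> pd.DataFrame:
    """Per logger-day mean/min/max/range of the ambient readings."""
    g = ambient.groupby(["logger_id", "day"])["temp"]
    out = g.agg(dmean="mean", dmin="min", dmax="max").reset_index()
    out["drange"] = out["dmax"] - out["dmin"]
    return out


_MEASURE_COL = {"mean": "dmean", "mmin": "dmin", "mmax": "dmax",
                "trange": "drange"}


def window_temperature(daily_stats: pd.DataFrame, logger_id: str,
                       start: int, end: int, measure: str) -> float:
    """Average the daily statistic over an inclusive day interval."""
    col = _MEASURE_COL[measure]
    sub = daily_stats[
        (daily_stats["logger_id"] == str(logger_id))
        & (daily_stats["day"] >= start) & (daily_stats["day"] <= end)
    ]
    got = set(sub["day"])
    missing = [d for d in range(start, end + 1) if d not in got]
    if missing:
        raise ValueError(
            f"logger {logger_id}: no ambient readings on day(s) {missing}"
        )
    return float(sub[col].mean())


def temperature_variables(table: pd.DataFrame, daily_stats: pd.DataFrame,
                          windows=DURATION_WINDOWS) -> pd.DataFrame:
    """Window-measure temperature values for every nest.

    ``table`` needs nest_id, logger_id, initiation_date, onset_date and
    (for window 12) hatch_date.  Returns a long frame with columns
    nest_id, window, measure, value.
    """
    stats = daily_stats.set_index(["logger_id", "day"]).sort_index()
    rows = []
    for rec in table.itertuples():
        lid = str(rec.logger_id)
        sub = stats.loc[lid]
        for w in windows:
            hatch = getattr(rec, "hatch_date", None)
            if w == 12 and (hatch is None or pd.isna(hatch)):
                continue
            start, end = window_dates(
                rec.initiation_date, rec.onset_date,
                None if w != 12 else int(hatch), w,
            )
            span = sub.loc[start:end]
            if len(span) != end - start + 1:
                missing = sorted(set(range(start, end + 1)) - set(span.index))
                raise ValueError(
                    f"logger {lid}: no ambient readings on day(s) {missing}"
                )
            vals = {
                "mean": span["dmean"].mean(),
                "mmin": span["dmin"].mean(),
                "mmax": span["dmax"].mean(),
                "trange": span["drange"].mean(),
            }
            for m in MEASURES:
                rows.append({
                    "nest_id": rec.nest_id, "window": w, "measure": m,
                    "value": float(vals[m]),
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian candidate fits (relative onset, duration)
# ---------------------------------------------------------------------------

def _ols_fit(X: np.ndarray, y: np.ndarray, names: list[str]) -> dict | None:
    """Least-squares fit with Gaussian ML log-likelihood and Wald SEs.

    Returns None for rank-deficient designs.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        return None
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    llf = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    k = p + 1  # + error variance
    dof = n - p
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(xtx_inv) * rss / max(dof, 1))
    return {
        "coefficients": dict(zip(names, beta.astype(float))),
        "bse": dict(zip(names, se.astype(float))),
        "llf": llf,
        "aic": 2.0 * k - 2.0 * llf,
        "k": k,
        "n": n,
    }


def _design(config: str, tvals: np.ndarray | None, behav: pd.DataFrame,
            include_onset: bool) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one candidate configuration.

    In the interaction configuration the initiation date (and the
    temperature) are centred at their sample means so the temperature main
    effect is the slope at the average initiation date; centring leaves the
    fit and AIC unchanged.
    """
    n = len(behav)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["const"]
    init = behav["initiation_date"].to_numpy(float)
    clutch = behav["clutch_size"].to_numpy(float)
    if config == "null:init":
        cols.append(init); names.append("initiation_date")
    elif config == "null:init+clutch":
        cols += [init, clutch]; names += ["initiation_date", "clutch_size"]
    elif config == "T":
        cols.append(tvals); names.append("temperature")
    elif config == "T+init":
        cols += [tvals, init]; names += ["temperature", "initiation_date"]
    elif config == "Txinit":
        ic = init - init.mean()
        cols += [tvals, ic, tvals * ic]
        names += ["temperature", "initiation_date_c", "temperature:initiation_c"]
    elif config == "T+clutch":
        cols += [tvals, clutch]; names += ["temperature", "clutch_size"]
    else:
        raise ValueError(f"unknown configuration {config}")
    if include_onset:
        cols.append(behav["relative_onset"].to_numpy(float))
        names.append("relative_onset")
    return np.column_stack(cols), names


def _rank(models: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(models)
    df["window"] = np.where(df["window"].isna(), 99, df["window"]).astype(int)
    df = df.sort_values(
        ["aic", "window", "measure", "config"], kind="stable"
    ).reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df["equivalent"] = df["delta_aic"] < AIC_EQUIVALENCE
    df["window"] = df["window"].astype("object").replace(99, pd.NA)
    return df


def _fit_gaussian_candidates(behaviours: pd.DataFrame, tvars: pd.DataFrame,
                             response: str, windows, include_onset: bool,
                             window12_configs: tuple = ()) -> pd.DataFrame:
    behav = behaviours.sort_values("nest_id").reset_index(drop=True)
    y = behav[response].to_numpy(float)
    wide = tvars.pivot_table(
        index="nest_id", columns=["window", "measure"], values="value"
    ).loc[behav["nest_id"]]
    models = []
    for config in NULL_CONFIGS:
        X, names = _design(config, None, behav, include_onset)
        fit = _ols_fit(X, y, names)
        if fit is not None:
            models.append({
                "response": response, "config": config,
                "window": None, "measure": "", **fit,
            })
    for w, m in itertools.product(windows, MEASURES):
        configs = ONSET_CONFIGS if w != 12 else window12_configs
        if (w, m) not in wide.columns:
            continue
        tvals = wide[(w, m)].to_numpy(float)
        for config in configs:
            X, names = _design(config, tvals, behav, include_onset)
            fit = _ols_fit(X, y, names)
            if fit is None:
                continue
            models.append({
                "response": response, "config": config,
                "window": w, "measure": m, **fit,
            })
    return _rank(models)


def fit_onset_candidates(behaviours: pd.DataFrame,
                         tvars: pd.DataFrame) -> pd.DataFrame:
    """Rank the 176 temperature + 2 null models for relative onset."""
    return _fit_gaussian_candidates(
        behaviours, tvars, "relative_onset", ONSET_WINDOWS, include_onset=False,
    )


def fit_duration_candidates(behaviours: pd.DataFrame,
                            tvars: pd.DataFrame) -> pd.DataFrame:
    """Rank the duration candidates; relative onset enters every model."""
    return _fit_gaussian_candidates(
        behaviours, tvars, "duration", DURATION_WINDOWS, include_onset=True,
        window12_configs=("T",),
    )


# ---------------------------------------------------------------------------
# Daily-intensity candidates (binomial GLMM)
# ---------------------------------------------------------------------------

def intensity_daily_table(profiles: dict, behaviours: pd.DataFrame,
                          daily_stats: pd.DataFrame,
                          pairing: pd.Series | dict) -> pd.DataFrame:
    """Per nest-day rows for the intensity mixed models.

    Incubation day 1 is the onset day; the hatch day is excluded.  Daily
    temperatures come from the nest's paired ambient logger.
    """
    pairing = pd.Series(pairing)
    stats = daily_stats.set_index(["logger_id", "day"])
    rows = []
    for rec in behaviours.itertuples():
        prof = profiles[rec.nest_id]
        days = prof.daily[
            (prof.daily["day"] >= rec.onset_date)
            & (prof.daily["day"] < rec.hatch_date)
            & prof.daily["classified"]
        ]
        lid = str(pairing[rec.nest_id])
        for d in days.itertuples():
            st = stats.loc[(lid, int(d.day))]
            rows.append({
                "nest_id": rec.nest_id,
                "day": int(d.day),
                "incubation_day": int(d.day) - int(rec.onset_date) + 1,
                "n_incubating": int(d.n_incubating),
                "n_active": int(d.n_active),
                "dmean": float(st["dmean"]),
                "dmin": float(st["dmin"]),
                "dmax": float(st["dmax"]),
                "drange": float(st["drange"]),
                "clutch_size": int(rec.clutch_size),
                "initiation_date": int(rec.initiation_date),
            })
    return pd.DataFrame(rows)


def _intensity_design(daily: pd.DataFrame, config: str,
                      measure: str | None) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(daily))})
    if config == "null":
        X["initiation_date"] = daily["initiation_date"].to_numpy(float)
        return X
    X["incubation_day"] = daily["incubation_day"].to_numpy(float)
    t = daily[_MEASURE_COL[measure]].to_numpy(float)
    X["temperature"] = t
    if config == "day+T+init":
        X["initiation_date"] = daily["initiation_date"].to_numpy(float)
    elif config == "dayxT":
        X["day:temperature"] = X["incubation_day"] * t
    elif config == "day+T+clutch":
        X["clutch_size"] = daily["clutch_size"].to_numpy(float)
    elif config != "day+T":
        raise ValueError(f"unknown intensity configuration {config}")
    return X


def fit_intensity_candidates(daily: pd.DataFrame,
                             n_quad: int = 15) -> tuple[pd.DataFrame, dict]:
    """Rank the 17 daily-intensity mixed models by ML AIC.

    Returns the ranking frame and a dict of fitted :class:`GLMMResult`
    keyed by (config, measure).  Non-converged fits are flagged and left
    out of the ranking.
    """
    models, fits = [], {}
    combos = [("null", None)] + [
        (c, m) for c, m in itertools.product(INTENSITY_CONFIGS, MEASURES)
    ]
    for config, measure in combos:
        X = _intensity_design(daily, config, measure)
        res = fit_binomial_glmm(
            daily["n_incubating"], daily["n_active"], X,
            daily["nest_id"], n_quad=n_quad,
        )
        fits[(config, measure or "")] = res
        models.append({
            "response": "daily_intensity", "config": config,
            "window": None, "measure": measure or "",
            "coefficients": res.params.to_dict(),
            "bse": res.bse.to_dict(),
            "re_sd": res.re_sd,
            "llf": res.llf, "aic": res.aic, "k": res.k_params,
            "n": res.nobs, "converged": res.converged,
        })
    df = pd.DataFrame(models)
    ranked = _rank([m for m in models if m["converged"]])
    dropped = df[~df["converged"]]
    if not dropped.empty:
        ranked.attrs["dropped"] = list(
            zip(dropped["config"], dropped["measure"])
        )
    return ranked, fits


def intensity_marginal_effects(res: GLMMResult,
                               daily: pd.DataFrame,
                               measure: str = "mmax") -> dict[str, float]:
    """Marginal effects of incubation day and temperature at the means.

    Computed on the proportion scale at the sample-mean covariates with
    the random effect at zero: ``p(1-p) * d(eta)/dx``.
    """
    day_bar = float(daily["incubation_day"].mean())
    t_bar = float(daily[_MEASURE_COL[measure]].mean())
    b = res.params
    eta = b.get("const", 0.0) + b.get("incubation_day", 0.0) * day_bar \
        + b.get("temperature", 0.0) * t_bar \
        + b.get("day:temperature", 0.0) * day_bar * t_bar
    if "initiation_date" in b.index:
        eta += b["initiation_date"] * float(daily["initiation_date"].mean())
    if "clutch_size" in b.index:
        eta += b["clutch_size"] * float(daily["clutch_size"].mean())
    p = 1.0 / (1.0 + np.exp(-eta))
    deriv = p * (1.0 - p)
    d_day = b.get("incubation_day", 0.0) + b.get("day:temperature", 0.0) * t_bar
    d_temp = b.get("temperature", 0.0) + b.get("day:temperature", 0.0) * day_bar
    return {
        "p_at_means": float(p),
        "marginal_per_day": float(deriv * d_day),
        "marginal_per_degC": float(deriv * d_temp),
        "interaction_logit": float(b.get("day:temperature", 0.0)),
    }


def candidates_to_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["coefficients"] = out["coefficients"].map(json.dumps)
    out["bse"] = out["bse"].map(json.dumps)
    out.to_csv(path, index=False)
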