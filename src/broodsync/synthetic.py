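"""Synthetic field data with known ground truth.

Emulates the four inputs of the analysis — an ambient temperature logger
grid, in-nest temperature traces, nest breeding records, and annual
caterpillar peak dates — for a woodland population of cavity-nesting birds
whose incubation behaviour responds to spring temperature.

The generating model, briefly:

* Ambient temperature at a logger is a seasonal warming trend plus a smooth
  spatial field, a shared AR(1) day-to-day anomaly, a small logger-specific
  daily anomaly, and a diurnal sinusoid (daily maximum mid-afternoon,
  minimum pre-dawn), plus instrument noise.
* Each nest lays one egg per day from a seasonally distributed initiation
  date; clutch size declines with later initiation, so completion dates are
  less variable than initiation dates.
* The relative onset of full (daytime) incubation — days from clutch
  completion to the first day with at least half the active day spent
  incubating — follows a linear cue model on the mean ambient temperature
  integrated from 7 days before laying up to the *expected* onset, with a
  temperature x initiation-date interaction.  The measured window-8
  variable (which ends at the realized onset) is the closest observable
  proxy for this cue.  Out-of-range draws are resampled (truncated-normal
  residuals), not clipped, so the regression structure is preserved.
* Incubation duration declines with relative onset and is otherwise
  temperature-independent.
* Daily incubation intensity (proportion of 36 twenty-minute active-day
  slots spent incubating) follows a logistic model in incubation day and
  the day's maximum ambient temperature, with a negative day x temperature
  interaction, a nest-level random intercept, and logit-normal day-to-day
  noise.  The logit-scale coefficients are calibrated so the generating
  marginal effects (on the proportion scale, at the reference covariates)
  take configured values.  In the trace world each nest's intensity ramp
  is shifted along the day axis so it crosses the 50% rule exactly on the
  cue-determined onset date (the measured onset is the crossing); days
  before the onset carry a sub-50% transition of growing daytime bouts.
* Fledgling counts are Poisson with a log-linear surface in hatching
  synchrony (hatch date minus caterpillar peak) and its square, clutch
  size, initiation synchrony and its square, and a woodland-section effect.

In-nest traces: slots where the bird incubates read a fixed contrast above
the *daily* local ambient level (the sitting bird buffers the diurnal
cycle) with a slow warming ramp over each night-plus-day stint and a small
nocturnal depression, so the nightly recalibration scheme recovers the
onset exactly on noise-free traces.  Non-incubated slots track instantaneous local ambient to within
the instrument noise.  Nocturnal incubation ramps up over the nights
before clutch completion; hot active-day slots fill contiguously from the
start of the active day.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from . import field_io

MINUTES_PER_DAY = 1440

# substream labels for seeded, order-independent generation
_STREAM_AMBIENT = 1
_STREAM_NESTS = 2
_STREAM_TRACES = 3
_STREAM_LONGTERM = 4
_STREAM_INTENSITY = 5


def _default_fitness_params() -> dict:
    # log-link Poisson surface; synchrony terms on the raw (unshifted) scale
    return {
        "intercept": 2.6,
        "synchrony": -0.074,
        "synchrony2": -0.0017,
        "clutch": 0.05,
        "init_synchrony": 0.036,
        "init_synchrony2": -0.00012,
        "section_sd": 0.05,
    }


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    n_nests: int = 93
    seed: int = 0
    year: int = 2014

    # season and sampling
    season_start: int = 75
    season_end: int = 190
    sampling_interval_nest: int = 20      # minutes
    sampling_interval_ambient: int = 30   # minutes
    active_day: tuple[int, int] = (420, 1140)    # 07:00-19:00, half-open
    night_window: tuple[int, int] = (1140, 1440)  # 19:00-24:00, half-open

    # ambient temperature field
    n_loggers: int = 25
    extent: float = 3000.0          # woodland side length, m
    base_temp: float = 10.0         # deg C at mid-season
    warming_rate: float = 0.06      # deg C per day seasonal trend
    diurnal_amplitude: float = 8.0  # mean daily max minus min, deg C
    amplitude_sd: float = 1.2       # shared day-to-day amplitude variation
    amplitude_logger_sd: float = 1.0  # per-logger amplitude microclimate
    amplitude_range: tuple[float, float] = (4.0, 10.0)
    diurnal_peak_minute: int = 900  # 15:00
    anomaly_sd: float = 1.0         # shared day-to-day anomaly, deg C
    anomaly_rho: float = 0.3        # AR(1) day-to-day correlation
    logger_anomaly_sd: float = 1.3   # day-to-day microclimate, per logger
    spatial_sd: float = 0.7
    noise_sd_ambient: float = 0.2

    # breeding schedule
    initiation_mean: float = 115.0
    initiation_sd: float = 5.0
    clutch_mean: float = 8.5
    clutch_initiation_slope: float = -0.25  # eggs per day of later initiation
    clutch_sd: float = 1.0
    clutch_range: tuple[int, int] = (5, 13)

    # relative-onset cue model (window-8 mean temperature is the cue)
    onset_mean: float = 4.5
    onset_temp_slope: float = -5.03        # days per deg C
    onset_initiation_interaction: float = 0.3  # days per deg C per day
    onset_sd: float = 1.5
    onset_range: tuple[int, int] = (-3, 12)

    # duration model
    duration_baseline: float = 11.5
    duration_onset_slope: float = -0.45
    duration_sd: float = 1.5
    duration_range: tuple[int, int] = (7, 19)

    # daily-intensity model; logit params calibrated unless given explicitly
    intensity_logit_params: tuple[float, float, float, float] | None = None
    intensity_marginal_day: float = 0.05    # proportion per incubation day
    intensity_marginal_tmax: float = 0.02   # proportion per deg C daily max
    intensity_interaction: float = -0.008   # logit scale, day x tmax
    intensity_mean: float = 0.70
    intensity_day_ref: float = 6.25     # expected mean incubation day
    intensity_random_sd: float = 0.35       # nest random intercept, logit
    intensity_day_noise_sd: float = 0.25    # logit-normal day noise

    # in-nest traces
    incubation_contrast: float = 10.0   # deg C above daily ambient level
    night_ramp_days: int = 3            # nights to ramp nocturnal incubation
    nocturnal_lead: int = 7             # nights before completion ramp starts
    bout_warming: float = 1.5           # deg C over a 24-h incubation stint
    night_depression: float = 0.3       # deg C cooler incubation at night
    noise_sd_nest: float = 0.5

    # fitness and synchrony
    optimum_offset: float = 13.0
    fitness_params: dict = field(default_factory=_default_fitness_params)
    n_sections: int = 9

    # long-series mode
    years: tuple[int, int] = (1960, 2014)
    nests_per_year: int = 212
    caterpillar_mean: float = 148.0
    caterpillar_sd: float = 6.0
    tracking_sd: float = 3.0     # imperfect tracking of the peak by laying
    compensation: float = 0.3    # fraction of timing error removed post-laying
    hatch_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        for iv in (self.sampling_interval_nest, self.sampling_interval_ambient):
            if 60 % iv != 0:
                raise ValueError(f"sampling interval {iv} must divide 60")
        a0, a1 = self.active_day
        n0, n1 = self.night_window
        if max(a0, n0) < min(a1, n1):
            raise ValueError("active_day and night_window must not overlap")
        if self.incubation_contrast <= 4.0:
            raise ValueError("incubation_contrast must exceed the 4 degC cutoff")
        if self.season_end <= self.season_start:
            raise ValueError("season span must be positive")
        for name in ("onset_range", "duration_range", "clutch_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")

    # -- derived quantities -------------------------------------------------

    @property
    def season_mid(self) -> float:
        return 0.5 * (self.season_start + self.season_end)

    @property
    def n_active_slots(self) -> int:
        a0, a1 = self.active_day
        return (a1 - a0) // self.sampling_interval_nest

    @property
    def n_night_slots(self) -> int:
        n0, n1 = self.night_window
        return (n1 - n0) // self.sampling_interval_nest

    def onset_temp_ref(self) -> float:
        """Climatological mean temperature of a typical cue window."""
        mid = self.initiation_mean + 2.5
        return self.base_temp + self.warming_rate * (mid - self.season_mid)

    def tmax_ref(self) -> float:
        """Climatological daily maximum around mid-incubation."""
        mid = (
            self.initiation_mean + self.clutch_mean - 1 + self.onset_mean
            + 0.5 * self.duration_baseline
        )
        return (
            self.base_temp
            + self.warming_rate * (mid - self.season_mid)
            + 0.5 * self.diurnal_amplitude
        )

    @property
    def onset_rule_logit(self) -> float:
        """Logit of the smallest intensity that rounds to the 50% rule."""
        k = int(np.ceil(0.5 * self.n_active_slots))  # 18 of 36
        return float(logit((k - 0.5) / self.n_active_slots))

    def intensity_params(self) -> tuple[float, float, float, float]:
        """Logit-scale (intercept, day, tmax, day*tmax) coefficients.

        Calibrated so that, at the reference incubation day and daily
        maximum, the mean intensity equals ``intensity_mean`` and the
        marginal effects on the proportion scale equal the configured
        targets (marginal = p(1-p) x logit-scale slope).
        """
        if self.intensity_logit_params is not None:
            return tuple(self.intensity_logit_params)
        p = self.intensity_mean
        deriv = p * (1.0 - p)
        day_ref = self.intensity_day_ref
        tref = self.tmax_ref()
        inter = self.intensity_interaction
        b_day = self.intensity_marginal_day / deriv - inter * tref
        b_tmax = self.intensity_marginal_tmax / deriv - inter * day_ref
        intercept = (
            logit(p) - b_day * day_ref - b_tmax * tref - inter * day_ref * tref
        )
        return (float(intercept), float(b_day), float(b_tmax), float(inter))

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    @classmethod
    def selection_study(cls, seed: int, n_nests: int = 500,
                        **kw) -> "GeneratorConfig":
        """Strong-signal, low-noise conditions for the window-selection
        recovery study: the cue effect is several residual SDs, so the true
        (window, measure) pair should attain the lowest AIC."""
        kw.setdefault("onset_sd", 0.5)
        return cls(seed=seed, n_nests=n_nests, **kw)

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Ambient grid
# ---------------------------------------------------------------------------

@dataclass
class AmbientGrid:
    """Generated ambient series plus the noise-free model behind them."""

    df: pd.DataFrame          # logger_id, x, y, day, minute, temp
    loggers: pd.DataFrame     # logger_id, x, y, spatial
    days: np.ndarray
    anomaly: np.ndarray           # shared, per day
    logger_anomaly: np.ndarray    # (n_loggers, n_days)
    amplitude: np.ndarray         # per (logger, day) diurnal amplitude
    config: GeneratorConfig

    def _day_index(self, day) -> np.ndarray:
        return np.asarray(day) - self.config.season_start

    def daily_level(self, logger_index, day) -> np.ndarray:
        """Noise-free daily mean temperature (diurnal cycle averages out)."""
        c = self.config
        li = np.asarray(logger_index)
        di = self._day_index(day)
        return (
            c.base_temp
            + c.warming_rate * (np.asarray(day) - c.season_mid)
            + self.loggers["spatial"].to_numpy()[li]
            + self.anomaly[di]
            + self.logger_anomaly[li, di]
        )

    def diurnal(self, logger_index, day, minute) -> np.ndarray:
        c = self.config
        trough = c.diurnal_peak_minute - MINUTES_PER_DAY // 2
        amp = self.amplitude[np.asarray(logger_index), self._day_index(day)]
        return -0.5 * amp * np.cos(
            2.0 * np.pi * (np.asarray(minute) - trough) / MINUTES_PER_DAY
        )

    def daily_tmax(self, logger_index, day) -> np.ndarray:
        """Noise-free daily maximum temperature."""
        return (
            self.daily_level(logger_index, day)
            + 0.5 * self.amplitude[np.asarray(logger_index), self._day_index(day)]
        )

    def temp_at(self, logger_index, day, minute) -> np.ndarray:
        """Noise-free instantaneous ambient temperature."""
        return self.daily_level(logger_index, day) + self.diurnal(
            logger_index, day, minute)


def generate_ambient_grid(config: GeneratorConfig) -> AmbientGrid:
    """Simulate the full-season ambient logger grid at 30-min spacing."""
    c = config
    rng = c.rng(_STREAM_AMBIENT)
    n = c.n_loggers
    side = int(np.ceil(np.sqrt(n)))
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    cell = c.extent / side
    xs = (gx.ravel()[:n] + 0.5) * cell + rng.uniform(-0.2, 0.2, n) * cell
    ys = (gy.ravel()[:n] + 0.5) * cell + rng.uniform(-0.2, 0.2, n) * cell
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    spatial = c.spatial_sd * (
        np.sin(2 * np.pi * xs / c.extent + ph1)
        + np.sin(2 * np.pi * ys / c.extent + ph2)
    ) / np.sqrt(2.0)
    loggers = pd.DataFrame({
        "logger_id": [f"L{i:03d}" for i in range(n)],
        "x": np.round(xs, 1),
        "y": np.round(ys, 1),
        "spatial": spatial,
    })

    days = np.arange(c.season_start, c.season_end + 1)
    nd = len(days)
    anomaly = np.empty(nd)
    innov_sd = c.anomaly_sd * np.sqrt(max(1.0 - c.anomaly_rho**2, 0.0))
    anomaly[0] = rng.normal(0.0, c.anomaly_sd)
    shocks = rng.normal(0.0, innov_sd, nd - 1)
    for t in range(1, nd):
        anomaly[t] = c.anomaly_rho * anomaly[t - 1] + shocks[t - 1]
    logger_anomaly = rng.normal(0.0, c.logger_anomaly_sd, (n, nd))
    amplitude = np.clip(
        c.diurnal_amplitude
        + rng.normal(0.0, c.amplitude_sd, nd)[None, :]
        + rng.normal(0.0, c.amplitude_logger_sd, (n, nd)),
        *c.amplitude_range,
    )

    grid = AmbientGrid(
        df=pd.DataFrame(), loggers=loggers, days=days,
        anomaly=anomaly, logger_anomaly=logger_anomaly,
        amplitude=amplitude, config=c,
    )
    minutes = np.arange(0, MINUTES_PER_DAY, c.sampling_interval_ambient)
    li = np.repeat(np.arange(n), nd * len(minutes))
    dd = np.tile(np.repeat(days, len(minutes)), n)
    mm = np.tile(minutes, n * nd)
    temp = grid.temp_at(li, dd, mm)
    if c.noise_sd_ambient > 0:
        temp = temp + rng.normal(0.0, c.noise_sd_ambient, temp.shape)
    grid.df = pd.DataFrame({
        "logger_id": loggers["logger_id"].to_numpy()[li],
        "x": loggers["x"].to_numpy()[li],
        "y": loggers["y"].to_numpy()[li],
        "day": dd,
        "minute": mm,
        "temp": temp,
    })
    return grid


# ---------------------------------------------------------------------------
# Nests and ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-nest generating quantities, echoed for recovery tests."""

    nests: pd.DataFrame   # nest_id, logger_index, true_onset_date,
                          # true_relative_onset, true_duration,
                          # window8_mean_temp, random_intercept
    daily: pd.DataFrame   # nest_id, day, incubation_day, tmax, true_intensity, n_hot
    params: dict          # generating coefficients echoed from the config


def _resample_truncated(rng, draw, lo, hi, max_rounds=200, what="value"):
    """Redraw out-of-range values until all fall in [lo, hi]."""
    vals = draw(None)
    for _ in range(max_rounds):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            return vals
        vals[bad] = draw(int(bad.sum()))
    raise ValueError(f"truncation of {what} to [{lo}, {hi}] empties the support")


def generate_nests(
    config: GeneratorConfig, grid: AmbientGrid
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw breeding records and the ground truth behind them."""
    c = config
    rng = c.rng(_STREAM_NESTS)
    n = c.n_nests
    nest_ids = np.array([f"N{i:03d}" for i in range(n)])
    xs = rng.uniform(0, c.extent, n)
    ys = rng.uniform(0, c.extent, n)
    lg = grid.loggers
    dx = xs[:, None] - lg["x"].to_numpy()[None, :]
    dy = ys[:, None] - lg["y"].to_numpy()[None, :]
    logger_index = np.argmin(dx**2 + dy**2, axis=1)

    lo_init = c.season_start + 11
    hi_init = c.season_end - 45
    initiation = np.rint(
        _resample_truncated(
            rng,
            lambda k: rng.normal(c.initiation_mean, c.initiation_sd,
                                 n if k is None else k),
            lo_init, hi_init, what="initiation date",
        )
    ).astype(int)
    mean_clutch = c.clutch_mean + c.clutch_initiation_slope * (
        initiation - c.initiation_mean
    )
    clutch = np.rint(mean_clutch + rng.normal(0.0, c.clutch_sd, n))
    for _ in range(200):
        bad = (clutch < c.clutch_range[0]) | (clutch > c.clutch_range[1])
        if not bad.any():
            break
        clutch[bad] = np.rint(
            mean_clutch[bad] + rng.normal(0.0, c.clutch_sd, int(bad.sum()))
        )
    else:
        raise ValueError("truncation of clutch size empties the support")
    clutch = clutch.astype(int)
    completion = initiation + clutch - 1

    # --- relative onset: the window-8 temperature cue ----------------------
    # The bird integrates mean temperature from 7 days before laying up to
    # its *expected* onset (completion + the population-mean relative
    # onset).  Using the expected rather than the realized endpoint keeps
    # the cue exogenous: the measured window-8 variable (ending at the
    # realized onset) is its closest observable proxy.  The cue is centred
    # on the realized cohort means — the configured slope is a
    # within-season contrast, and a shared warm spell should not push the
    # whole cohort against the truncation bounds.
    lo, hi = c.onset_range
    if hi - lo < 1:
        raise ValueError("truncation of relative onset empties the support")
    end_offset = int(round(c.onset_mean))
    w8 = np.empty(n)
    for i in range(n):
        d0 = max(initiation[i] - 7, c.season_start)
        d1 = min(completion[i] + end_offset, c.season_end)
        w8[i] = grid.daily_level(
            logger_index[i], np.arange(d0, d1 + 1)
        ).mean()
    t_ref = float(w8.mean())
    init_ref = float(initiation.mean())
    dt = w8 - t_ref
    sys_rel = (
        c.onset_mean
        + c.onset_temp_slope * dt
        + c.onset_initiation_interaction * dt * (initiation - init_ref)
    )
    # truncation by resampling, drawn in one pass from the equivalent
    # per-nest truncated normal so the rounded onset lands in range
    u = rng.uniform(0.0, 1.0, n)
    a = (lo - 0.499 - sys_rel) / c.onset_sd
    b = (hi + 0.499 - sys_rel) / c.onset_sd
    eps = stats.truncnorm.ppf(u, a, b) * c.onset_sd
    rel = np.clip(np.rint(sys_rel + eps), lo, hi).astype(int)

    dlo, dhi = c.duration_range
    mean_dur = c.duration_baseline + c.duration_onset_slope * (rel - c.onset_mean)
    duration = np.rint(mean_dur + rng.normal(0.0, c.duration_sd, n))
    for _ in range(200):
        bad = (duration < dlo) | (duration > dhi)
        if not bad.any():
            break
        duration[bad] = np.rint(
            mean_dur[bad] + rng.normal(0.0, c.duration_sd, int(bad.sum()))
        )
    else:
        raise ValueError("truncation of duration empties the support")
    duration = duration.astype(int)

    onset = completion + rel
    hatch = onset + duration

    # --- daily intensity ---------------------------------------------------
    # The intensity ramp is anchored at the onset: each nest's trajectory is
    # shifted along the (latent) day axis so that it crosses the 50% rule
    # exactly on the cue-determined onset date — the measured onset IS the
    # crossing.  The shift is a per-nest constant, so the within-nest day
    # and temperature slopes the mixed model estimates are untouched.
    # Days before the onset form a sub-50% transition (growing daytime
    # bouts), capped below the rule so the first crossing is the onset.
    a0, b_day, b_tmax, b_int = c.intensity_params()
    u = rng.normal(0.0, c.intensity_random_sd, n)
    rows = []
    n_slots = c.n_active_slots
    rule_slots = int(np.ceil(0.5 * n_slots))
    thr = c.onset_rule_logit
    cap = thr - 0.70  # transition bouts stay clearly below the rule (~1/3)
    ramp_start = np.empty(n, dtype=int)
    max_transition = 8
    for i in range(n):
        days = np.arange(onset[i] - max_transition, hatch[i])  # hatch excluded
        io = max_transition  # index of the onset day
        tmax = grid.daily_tmax(logger_index[i], days)
        base = (
            a0 + b_tmax * tmax + u[i]
            + rng.normal(0.0, c.intensity_day_noise_sd, len(days))
        )
        slope = b_day + b_int * tmax
        # smallest ramp day index on the onset date that reaches the rule
        m_o = max(1, int(np.ceil((thr - base[io]) / slope[io])))
        day_model = (days - onset[i]) + m_o
        eta = base + slope * day_model
        eta = np.where(day_model < 1, -np.inf, eta)
        eta[:io] = np.minimum(eta[:io], cap)
        p = expit(eta)
        n_hot = np.clip(np.rint(p * n_slots), 0, n_slots).astype(int)
        n_hot[io] = max(n_hot[io], rule_slots)
        keep = n_hot > 0
        keep[io:] = True
        ramp_start[i] = int(days[keep][0])
        rows.append(pd.DataFrame({
            "nest_id": nest_ids[i],
            "day": days[keep],
            "incubation_day": days[keep] - onset[i] + 1,
            "ramp_day": day_model[keep],
            "tmax": tmax[keep],
            "n_hot": n_hot[keep],
            "true_intensity": n_hot[keep] / n_slots,
        }))
    daily = pd.concat(rows, ignore_index=True)

    # --- fitness -----------------------------------------------------------
    caterpillar_peak = int(round(hatch.mean() + c.optimum_offset))
    fp = c.fitness_params
    section = rng.integers(1, c.n_sections + 1, n)
    section_effects = rng.normal(0.0, fp.get("section_sd", 0.0), c.n_sections)
    hs = hatch - caterpillar_peak
    isyn = initiation - caterpillar_peak
    eta_f = (
        fp["intercept"]
        + fp["synchrony"] * hs
        + fp["synchrony2"] * hs**2
        + fp["clutch"] * (clutch - c.clutch_mean)
        + fp["init_synchrony"] * isyn
        + fp["init_synchrony2"] * isyn**2
        + section_effects[section - 1]
    )
    fledglings = rng.poisson(np.exp(eta_f))

    records = pd.DataFrame({
        "nest_id": nest_ids,
        "year": c.year,
        "x": np.round(xs, 1),
        "y": np.round(ys, 1),
        "initiation_date": initiation,
        "clutch_size": clutch,
        "completion_date": completion,
        "hatch_date": hatch,
        "fledglings": fledglings,
        "section": section,
    })
    truth_nests = pd.DataFrame({
        "nest_id": nest_ids,
        "logger_index": logger_index,
        "logger_id": lg["logger_id"].to_numpy()[logger_index],
        "true_onset_date": onset,
        "true_relative_onset": rel,
        "true_duration": duration,
        "window8_mean_temp": w8,
        "ramp_start": ramp_start,
        "random_intercept": u,
    })
    params = {
        "onset_temp_slope": c.onset_temp_slope,
        "onset_initiation_interaction": c.onset_initiation_interaction,
        "onset_temp_ref": t_ref,
        "onset_init_ref": init_ref,
        "duration_onset_slope": c.duration_onset_slope,
        "intensity_logit_params": (a0, b_day, b_tmax, b_int),
        "caterpillar_peak": caterpillar_peak,
        "section_effects": section_effects,
        "fitness_params": dict(fp),
    }
    truth = GroundTruth(nests=truth_nests, daily=daily, params=params)
    if (onset < initiation).any():
        raise AssertionError("generated onset precedes clutch initiation")
    return records, truth


def generate_intensity_counts(
    config: GeneratorConfig,
    grid: AmbientGrid | None = None,
    records: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Per nest-day incubation counts drawn directly from the latent model.

    This is the clean parameter-recovery dataset for the daily-intensity
    mixed models: counts of incubating 20-min slots (out of the active-day
    total) for incubation days 1..duration, generated from the calibrated
    logistic model in incubation day and the day's maximum temperature at
    the nest's paired logger, with a nest random intercept and logit-normal
    day noise — no detector in the loop.  Columns match
    :func:`broodsync.cues.intensity_daily_table`.
    """
    c = config
    if grid is None:
        grid = generate_ambient_grid(c)
    if records is None or truth is None:
        records, truth = generate_nests(c, grid)
    rng = c.rng(_STREAM_INTENSITY)
    a0, b_day, b_tmax, b_int = c.intensity_params()
    n = len(records)
    u = rng.normal(0.0, c.intensity_random_sd, n)
    n_slots = c.n_active_slots
    rows = []
    for i, rec in enumerate(records.itertuples()):
        tn = truth.nests.iloc[i]
        li = int(tn["logger_index"])
        onset = int(tn["true_onset_date"])
        days = np.arange(onset, int(rec.hatch_date))  # hatch day excluded
        inc_day = days - onset + 1
        tmax = grid.daily_tmax(li, days)
        eta = (
            a0 + b_day * inc_day + b_tmax * tmax + b_int * inc_day * tmax
            + u[i] + rng.normal(0.0, c.intensity_day_noise_sd, len(days))
        )
        n_hot = np.clip(np.rint(expit(eta) * n_slots), 0, n_slots).astype(int)
        rows.append(pd.DataFrame({
            "nest_id": rec.nest_id,
            "day": days,
            "incubation_day": inc_day,
            "n_incubating": n_hot,
            "n_active": n_slots,
            "dmean": grid.daily_level(li, days),
            "dmin": 2.0 * grid.daily_level(li, days) - tmax,
            "dmax": tmax,
            "drange": 2.0 * (tmax - grid.daily_level(li, days)),
            "clutch_size": int(rec.clutch_size),
            "initiation_date": int(rec.initiation_date),
        }))
    return pd.concat(rows, ignore_index=True)


def caterpillar_table(config: GeneratorConfig, truth: GroundTruth) -> pd.DataFrame:
    return pd.DataFrame({
        "year": [config.year],
        "peak_date": [truth.params["caterpillar_peak"]],
    })


# ---------------------------------------------------------------------------
# In-nest traces
# ---------------------------------------------------------------------------

def placement_dates(config: GeneratorConfig, records: pd.DataFrame,
                    truth: GroundTruth) -> pd.Series:
    """Logger placement early enough to leave a clean non-incubating day."""
    nocturnal_start = (
        records["completion_date"].to_numpy() - config.nocturnal_lead
    )
    placement = np.minimum.reduce([
        records["initiation_date"].to_numpy() - 2,
        nocturnal_start - 1,
        truth.nests["true_onset_date"].to_numpy() - 3,
        truth.nests["ramp_start"].to_numpy() - 2,
    ])
    return pd.Series(placement, index=records.index)


def generate_nest_traces(
    config: GeneratorConfig,
    records: pd.DataFrame,
    truth: GroundTruth,
    grid: AmbientGrid,
) -> pd.DataFrame:
    """Simulate 20-min in-nest temperature traces from placement to hatch-1."""
    c = config
    rng = c.rng(_STREAM_TRACES)
    placement = placement_dates(c, records, truth)
    slots = np.arange(0, MINUTES_PER_DAY, c.sampling_interval_nest)
    a0, a1 = c.active_day
    n0, n1 = c.night_window
    active_mask = (slots >= a0) & (slots < a1)
    night_mask = (slots >= n0) & (slots < n1)
    active_slots = slots[active_mask]
    night_slots = slots[night_mask]
    n_active = len(active_slots)
    n_night = len(night_slots)

    hot_by_day = {
        (r.nest_id, r.day): r.n_hot for r in truth.daily.itertuples()
    }
    parts = []
    for i, rec in enumerate(records.itertuples()):
        tn = truth.nests.iloc[i]
        li = int(tn["logger_index"])
        onset = int(tn["true_onset_date"])
        completion = int(rec.completion_date)
        hatch = int(rec.hatch_date)
        p0 = int(placement.iloc[i])
        days = np.arange(p0, hatch)
        nd = len(days)
        day_grid = np.repeat(days, len(slots))
        minute_grid = np.tile(slots, nd)
        # start from instantaneous ambient tracking
        temp = grid.temp_at(li, day_grid, minute_grid)

        # daily ambient level of the segment each slot belongs to: the night
        # of day d calibrates (and shares a level with) the active day d+1
        seg_day = np.where(minute_grid >= n0, day_grid + 1, day_grid)
        seg_level = grid.daily_level(li, np.clip(seg_day, c.season_start,
                                                 c.season_end))
        minutes_into_seg = np.where(
            minute_grid >= n0,
            minute_grid - n0,
            minute_grid + (MINUTES_PER_DAY - n0),
        )
        hot_temp = (
            seg_level
            + c.incubation_contrast
            + c.bout_warming * minutes_into_seg / MINUTES_PER_DAY
            - np.where(minute_grid >= n0, c.night_depression, 0.0)
        )

        # which slots are incubated?
        hot = np.zeros(nd * len(slots), dtype=bool)
        nocturnal_start = completion - c.nocturnal_lead
        for j, d in enumerate(days):
            base = j * len(slots)
            # nights: ramp up before completion, full from several days
            # before completion onward and throughout incubation
            if d >= nocturnal_start:
                frac = min((d - nocturnal_start + 1) / c.night_ramp_days, 1.0)
                k = int(round(frac * n_night))
                if k > 0:
                    idx = np.flatnonzero(night_mask)[:k]
                    hot[base + idx] = True
            # active day: contiguous block from the start of the day
            # (transition days before the onset carry sub-50% bouts)
            k = int(hot_by_day.get((rec.nest_id, d), 0))
            if k > 0:
                idx = np.flatnonzero(active_mask)[:k]
                hot[base + idx] = True
        temp = np.where(hot, hot_temp, temp)
        if c.noise_sd_nest > 0:
            temp = temp + rng.normal(0.0, c.noise_sd_nest, temp.shape)
        parts.append(pd.DataFrame({
            "nest_id": rec.nest_id,
            "x": rec.x,
            "y": rec.y,
            "placement_date": p0,
            "day": day_grid,
            "minute": minute_grid,
            "temp": temp,
        }))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# Long-series mode (records + caterpillar dates only)
# ---------------------------------------------------------------------------

def generate_longterm(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multi-decade records with compensatory incubation adjustments.

    Laying tracks the caterpillar peak imperfectly; clutch size declines
    with later initiation; the post-completion interval (onset + duration)
    removes a configured fraction of each nest's remaining timing error.
    """
    c = config
    rng = c.rng(_STREAM_LONGTERM)
    y0, y1 = c.years
    years = np.arange(y0, y1 + 1)
    fp = c.fitness_params
    section_effects = rng.normal(0.0, fp.get("section_sd", 0.0), c.n_sections)
    rec_parts, cat_rows = [], []
    for year in years:
        peak = int(round(rng.normal(c.caterpillar_mean, c.caterpillar_sd)))
        cat_rows.append({"year": year, "peak_date": peak})
        n = c.nests_per_year
        # annual mean initiation tracks the peak with error
        target_hatch = peak - c.optimum_offset
        mean_init = (
            target_hatch - (c.clutch_mean - 1) - c.onset_mean
            - c.duration_baseline + rng.normal(0.0, c.tracking_sd)
        )
        initiation = np.rint(rng.normal(mean_init, c.initiation_sd, n)).astype(int)
        clutch = np.rint(
            c.clutch_mean
            + c.clutch_initiation_slope * (initiation - mean_init)
            + rng.normal(0.0, c.clutch_sd, n)
        )
        clutch = np.clip(clutch, *c.clutch_range).astype(int)
        completion = initiation + clutch - 1
        # deviation of the no-adjustment expectation from the optimum
        dev = completion + c.onset_mean + c.duration_baseline - target_hatch
        post = (
            c.onset_mean + c.duration_baseline
            - c.compensation * dev
            + rng.normal(0.0, c.hatch_noise_sd, n)
        )
        hatch = completion + np.maximum(np.rint(post), 4).astype(int)
        section = rng.integers(1, c.n_sections + 1, n)
        hs = hatch - peak
        isyn = initiation - peak
        eta = (
            fp["intercept"]
            + fp["synchrony"] * hs
            + fp["synchrony2"] * hs**2
            + fp["clutch"] * (clutch - c.clutch_mean)
            + fp["init_synchrony"] * isyn
            + fp["init_synchrony2"] * isyn**2
            + section_effects[section - 1]
        )
        fledglings = rng.poisson(np.exp(eta))
        rec_parts.append(pd.DataFrame({
            "nest_id": [f"Y{year}N{i:03d}" for i in range(n)],
            "year": year,
            "x": rng.uniform(0, c.extent, n).round(1),
            "y": rng.uniform(0, c.extent, n).round(1),
            "initiation_date": initiation,
            "clutch_size": clutch,
            "completion_date": completion,
            "hatch_date": hatch,
            "fledglings": fledglings,
            "section": section,
        }))
    return pd.concat(rec_parts, ignore_index=True), pd.DataFrame(cat_rows)


# ---------------------------------------------------------------------------
# Bundles and CSV output
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    grid: AmbientGrid
    records: pd.DataFrame
    truth: GroundTruth
    traces: pd.DataFrame
    caterpillar: pd.DataFrame


def generate_dataset(config: GeneratorConfig, traces: bool = True) -> SyntheticDataset:
    """Run the full focal-season generator."""
    grid = generate_ambient_grid(config)
    records, truth = generate_nests(config, grid)
    trace_df = (
        generate_nest_traces(config, records, truth, grid)
        if traces else pd.DataFrame(columns=field_io.TRACE_COLUMNS)
    )
    return SyntheticDataset(
        config=config, grid=grid, records=records, truth=truth,
        traces=trace_df, caterpillar=caterpillar_table(config, truth),
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the four input CSVs plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ambient": outdir / "ambient.csv",
        "traces": outdir / "nest_traces.csv",
        "records": outdir / "nest_records.csv",
        "caterpillar": outdir / "caterpillar.csv",
        "ground_truth": outdir / "ground_truth.csv",
        "ground_truth_daily": outdir / "ground_truth_daily.csv",
    }
    ds.grid.df.to_csv(paths["ambient"], index=False, float_format="%.3f")
    ds.traces.to_csv(paths["traces"], index=False, float_format="%.3f")
    ds.records.to_csv(paths["records"], index=False)
    ds.caterpillar.to_csv(paths["caterpillar"], index=False)
    ds.truth.nests.to_csv(paths["ground_truth"], index=False, float_format="%.4f")
    ds.truth.daily.to_csv(paths["ground_truth_daily"], index=False,
                          float_format="%.4f")
    return paths
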