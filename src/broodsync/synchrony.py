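"""Hatching synchrony with the caterpillar food peak: indices, null
expectations, variance comparisons and the fitness surface.

Raw synchrony is hatch date minus the year's caterpillar peak (the median
date caterpillars descend to pupate).  An offset (default +13 days, the
optimum implied by the long-term fitness analysis) shifts the index so 0
marks optimal timing; the index is squared where an unsigned distance from
the optimum is wanted.  Null expectations remove one behavioural
adjustment at a time:

* long-term null — completion + 14 days (a fixed incubation period),
* no-onset null — completion + observed duration (onset at completion),
* no-duration null — completion + relative onset + the focal year's mean
  duration.

Reproductive success is modelled as a Poisson GLM of fledgling counts on
hatching synchrony and its square, clutch size, initiation synchrony and
its square, and woodland section; the quadratic's vertex gives the
implied optimum synchrony.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats


def build_synchrony(
    records: pd.DataFrame,
    caterpillar: pd.DataFrame,
    behaviours: pd.DataFrame | None = None,
    offset: float = 13.0,
    null_duration_longterm: float = 14.0,
    mean_duration_focal: float = 12.0,
) -> pd.DataFrame:
    """Synchrony table: observed index, squared index, and the nulls.

    Focal-year nulls (no-onset, no-duration) are filled only for nests
    present in ``behaviours``.
    """
    cat = caterpillar.set_index("year")["peak_date"]
    missing = sorted(set(records["year"].unique()) - set(cat.index))
    if missing:
        raise ValueError(f"no caterpillar peak date for year(s) {missing}")
    df = records[[
        "nest_id", "year", "initiation_date", "clutch_size",
        "completion_date", "hatch_date", "fledglings", "section",
    ]].copy()
    df["caterpillar_peak"] = df["year"].map(cat)
    df = df[df["hatch_date"].notna()].reset_index(drop=True)
    df["raw_synchrony"] = df["hatch_date"] - df["caterpillar_peak"]
    df["index"] = df["raw_synchrony"] + offset
    df["index_squared"] = df["index"] ** 2
    df["init_synchrony"] = df["initiation_date"] - df["caterpillar_peak"]
    df["null_longterm"] = (
        df["completion_date"] + null_duration_longterm
        - df["caterpillar_peak"] + offset
    )
    df["null_longterm_squared"] = df["null_longterm"] ** 2
    if behaviours is not None and not behaviours.empty:
        beh = behaviours.set_index("nest_id")
        df = df.set_index("nest_id")
        common = df.index.intersection(beh.index)
        df.loc[common, "relative_onset"] = beh.loc[common, "relative_onset"]
        df.loc[common, "duration"] = beh.loc[common, "duration"]
        df["null_no_onset"] = (
            df["completion_date"] + df["duration"] - df["caterpillar_peak"]
        )
        df["null_no_duration"] = (
            df["completion_date"] + df["relative_onset"]
            + mean_duration_focal - df["caterpillar_peak"]
        )
        df = df.reset_index()
    return df


def variance_anova(records: pd.DataFrame) -> dict:
    """Compare annual variances of initiation, completion and hatch dates.

    Per year the sample variance of each event date is computed; a linear
    model of variance on event type with year as a categorical covariate
    gives the pairwise variance differences, their SEs and p-values.
    Years with fewer than 2 hatched nests are dropped.
    """
    events = {
        "initiation": "initiation_date",
        "completion": "completion_date",
        "hatch": "hatch_date",
    }
    rows = []
    for year, grp in records.groupby("year"):
        grp = grp[grp["hatch_date"].notna()]
        if len(grp) < 2:
            continue
        for ev, col in events.items():
            rows.append({
                "year": year, "event": ev,
                "variance": float(grp[col].var(ddof=1)),
            })
    long = pd.DataFrame(rows)
    if long["year"].nunique() < 2:
        raise ValueError("variance ANOVA needs at least 2 years")
    model = smf.ols(
        "variance ~ C(event, Treatment('initiation')) + C(year)", data=long
    ).fit()
    pairs = {}
    names = model.params.index
    c_completion = [n for n in names if "completion" in n][0]
    c_hatch = [n for n in names if "hatch" in n][0]
    for label, contrast in [
        ("completion-initiation", {c_completion: 1.0}),
        ("hatch-initiation", {c_hatch: 1.0}),
        ("hatch-completion", {c_hatch: 1.0, c_completion: -1.0}),
    ]:
        L = np.zeros(len(names))
        for nm, w in contrast.items():
            L[list(names).index(nm)] = w
        tt = model.t_test(L)
        pairs[label] = {
            "difference": float(np.squeeze(tt.effect)),
            "se": float(np.squeeze(tt.sd)),
            "t": float(np.squeeze(tt.tvalue)),
            "p": float(np.squeeze(tt.pvalue)),
        }
    mean_var = long.groupby("event")["variance"].mean().to_dict()
    return {"per_year": long, "mean_variance": mean_var, "pairwise": pairs,
            "model": model}


def paired_improvement_test(observed, null) -> dict:
    """Paired t test of observed vs null synchrony (any common scale).

    Returns the signed mean difference (observed - null), t, df and p.
    """
    obs = np.asarray(observed, float)
    nul = np.asarray(null, float)
    if obs.shape != nul.shape:
        raise ValueError("paired vectors must have equal length")
    if len(obs) < 2:
        raise ValueError("need at least 2 pairs")
    res = stats.ttest_rel(obs, nul)
    return {
        "mean_difference": float(np.mean(obs - nul)),
        "t": float(res.statistic),
        "df": int(len(obs) - 1),
        "p": float(res.pvalue),
    }


def variance_ratio_test(observed, null) -> dict:
    """Two-sided F test of equality of variances, ratio var(null)/var(obs)."""
    obs = np.asarray(observed, float)
    nul = np.asarray(null, float)
    if len(obs) < 2 or len(nul) < 2:
        raise ValueError("need at least 2 observations per vector")
    v_obs = obs.var(ddof=1)
    v_nul = nul.var(ddof=1)
    if v_obs == 0 or v_nul == 0:
        raise ValueError("zero variance in one of the vectors")
    ratio = v_nul / v_obs
    dfn, dfd = len(nul) - 1, len(obs) - 1
    cdf = stats.f.cdf(ratio, dfn, dfd)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return {"ratio": float(ratio), "df": (dfn, dfd), "p": float(min(p, 1.0))}


def fit_fitness_model(synchrony: pd.DataFrame) -> dict:
    """Poisson GLM of fledgling counts on the synchrony surface.

    Uses raw (unshifted) synchrony; the optimum is reported as the vertex
    of the hatch-synchrony quadratic, defined only when the quadratic
    coefficient is negative.
    """
    df = synchrony.dropna(subset=["fledglings"]).copy()
    y = df["fledglings"].to_numpy()
    if not np.allclose(y, np.round(y)) or (y < 0).any():
        raise ValueError("fledgling counts must be non-negative integers")
    df["sync"] = df["raw_synchrony"].astype(float)
    df["sync2"] = df["sync"] ** 2
    df["isync"] = df["init_synchrony"].astype(float)
    df["isync2"] = df["isync"] ** 2
    model = smf.glm(
        "fledglings ~ sync + sync2 + clutch_size + isync + isync2 + C(section)",
        data=df, family=sm.families.Poisson(),
    ).fit()
    if not np.isfinite(model.bse).all():
        raise ValueError("fitness model is separated or singular")
    b1 = model.params["sync"]
    b2 = model.params["sync2"]
    optimum = float(-b1 / (2.0 * b2)) if b2 < 0 else None
    return {
        "params": model.params,
        "bse": model.bse,
        "pvalues": model.pvalues,
        "optimum_synchrony": optimum,
        "model": model,
    }
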