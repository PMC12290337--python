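"""Asymmetric-matching error analysis.

Observers adjust a comparison object in plain view until it matches a
target seen behind a transparent layer, choosing from a 7-step material
lattice (albedo x gloss) whose steps are perceptually equal.  The
matching error is matched minus true level: positive = overestimation.
This module summarises errors per condition/filter/material cell, relates
gloss errors to the Michelson contrast of the filtered images, and tests
whether joint (both-attributes) matching errors are predicted by the
Euclidean combination of the single-attribute errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import metelli
from .synth import MatchTrial, match_trials_to_frame

__all__ = [
    "MatchingSummary",
    "matching_errors",
    "contrast_error_table",
    "predict_condition3",
    "paired_t",
]

DEFAULT_GROUPING = ("condition", "filter_id", "target_albedo", "target_gloss", "target_shape")


@dataclass(frozen=True)
class MatchingSummary:
    """Tidy per-trial errors plus a grouped mean/SEM/n table.

    ``errors`` has one row per trial with signed ``albedo_error`` and
    ``gloss_error`` (matched - true, on the 7-step lattice, so each lies
    in [-6, +6]); ``table`` aggregates them over ``grouping``.
    """

    errors: pd.DataFrame
    table: pd.DataFrame
    grouping: tuple


def _validate_trial(t: MatchTrial) -> None:
    if t.matched_albedo is None or t.matched_gloss is None:
        raise ValueError("matching trial without matched values")
    if t.condition == "albedo_only" and t.matched_gloss != t.target_gloss:
        raise ValueError("albedo_only trial must keep gloss at its target value")
    if t.condition == "gloss_only" and t.matched_albedo != t.target_albedo:
        raise ValueError("gloss_only trial must keep albedo at its target value")


def matching_errors(trials, grouping: tuple = DEFAULT_GROUPING) -> MatchingSummary:
    """Signed matching errors and their grouped means.

    Overestimation is positive (matched level above the true level).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no matching trials")
    for t in trials:
        _validate_trial(t)
    df = match_trials_to_frame(trials)
    df["albedo_error"] = df["matched_albedo"] - df["target_albedo"]
    df["gloss_error"] = df["matched_gloss"] - df["target_gloss"]

    def _sem(s: pd.Series) -> float:
        return 0.0 if len(s) < 2 else float(s.std(ddof=1) / np.sqrt(len(s)))

    table = (
        df.groupby(list(grouping), observed=True)
        .agg(
            mean_albedo_error=("albedo_error", "mean"),
            sem_albedo_error=("albedo_error", _sem),
            mean_gloss_error=("gloss_error", "mean"),
            sem_gloss_error=("gloss_error", _sem),
            n=("gloss_error", "size"),
        )
        .reset_index()
    )
    return MatchingSummary(errors=df, table=table, grouping=tuple(grouping))


def contrast_error_table(summary: MatchingSummary, images: dict) -> pd.DataFrame:
    """Per-filter gloss-matching error against filtered-image contrast.

    `images` maps each filter level to the luminance image of the object
    behind that layer (or to a (plain, filtered) pair, in which case the
    filtered one is used).  Rows are sorted by Michelson contrast.
    """
    gdf = summary.errors[summary.errors["condition"] == "gloss_only"]
    if gdf.empty:
        raise ValueError("no gloss_only trials in the summary")
    rows = []
    for fid, grp in gdf.groupby("filter_id"):
        if fid not in images:
            raise KeyError(f"no image supplied for filter level {fid}")
        img = images[fid]
        if isinstance(img, (tuple, list)):
            img = img[-1]
        rows.append(
            {
                "filter_id": int(fid),
                "michelson_contrast": metelli.michelson_contrast(img),
                "mean_gloss_error": float(grp["gloss_error"].mean()),
                "n": int(len(grp)),
            }
        )
    return pd.DataFrame(rows).sort_values("michelson_contrast").reset_index(drop=True)


def predict_condition3(
    summary: MatchingSummary,
    by: tuple = ("target_albedo", "target_gloss", "filter_id"),
) -> tuple[pd.DataFrame, dict]:
    """Do single-attribute errors predict the joint matching error?

    For each cell of `by` the predicted displacement is the Euclidean norm
    of (mean Condition-1 albedo error, mean Condition-2 gloss error); the
    observed displacement is the Euclidean distance from the true material
    to the mean Condition-3 match.  Observed is regressed on predicted by
    OLS; the slope is tested against 1 with a one-sample t-test on its
    standard error (df = n - 2).  If joint errors are simply the vector
    sum of the single-attribute errors the slope is 1.
    """
    df = summary.errors
    cells = []
    for key, grp in df.groupby(list(by)):
        c1 = grp[grp["condition"] == "albedo_only"]
        c2 = grp[grp["condition"] == "gloss_only"]
        c3 = grp[grp["condition"] == "both"]
        if c1.empty or c2.empty or c3.empty:
            raise ValueError(f"cell {key}: all three conditions must be present")
        e1 = float(c1["albedo_error"].mean())
        e2 = float(c2["gloss_error"].mean())
        oa = float(c3["albedo_error"].mean())
        og = float(c3["gloss_error"].mean())
        rec = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        rec["predicted_distance"] = float(np.hypot(e1, e2))
        rec["observed_distance"] = float(np.hypot(oa, og))
        cells.append(rec)
    records = pd.DataFrame(cells)
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 cells for the regression")

    x = records["predicted_distance"].to_numpy()
    yv = records["observed_distance"].to_numpy()
    degenerate = bool(np.std(yv) == 0.0 or np.std(x) == 0.0)
    if degenerate:
        reg = {
            "slope": 0.0, "intercept": float(yv.mean()), "r": 0.0,
            "t_vs_1": float("nan"), "p_vs_1": float("nan"),
            "df": n - 2, "n_cells": n, "degenerate": True,
        }
        return records, reg
    ols = sm.OLS(yv, sm.add_constant(x)).fit()
    slope = float(ols.params[1])
    se = float(ols.bse[1])
    if se < 1e-10:  # perfect fit: zero residual variance
        t_vs_1 = 0.0 if abs(slope - 1.0) < 1e-8 else float(np.sign(slope - 1.0) * np.inf)
    else:
        t_vs_1 = (slope - 1.0) / se
    p_vs_1 = 2.0 * stats.t.sf(abs(t_vs_1), df=n - 2)
    reg = {
        "slope": slope,
        "intercept": float(ols.params[0]),
        "r": float(np.sign(slope) * np.sqrt(ols.rsquared)),
        "t_vs_1": float(t_vs_1),
        "p_vs_1": float(p_vs_1),
        "df": n - 2,
        "n_cells": n,
        "degenerate": False,
    }
    return records, reg


def paired_t(x, y) -> dict:
    """Classic paired t-test on x - y (df = n - 1, two-sided).

    A zero-variance difference vector is flagged degenerate: t = 0, p = 1
    when the differences are all zero, otherwise t is reported as signed
    infinity with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return {"t": 0.0, "df": n - 1, "p": 1.0, "degenerate": True}
        return {"t": float(np.sign(d.mean()) * np.inf), "df": n - 1, "p": 0.0, "degenerate": True}
    t, p = stats.ttest_rel(x, y)
    return {"t": float(t), "df": n - 1, "p": float(p), "degenerate": False}
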