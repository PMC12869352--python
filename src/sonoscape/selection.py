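"""Identify the biologically informative region of acoustic time.

For every minute of the day, the per-site ΣPMN response (averaged across
recording days, aggregated over a focal frequency range) is fitted with
all 2^7 = 128 candidate linear mixed models — one per subset of seven
predictors (land-use type, per-band background noise BGNsp, annual
precipitation, EVI, human modification, elevation, canopy height) — with
recorder hardware as a random intercept.  The minimum-AIC model wins; a
minute counts as informative when the winning subset retains land use, and
a 10-min bin is retained when *strictly more than half* of its valid
minutes are informative.

A gradient-boosted validation model with SHAP attributions (land-use
encoded as four binary indicators whose attributions are re-aggregated
into a single undirected importance) ranks the drivers of ΣPMN across the
whole day.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .lmm import DEFAULT_LAMBDA_GRID, fit_all_subsets
from .synth import LAND_USES

logger = logging.getLogger(__name__)

#: predictor set of the per-minute mixed models (time replaced by BGNsp)
LMM_PREDICTORS = ("land_use", "bgn", "annual_precipitation", "evi",
                  "human_modification", "elevation", "canopy_height")
#: predictor set of the boosted validation model (time version)
GBM_PREDICTORS = ("land_use", "time_bin", "annual_precipitation", "evi",
                  "human_modification", "elevation", "canopy_height")


@dataclass
class MinuteSelection:
    """All-subsets result for one minute of the day."""

    minute_of_day: int
    best_subset: tuple[str, ...]
    best_aic: float
    landuse_retained: bool
    n_candidates_fit: int
    valid: bool = True


def enumerate_candidates(predictors) -> list[tuple[str, ...]]:
    """All subsets of the predictors, intercept-only first, deterministic.

    Exactly seven predictors are expected (2^7 = 128 candidates); subsets
    are ordered by size and then by predictor position.
    """
    predictors = tuple(predictors)
    if len(predictors) != 7:
        raise ValueError(f"expected 7 predictors, got {len(predictors)}")
    return _all_subsets(predictors)


def _all_subsets(predictors: tuple) -> list[tuple]:
    out = []
    for k in range(len(predictors) + 1):
        out.extend(combinations(predictors, k))
    return out


def _design(data: pd.DataFrame, predictors=LMM_PREDICTORS):
    """Build (y, X, groups, column blocks) for the per-minute LMM.

    Continuous predictors are standardized (zero mean, unit variance) for
    conditioning only — AIC and subset choice are invariant to this linear
    reparameterization.  Land use enters as an all-or-nothing block of
    class indicator columns (reference level: reference_forest).
    """
    y = data["sigma_pmn"].to_numpy(float)
    cols = [np.ones(len(data))]
    blocks: dict[str, tuple[int, ...]] = {}
    j = 1
    for name in predictors:
        if name == "land_use":
            idxs = []
            for cls in LAND_USES[1:]:
                cols.append((data["land_use"] == cls).to_numpy(float))
                idxs.append(j)
                j += 1
            blocks[name] = tuple(idxs)
        else:
            v = data[name].to_numpy(float)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
            blocks[name] = (j,)
            j += 1
    x = np.column_stack(cols)
    return y, x, data["hardware"].to_numpy(), blocks


def fit_minute_models(data: pd.DataFrame,
                      predictors=LMM_PREDICTORS,
                      lambda_grid=DEFAULT_LAMBDA_GRID,
                      use_aicc: bool = False) -> MinuteSelection:
    """All-subsets AIC selection for one minute's per-site data.

    ``data`` has one row per site: sigma_pmn (the response), the seven
    predictors and the hardware version.  Returns the minimum-AIC subset
    and whether the land-use block was retained.  Candidates that fail
    numerically are skipped; if none converge the minute is marked invalid.
    """
    minute = int(data["minute_of_day"].iloc[0]) if "minute_of_day" in data else -1
    if len(data) < 10:
        raise ValueError(f"minute {minute}: need >= 10 sites, got {len(data)}")
    y, x, groups, blocks = _design(data, predictors)
    name_subsets = enumerate_candidates(predictors)
    col_subsets = [sum((blocks[nm] for nm in s), ()) for s in name_subsets]
    fits = fit_all_subsets(y, x, groups, col_subsets, lambda_grid=lambda_grid)
    n_ok = sum(f.converged for f in fits)
    if n_ok == 0:
        return MinuteSelection(minute, (), np.inf, False, 0, valid=False)
    crit = []
    n = len(data)
    for f in fits:
        a = f.aic
        if use_aicc and f.converged:
            k = f.n_params + 2
            a = a + 2.0 * k * (k + 1) / max(n - k - 1, 1)
        crit.append(a)
    best_i = int(np.argmin(crit))
    best_names = name_subsets[best_i]
    return MinuteSelection(minute_of_day=minute, best_subset=best_names,
                          best_aic=float(crit[best_i]),
                          landuse_retained="land_use" in best_names,
                          n_candidates_fit=n_ok)


def select_minutes(response: pd.DataFrame, sites: pd.DataFrame,
                   predictors=LMM_PREDICTORS, **kwargs) -> pd.DataFrame:
    """Run :func:`fit_minute_models` for every minute present in ``response``.

    ``response`` has one row per (site_id, minute_of_day) with sigma_pmn and
    bgn columns (cross-day means); site covariates come from ``sites``.
    """
    merged = response.merge(sites, on="site_id", validate="many_to_one")
    rows = []
    for minute, grp in merged.groupby("minute_of_day", sort=True):
        sel = fit_minute_models(grp, predictors=predictors, **kwargs)
        rows.append({"minute_of_day": int(minute),
                     "best_subset": "+".join(sel.best_subset) or "(intercept)",
                     "best_aic": sel.best_aic,
                     "landuse_retained": sel.landuse_retained,
                     "valid": sel.valid})
    return pd.DataFrame(rows)


def retained_bins(selections: pd.DataFrame, threshold: float = 0.5) -> list[int]:
    """10-min bins where a strict majority of valid minutes retain land use.

    A bin is kept iff strictly more than ``threshold`` of its valid minutes
    selected a model containing land use (6 of 10 qualifies, 5 of 10 does
    not).  Bins with no valid minutes are excluded and logged.
    """
    df = selections.loc[selections.get("valid", True) == True]  # noqa: E712
    if len(df) == 0:
        return []
    bins = df.assign(time_bin=df["minute_of_day"] // 10) \
             .groupby("time_bin")["landuse_retained"].mean()
    n_empty = 144 - len(set(df["minute_of_day"] // 10))
    if n_empty:
        logger.info("retained_bins: %d bins had no valid minutes", n_empty)
    return [int(b) for b, frac in bins.items() if frac > threshold]


def variable_importance(table: pd.DataFrame,
                        predictors=GBM_PREDICTORS,
                        seed: int = 0,
                        n_estimators: int = 300,
                        max_depth: int = 3,
                        learning_rate: float = 0.1) -> pd.DataFrame:
    """Boosted-model SHAP importance of the seven predictors on ΣPMN.

    Fits a gradient-boosted regressor (xgboost) of 10-min aggregated ΣPMN
    on the predictors, with land use expanded into four binary indicator
    columns.  Per-feature importance is the mean absolute SHAP attribution
    (TreeSHAP); the four land-use indicators are summed into a single
    undirected "land_use" row.  Returns importances sorted descending.
    """
    import xgboost as xgb

    y = table["sigma_pmn"].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("degenerate constant response")
    feat_cols, feat_names = [], []
    for name in predictors:
        if name == "land_use":
            for cls in LAND_USES:
                feat_cols.append((table["land_use"] == cls).to_numpy(float))
                feat_names.append(f"land_use={cls}")
        else:
            feat_cols.append(table[name].to_numpy(float))
            feat_names.append(name)
    x = np.column_stack(feat_cols)
    model = xgb.XGBRegressor(n_estimators=n_estimators, max_depth=max_depth,
                             learning_rate=learning_rate, random_state=seed,
                             n_jobs=1, tree_method="hist")
    model.fit(x, y)
    dmat = xgb.DMatrix(x, feature_names=feat_names)
    contribs = model.get_booster().predict(dmat, pred_contribs=True)[:, :-1]
    mean_abs = np.abs(contribs).mean(axis=0)
    agg: dict[str, float] = {}
    for name, v in zip(feat_names, mean_abs):
        key = "land_use" if name.startswith("land_use=") else name
        agg[key] = agg.get(key, 0.0) + float(v)
    out = pd.DataFrame({"predictor": list(agg), "importance": list(agg.values())})
    return out.sort_values("importance", ascending=False).reset_index(drop=True)
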