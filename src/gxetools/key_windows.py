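"""Key environmental factors and critical windows from a random forest.

A regression forest is trained on the dense grid of 5-day window features
(plus genotype principal components); two complementary per-feature signals
are extracted — impurity feature importance and the mean absolute SHAP
value over all samples — and arranged per factor along the window-start
axis.  The temporal profiles are smoothed with a centered 5-window moving
average, and windows whose smoothed importance AND smoothed mean |SHAP|
both reach 10% of the respective global maximum are declared significant.
Overlapping or adjacent significant windows of the same factor merge into
one critical period.

Genotype principal components are used as model covariates but are never
eligible as environmental key windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .env_features import is_window_key, parse_feature_key
from .treeshap import forest_shap_values

RF_DEFAULTS = dict(
    n_estimators=500,
    criterion="squared_error",
    max_features=0.3,
    min_samples_leaf=5,
    n_jobs=1,
)


def fit_rf_for_trait(
    X: pd.DataFrame,
    y: pd.Series,
    n_estimators: int = 500,
    seed: int = 0,
    **rf_params,
) -> tuple[RandomForestRegressor, float]:
    """Fit the attribution forest; returns (model, training R2).

    Training R2 is reported for transparency — forests overfit their
    training samples, so it exceeds any cross-environment estimate and is
    not a measure of predictive ability.
    """
    if X.shape[0] < 50:
        raise ValueError("need at least 50 samples to fit the forest")
    values = X.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("feature matrix contains non-numeric columns")
    kw = dict(RF_DEFAULTS)
    kw["n_estimators"] = n_estimators
    kw.update(rf_params)
    model = RandomForestRegressor(random_state=seed, **kw)
    model.fit(values, np.asarray(y, dtype=float))
    train_r2 = float(model.score(values, np.asarray(y, dtype=float)))
    return model, train_r2


@dataclass
class WindowProfiles:
    """Temporal attribution profiles for one trait.

    ``env_profiles`` has one row per window feature (factor, start, end)
    with raw and smoothed importance and mean-|SHAP| columns, ordered by
    factor then start; ``other_importance`` covers non-window covariates
    (genotype PCs).  ``shap_values``/``expected_value`` retain the full
    per-sample attributions for dependence exports.
    """

    trait: str
    env_profiles: pd.DataFrame
    other_importance: pd.Series
    shap_values: pd.DataFrame
    expected_value: float
    smooth_span: int | None = None


def attribution_profiles(
    model: RandomForestRegressor, X: pd.DataFrame, trait: str = "trait"
) -> WindowProfiles:
    """Per-feature importance and mean |SHAP|, grouped by factor over time.

    Impurity importances come normalized (they sum to one over all
    features); mean absolute SHAP values are in trait units.  Signed mean
    SHAP is kept as a direction-of-effect indicator.
    """
    if getattr(model, "n_features_in_", None) != X.shape[1]:
        raise ValueError("model was not fitted on this feature matrix")
    importances = pd.Series(model.feature_importances_, index=X.columns)
    phi, base = forest_shap_values(model, X)
    shap_df = pd.DataFrame(phi, index=X.index, columns=X.columns)

    rows = []
    other = {}
    for col in X.columns:
        if is_window_key(col):
            factor, start, end = parse_feature_key(col)
            rows.append(
                {
                    "key": col,
                    "factor": factor,
                    "start": start,
                    "end": end,
                    "importance": importances[col],
                    "mean_abs_shap": float(shap_df[col].abs().mean()),
                    "mean_shap": float(shap_df[col].mean()),
                }
            )
        else:
            other[col] = importances[col]
    if not rows:
        raise ValueError("no environment window columns in the feature matrix")
    env = pd.DataFrame(rows).sort_values(["factor", "start"]).reset_index(drop=True)
    return WindowProfiles(
        trait=trait,
        env_profiles=env,
        other_importance=pd.Series(other, dtype=float),
        shap_values=shap_df,
        expected_value=base,
    )


def smooth_profile(values, span: int = 5) -> np.ndarray:
    """Centered moving average along the ordered window sequence.

    At the edges the average shrinks to the available neighbors (it is
    never zero-padded), so a constant profile is returned unchanged.
    ``span`` must be odd so the window is symmetric.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be odd and >= 1")
    s = pd.Series(np.asarray(values, dtype=float))
    return s.rolling(window=span, center=True, min_periods=1).mean().to_numpy()


def smooth_profiles(profiles: WindowProfiles, span: int = 5) -> WindowProfiles:
    """Add smoothed importance/mean-|SHAP| columns (per factor, ordered by start)."""
    env = profiles.env_profiles.copy()
    for col in ("importance", "mean_abs_shap"):
        env[f"{col}_smooth"] = (
            env.groupby("factor", sort=False)[col]
            .transform(lambda v: smooth_profile(v.to_numpy(), span))
        )
    return WindowProfiles(
        trait=profiles.trait,
        env_profiles=env,
        other_importance=profiles.other_importance,
        shap_values=profiles.shap_values,
        expected_value=profiles.expected_value,
        smooth_span=span,
    )


@dataclass
class KeyWindowSet:
    """Merged critical periods per factor for one trait.

    ``entries`` rows: factor, start_day, end_day, peak_importance,
    peak_mean_abs_shap, n_windows; ranked by peak smoothed mean |SHAP|.
    ``selected_keys`` lists the individual significant window columns that
    produced the periods (the feature subset used for model re-training).
    """

    trait: str
    entries: pd.DataFrame
    selected_keys: list[str]
    tau: float
    combine: str


def select_key_windows(
    profiles: WindowProfiles,
    tau: float = 0.10,
    combine: str = "and",
    span: int = 5,
) -> KeyWindowSet:
    """Threshold the smoothed profiles and merge windows into key periods.

    A window is significant when its smoothed importance >= tau * (global
    max smoothed importance) and its smoothed mean |SHAP| >= tau * (global
    max smoothed mean |SHAP|); ``combine`` may relax this to "or",
    "importance" or "shap".  The thresholds are global across all
    environmental features, not per factor.  Overlapping or adjacent
    significant windows of one factor merge into a single period spanning
    their union.
    """
    if combine not in {"and", "or", "importance", "shap"}:
        raise ValueError(f"unknown combine rule {combine!r}")
    if profiles.smooth_span is None:
        profiles = smooth_profiles(profiles, span)
    env = profiles.env_profiles
    max_imp = env["importance_smooth"].max()
    max_shap = env["mean_abs_shap_smooth"].max()
    if max_imp <= 0 and max_shap <= 0:
        warnings.warn("all attribution profiles are zero; empty key-window set",
                      stacklevel=2)
        empty = pd.DataFrame(
            columns=["factor", "start_day", "end_day",
                     "peak_importance", "peak_mean_abs_shap", "n_windows"]
        )
        return KeyWindowSet(profiles.trait, empty, [], tau, combine)

    sig_imp = env["importance_smooth"] >= tau * max_imp
    sig_shap = env["mean_abs_shap_smooth"] >= tau * max_shap
    significant = {
        "and": sig_imp & sig_shap,
        "or": sig_imp | sig_shap,
        "importance": sig_imp,
        "shap": sig_shap,
    }[combine]

    entries = []
    selected = []
    for factor, grp in env[significant].groupby("factor", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for _, row in grp.iterrows():
            selected.append(row["key"])
            if cur is not None and row["start"] <= cur["end_day"] + 1:
                cur["end_day"] = max(cur["end_day"], int(row["end"]))
                cur["peak_importance"] = max(cur["peak_importance"],
                                             row["importance_smooth"])
                cur["peak_mean_abs_shap"] = max(cur["peak_mean_abs_shap"],
                                                row["mean_abs_shap_smooth"])
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    entries.append(cur)
                cur = {
                    "factor": factor,
                    "start_day": int(row["start"]),
                    "end_day": int(row["end"]),
                    "peak_importance": float(row["importance_smooth"]),
                    "peak_mean_abs_shap": float(row["mean_abs_shap_smooth"]),
                    "n_windows": 1,
                }
        if cur is not None:
            entries.append(cur)
    table = pd.DataFrame(
        entries,
        columns=["factor", "start_day", "end_day",
                 "peak_importance", "peak_mean_abs_shap", "n_windows"],
    ).sort_values("peak_mean_abs_shap", ascending=False).reset_index(drop=True)
    return KeyWindowSet(profiles.trait, table, selected, tau, combine)


def selected_feature_matrix(
    X: pd.DataFrame, key_set: KeyWindowSet, keep_non_window: bool = True
) -> pd.DataFrame:
    """Subset the feature matrix to the selected windows (plus PCs)."""
    cols = [c for c in X.columns if c in set(key_set.selected_keys)]
    if keep_non_window:
        cols += [c for c in X.columns if not is_window_key(c)]
    if not cols:
        raise ValueError("selection produced an empty feature set")
    return X[cols]


def shap_dependence_export(
    model: RandomForestRegressor,
    X: pd.DataFrame,
    feature_key: str,
    profiles: WindowProfiles | None = None,
) -> pd.DataFrame:
    """Per-sample (feature value, SHAP attribution) pairs for one feature.

    Passing precomputed ``profiles`` reuses their SHAP values; otherwise
    attributions are recomputed from the model.
    """
    if feature_key not in X.columns:
        raise KeyError(f"unknown feature {feature_key!r}")
    if profiles is not None:
        shap_col = profiles.shap_values[feature_key]
    else:
        phi, _ = forest_shap_values(model, X)
        shap_col = pd.Series(
            phi[:, X.columns.get_loc(feature_key)], index=X.index
        )
    return pd.DataFrame(
        {"value": X[feature_key].to_numpy(), "shap": shap_col.to_numpy()},
        index=X.index,
    )
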