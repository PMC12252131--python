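"""Derived environmental indices and window-aggregated feature matrices.

Daily weather records (eight base variables) are expanded into five derived
thermal/photothermal indices, giving 13 environmental factors per day.  The
factors are then aggregated into sliding-window means — the inputs both to
the exhaustive correlation scan and to the random-forest feature matrix —
and marker data are reduced to genotype principal components.

Factor units: temperatures in degC, pcp in mm/day, dh in sunshine hours/day,
rhmean in %, radn in MJ/m2/day, wsmean in m/s; gdd in degC day, dtr in degC,
prdtr in mm/degC, ptq in MJ m-2 (degC day)-1, ptt in degC day hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Base temperature for growing degree days (degC).
T_BASE = 10.0

#: The eight base weather variables recorded per day.
BASE_VARS = ["tmax", "tmin", "tmean", "pcp", "dh", "rhmean", "radn", "wsmean"]

#: The five indices derived from the base variables.
DERIVED_VARS = ["gdd", "dtr", "prdtr", "ptq", "ptt"]

#: All 13 scan factors, in canonical order.
FACTORS = BASE_VARS + DERIVED_VARS

WEATHER_COLUMNS = ["env_id", "day"] + BASE_VARS


class WeatherValidationError(ValueError):
    """A daily weather table violates its invariants."""


def validate_weather(weather: pd.DataFrame) -> None:
    """Check daily-weather invariants, naming the offending environment/day.

    Requires: all base columns present; per environment, days consecutive
    from 1; tmin <= tmean <= tmax; rhmean in [0, 100]; pcp, dh, radn,
    wsmean >= 0; all values finite.
    """
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise WeatherValidationError(f"weather table missing columns: {missing}")
    num = weather[BASE_VARS]
    if not np.isfinite(num.to_numpy(dtype=float)).all():
        bad = weather.loc[~np.isfinite(num).all(axis=1)].iloc[0]
        raise WeatherValidationError(
            f"non-finite weather value (env_id={bad['env_id']}, day={bad['day']})"
        )
    for env_id, grp in weather.groupby("env_id", sort=False):
        days = grp["day"].to_numpy()
        if not np.array_equal(days, np.arange(1, len(days) + 1)):
            raise WeatherValidationError(
                f"days not consecutive from 1 in env_id={env_id}"
            )
        for cond, msg in [
            (grp["tmin"] > grp["tmean"], "tmin > tmean"),
            (grp["tmean"] > grp["tmax"], "tmean > tmax"),
            ((grp["rhmean"] < 0) | (grp["rhmean"] > 100), "rhmean outside [0, 100]"),
            ((grp[["pcp", "dh", "radn", "wsmean"]] < 0).any(axis=1), "negative value"),
        ]:
            if cond.any():
                day = int(grp.loc[cond, "day"].iloc[0])
                raise WeatherValidationError(f"{msg} (env_id={env_id}, day={day})")


def derive_daily_indices(weather: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Compute the five derived indices per day.

    gdd = max(0, (tmax + tmin)/2 - 10); dtr = tmax - tmin;
    prdtr = pcp/dtr (0 when dtr <= 0); ptq = radn/gdd (0 when gdd <= 0);
    ptt = gdd * dh.

    The degree-day formula is clamped at zero (negative thermal time is
    non-physical) and the two daily ratios fall back to zero when their
    denominator vanishes, so every value is finite.

    Returns a frame with env_id, day and one column per derived index.
    """
    if validate:
        validate_weather(weather)
    out = weather[["env_id", "day"]].copy()
    gdd = np.maximum(0.0, (weather["tmax"] + weather["tmin"]) / 2.0 - T_BASE)
    dtr = weather["tmax"] - weather["tmin"]
    with np.errstate(divide="ignore", invalid="ignore"):
        prdtr = np.where(dtr > 0, weather["pcp"] / dtr, 0.0)
        ptq = np.where(gdd > 0, weather["radn"] / gdd, 0.0)
    out["gdd"] = gdd
    out["dtr"] = dtr
    out["prdtr"] = prdtr
    out["ptq"] = ptq
    out["ptt"] = gdd * weather["dh"]
    return out


def daily_factor_table(weather: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Full 13-factor daily table: the 8 base variables plus 5 derived indices."""
    derived = derive_daily_indices(weather, validate=validate)
    out = weather[["env_id", "day"] + BASE_VARS].merge(
        derived, on=["env_id", "day"], validate="one_to_one"
    )
    return out[["env_id", "day"] + FACTORS]


def aggregate_window(series: pd.Series, start: int, end: int) -> float:
    """Arithmetic mean of a day-indexed series over the closed window start..end.

    Days are 1-based days after planting.  The mean (rather than the sum)
    keeps windows of different lengths comparable; cumulative readings such
    as total thermal time are recoverable as mean x length.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid window ({start}, {end})")
    idx = series.index
    if start not in idx or end not in idx:
        raise ValueError(
            f"window ({start}, {end}) outside day range {idx.min()}..{idx.max()}"
        )
    return float(series.loc[start:end].mean())


def feature_key(factor: str, start: int, end: int) -> str:
    """Column key '<factor>_<start>_<end>' for a window aggregate."""
    return f"{factor}_{start}_{end}"


def parse_feature_key(key: str) -> tuple[str, int, int]:
    """Invert :func:`feature_key`; raises ValueError for non-window keys."""
    parts = key.rsplit("_", 2)
    if len(parts) != 3 or parts[0] not in FACTORS:
        raise ValueError(f"not a window feature key: {key!r}")
    factor, start, end = parts[0], int(parts[1]), int(parts[2])
    if start < 1 or end < start:
        raise ValueError(f"not a window feature key: {key!r}")
    return factor, start, end


def is_window_key(key: str) -> bool:
    try:
        parse_feature_key(key)
        return True
    except (ValueError, TypeError):
        return False


def _env_day_matrix(factor_table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Pivot one factor to an environments x days matrix, checking day ranges."""
    mat = factor_table.pivot(index="env_id", columns="day", values=factor)
    if mat.isna().any().any():
        raise ValueError("environments do not share a common day range")
    return mat.sort_index(axis=1)


def build_window_features(
    factor_table: pd.DataFrame,
    window_size: int = 5,
    stride: int = 1,
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """Dense grid of fixed-size window means, one row per environment.

    For a 150-day season with the default 5-day windows and stride 1 this
    yields 146 windows per factor, columns keyed ``<factor>_<start>_<end>``.
    """
    if window_size < 1 or stride < 1:
        raise ValueError("window_size and stride must be >= 1")
    factors = list(factors) if factors is not None else FACTORS
    blocks = []
    for factor in factors:
        mat = _env_day_matrix(factor_table, factor)
        n_days = mat.shape[1]
        vals = mat.to_numpy()
        csum = np.concatenate(
            [np.zeros((vals.shape[0], 1)), np.cumsum(vals, axis=1)], axis=1
        )
        starts = np.arange(1, n_days - window_size + 2, stride)
        cols = {}
        for s in starts:
            e = s + window_size - 1
            cols[feature_key(factor, int(s), int(e))] = (
                csum[:, e] - csum[:, s - 1]
            ) / window_size
        blocks.append(pd.DataFrame(cols, index=mat.index))
    out = pd.concat(blocks, axis=1)
    out.index.name = "env_id"
    return out


@dataclass
class GenotypePCs:
    """Principal-component summary of a marker matrix.

    ``scores`` holds PC1..PCk per genotype where k is the smallest count of
    components whose cumulative explained fraction exceeds the threshold;
    ``explained_fraction`` covers every component, not just the retained k.
    """

    scores: pd.DataFrame
    explained_fraction: np.ndarray
    k: int
    cum_threshold: float = field(default=0.90)

    @property
    def cumulative_explained(self) -> float:
        return float(self.explained_fraction[: self.k].sum())


def genotype_pcs(genotypes: pd.DataFrame, cum_threshold: float = 0.90) -> GenotypePCs:
    """Column-centered PCA of a biallelic marker matrix (rows = genotypes).

    Markers are centered but not scaled ({0,1} coding shares a common
    scale).  k is the smallest component count whose cumulative explained
    fraction strictly exceeds ``cum_threshold``.  Loadings follow a
    deterministic sign convention: each component is flipped so that its
    largest-magnitude loading is positive.
    """
    X = genotypes.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genotypes for PCA")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("degenerate input: all markers are constant")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| element of each PC made positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    explained = s**2 / np.sum(s**2)
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, cum_threshold, side="right") + 1)
    k = min(k, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k],
        index=genotypes.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    scores.index.name = genotypes.index.name or "genotype_id"
    return GenotypePCs(
        scores=scores,
        explained_fraction=explained,
        k=k,
        cum_threshold=cum_threshold,
    )
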