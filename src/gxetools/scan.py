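"""Exhaustive sliding-window correlation scan (CERIS-style).

For every environmental factor and every (start day, duration) window, the
factor is averaged over the window in each environment and the resulting
per-environment values are correlated with the per-environment population
phenotype means.  Windows with high |r| (equivalently high -log10 p) locate
the phenological periods in which an environmental variable tracks the
trait across environments.

Default grid: start days 1..145, durations 5..150, window ends bounded only
by the last recorded day (so late starts admit windows running to the end
of the season).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .env_features import FACTORS, _env_day_matrix

_P_FLOOR = np.finfo(float).tiny


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-based p-value.

    p comes from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, the
    exact sampling distribution under bivariate normality.  |r| = 1 returns
    the numeric p floor rather than 0 so -log10(p) stays finite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need n >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip(xc @ yc / np.sqrt(sx * sy), -1.0, 1.0))
    p = _p_from_r(np.array([r]), n)[0]
    return r, float(p)


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(r) >= 1.0, _P_FLOOR, p)
    return np.maximum(p, _P_FLOOR)


def pearson_perm_p(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Permutation alternative to the t-based p-value.

    Two-sided randomization p: the fraction of random re-pairings whose |r|
    reaches the observed |r|, with the add-one estimator (1+k)/(1+B).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    r, _ = pearson_with_p(x, y)
    xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
    yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
    perms = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    r_null = yc[perms] @ xc
    k = int((np.abs(r_null) >= abs(r) - 1e-12).sum())
    return r, (1 + k) / (1 + n_perm)


def window_grid(
    n_days: int,
    start_min: int = 1,
    start_max: int = 145,
    dur_min: int = 5,
    dur_max: int = 150,
) -> np.ndarray:
    """All valid (start, duration) pairs with end = start + duration - 1 <= n_days."""
    pairs = [
        (s, d)
        for s in range(start_min, min(start_max, n_days) + 1)
        for d in range(dur_min, dur_max + 1)
        if s + d - 1 <= n_days
    ]
    return np.asarray(pairs, dtype=int)


def grid_size(
    n_days: int,
    start_min: int = 1,
    start_max: int = 145,
    dur_min: int = 5,
    dur_max: int = 150,
) -> int:
    """Closed-form count of valid windows per factor."""
    total = 0
    for s in range(start_min, min(start_max, n_days) + 1):
        total += max(0, min(dur_max, n_days - s + 1) - dur_min + 1)
    return total


@dataclass
class WindowScanResult:
    """Complete grid of window scores for one trait.

    ``scores`` has one row per (factor, start, duration) with columns r, p
    and neg_log_p (base-10).  Windows whose per-environment means are
    constant have undefined correlation and carry NaN.
    """

    trait: str
    scores: pd.DataFrame
    n_envs: int
    start_range: tuple[int, int]
    duration_range: tuple[int, int]


def scan_windows(
    factor_table: pd.DataFrame,
    env_phenotype_means: pd.Series,
    trait: str = "trait",
    start_min: int = 1,
    start_max: int = 145,
    dur_min: int = 5,
    dur_max: int = 150,
    factors: list[str] | None = None,
) -> WindowScanResult:
    """Score every (factor, start, duration) window against the trait means.

    ``env_phenotype_means`` is the per-environment population mean (over
    genotypes and replicates).  Environments present in one input but not
    the other raise an alignment error naming them.
    """
    factors = list(factors) if factors is not None else FACTORS
    weather_envs = set(factor_table["env_id"])
    pheno_envs = set(env_phenotype_means.index)
    if weather_envs != pheno_envs:
        raise ValueError(
            "environment mismatch between weather and phenotypes: "
            f"weather-only={sorted(weather_envs - pheno_envs)}, "
            f"phenotype-only={sorted(pheno_envs - weather_envs)}"
        )
    if len(pheno_envs) < 3:
        raise ValueError("need >= 3 environments to correlate")

    first = _env_day_matrix(factor_table, factors[0])
    env_order = first.index
    y = env_phenotype_means.reindex(env_order).to_numpy(dtype=float)
    yc = y - y.mean()
    sy = float(yc @ yc)
    if sy == 0:
        raise ValueError("environment phenotype means are constant")
    yn = yc / np.sqrt(sy)
    n_envs = len(y)
    n_days = first.shape[1]
    pairs = window_grid(n_days, start_min, start_max, dur_min, dur_max)
    starts, durs = pairs[:, 0], pairs[:, 1]
    ends = starts + durs - 1

    frames = []
    for factor in factors:
        mat = _env_day_matrix(factor_table, factor).loc[env_order].to_numpy()
        csum = np.concatenate(
            [np.zeros((n_envs, 1)), np.cumsum(mat, axis=1)], axis=1
        )
        W = (csum[:, ends] - csum[:, starts - 1]) / durs  # envs x windows
        Wc = W - W.mean(axis=0, keepdims=True)
        ssw = (Wc**2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((Wc * yn[:, None]).sum(axis=0) / np.sqrt(ssw), -1.0, 1.0)
        r[ssw == 0] = np.nan
        p = np.where(np.isnan(r), np.nan, _p_from_r(np.nan_to_num(r), n_envs))
        frames.append(
            pd.DataFrame(
                {
                    "factor": factor,
                    "start": starts,
                    "end": ends,
                    "duration": durs,
                    "r": r,
                    "p": p,
                    "neg_log_p": -np.log10(p),
                }
            )
        )
    scores = pd.concat(frames, ignore_index=True)
    return WindowScanResult(
        trait=trait,
        scores=scores,
        n_envs=n_envs,
        start_range=(start_min, start_max),
        duration_range=(dur_min, dur_max),
    )


def top_windows(
    result: WindowScanResult, per_factor: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank windows by |r| (ties: larger -log10 p, earlier start, shorter duration).

    Returns (per-factor top windows, complete global ranking); windows with
    undefined correlation are dropped.
    """
    df = result.scores.dropna(subset=["r"]).copy()
    if df.empty:
        raise ValueError("empty scan result")
    df["abs_r"] = df["r"].abs()
    df = df.sort_values(
        ["abs_r", "neg_log_p", "start", "duration"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    best = df.groupby("factor", sort=False).head(per_factor).reset_index(drop=True)
    return best, df
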