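"""Phenotypic variance decomposition for multi-environment trials.

Three complementary views of genotype-by-environment structure:

* a fixed-effects ANOVA over the strata Genotype, ENVs, Rep, Genotype:ENVs
  and Residuals, reporting each stratum's share of the total sum of squares
  as "variance %" (the convention used when trial tables print percentages
  that add to 100);
* Finlay-Wilkinson joint regression: each genotype's environment means are
  regressed on the environment effects, the slope (1 + b_i) measuring
  phenotypic plasticity;
* the GGE model Y_ij = mu + beta_j + sum_k lambda_k gamma_ik delta_jk via a
  singular value decomposition of the environment-centered mean table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STRATA = ["Genotype", "ENVs", "Rep", "Genotype:ENVs", "Residuals"]


class DegenerateDesignError(ValueError):
    """The design leaves a stratum with zero degrees of freedom."""


def _check_phenotypes(phenotypes: pd.DataFrame, trait: str) -> pd.DataFrame:
    for col in ("genotype_id", "env_id"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    if trait not in phenotypes.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")
    df = phenotypes[["genotype_id", "env_id"]].copy()
    if "rep" in phenotypes.columns:
        df["rep"] = phenotypes["rep"]
    df["y"] = pd.to_numeric(phenotypes[trait])
    if not np.isfinite(df["y"]).all():
        raise ValueError(f"non-finite values in trait {trait!r}")
    return df


def _is_balanced(df: pd.DataFrame) -> bool:
    """True when every genotype x environment x rep combination occurs once."""
    if "rep" not in df.columns:
        return False
    counts = df.groupby(["genotype_id", "env_id", "rep"], sort=False).size()
    ng = df["genotype_id"].nunique()
    ne = df["env_id"].nunique()
    nr = df["rep"].nunique()
    return len(counts) == ng * ne * nr and (counts == 1).all()


def anova_decompose(phenotypes: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Fixed-effects ANOVA table for one trait.

    Strata are Genotype, ENVs, Rep (a crossed main effect: one replicate
    blocking level shared across environments), Genotype:ENVs, and
    Residuals.  Sums of squares are sequential in that fixed order; for a
    balanced design they equal the classical main-effect/interaction sums
    of squares computed from group means, and the implementation uses those
    closed forms.  Unbalanced data fall back to a sequential (type I) least
    squares fit with a warning.

    Returns a frame indexed by stratum with Df, SS, MS, F, p and
    variance_pct = 100 * SS / total SS.
    """
    df = _check_phenotypes(phenotypes, trait)
    if "rep" not in df.columns:
        raise ValueError("ANOVA requires a 'rep' column")
    ng = df["genotype_id"].nunique()
    ne = df["env_id"].nunique()
    nr = df["rep"].nunique()
    if ng < 2 or ne < 2:
        raise DegenerateDesignError("need >= 2 genotypes and >= 2 environments")
    if nr < 2:
        raise DegenerateDesignError("Rep stratum has zero degrees of freedom")

    if _is_balanced(df):
        ss, dof = _balanced_ss(df, ng, ne, nr)
    else:
        warnings.warn(
            "unbalanced design: using sequential (type I) sums of squares "
            "in the order Genotype, ENVs, Rep, Genotype:ENVs",
            stacklevel=2,
        )
        ss, dof = _sequential_ss(df)
    if dof["Residuals"] <= 0:
        raise DegenerateDesignError("no residual degrees of freedom")
    return anova_from_ss(ss, dof)


def _balanced_ss(df: pd.DataFrame, ng: int, ne: int, nr: int):
    y = df["y"].to_numpy()
    grand = y.mean()
    gm = df.groupby("genotype_id")["y"].mean()
    em = df.groupby("env_id")["y"].mean()
    rm = df.groupby("rep")["y"].mean()
    cell = df.groupby(["genotype_id", "env_id"])["y"].mean().unstack()
    inter = cell.sub(gm, axis=0).sub(em, axis=1) + grand
    ss = {
        "Genotype": ne * nr * float(((gm - grand) ** 2).sum()),
        "ENVs": ng * nr * float(((em - grand) ** 2).sum()),
        "Rep": ng * ne * float(((rm - grand) ** 2).sum()),
        "Genotype:ENVs": nr * float((inter**2).to_numpy().sum()),
    }
    total = float(((y - grand) ** 2).sum())
    ss["Residuals"] = total - sum(ss.values())
    n = len(y)
    dof = {
        "Genotype": ng - 1,
        "ENVs": ne - 1,
        "Rep": nr - 1,
        "Genotype:ENVs": (ng - 1) * (ne - 1),
    }
    dof["Residuals"] = n - 1 - sum(dof.values())
    return ss, dof


def _sequential_ss(df: pd.DataFrame):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fit = smf.ols(
        "y ~ C(genotype_id) + C(env_id) + C(rep) + C(genotype_id):C(env_id)", df
    ).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    key = {
        "C(genotype_id)": "Genotype",
        "C(env_id)": "ENVs",
        "C(rep)": "Rep",
        "C(genotype_id):C(env_id)": "Genotype:ENVs",
        "Residual": "Residuals",
    }
    ss = {key[k]: float(tab.loc[k, "sum_sq"]) for k in tab.index}
    dof = {key[k]: int(tab.loc[k, "df"]) for k in tab.index}
    return ss, dof


def anova_from_ss(ss: dict[str, float], dof: dict[str, int]) -> pd.DataFrame:
    """Assemble the ANOVA table from per-stratum SS and Df.

    Useful both internally and for re-deriving the printed columns (MS, F,
    p, variance %) of a published table from its printed SS and Df.
    """
    order = [s for s in STRATA if s in ss]
    total_ss = sum(ss.values())
    ms = {s: ss[s] / dof[s] if dof[s] > 0 else np.nan for s in order}
    ms_res = ms["Residuals"]
    out = pd.DataFrame(index=pd.Index(order, name="stratum"))
    out["Df"] = [dof[s] for s in order]
    out["SS"] = [ss[s] for s in order]
    out["MS"] = [ms[s] for s in order]
    out["F"] = [
        ms[s] / ms_res if s != "Residuals" and ms_res > 0 else np.nan for s in order
    ]
    out["p"] = [
        float(stats.f.sf(out.loc[s, "F"], dof[s], dof["Residuals"]))
        if s != "Residuals" and np.isfinite(out.loc[s, "F"])
        else np.nan
        for s in order
    ]
    if total_ss > 0:
        out["variance_pct"] = 100.0 * out["SS"] / total_ss
    else:
        warnings.warn("total SS is zero; variance percentages set to 0", stacklevel=2)
        out["variance_pct"] = 0.0
    return out


@dataclass
class FWResult:
    """Finlay-Wilkinson joint-regression fits.

    ``fits`` is indexed by genotype with columns intercept, slope, r2 and
    n_envs; ``env_effects`` are the centered environment means E_j used as
    the regressor (they sum to zero).
    """

    fits: pd.DataFrame
    env_effects: pd.Series
    trait: str


def fw_regression(phenotypes: pd.DataFrame, trait: str) -> FWResult:
    """Regress each genotype's environment means on the environment effects.

    E_j is the environment mean minus the grand mean of environment means.
    Genotypes observed in fewer than 3 environments are excluded with a
    warning.  A genotype whose values track the environment means exactly
    has slope 1 with zero residual; a genotype constant across environments
    has slope 0.
    """
    df = _check_phenotypes(phenotypes, trait)
    cell = df.groupby(["genotype_id", "env_id"], sort=False)["y"].mean().unstack()
    env_means = cell.mean(axis=0)
    E = env_means - env_means.mean()

    n_envs = cell.notna().sum(axis=1)
    keep = n_envs >= 3
    if (~keep).any():
        warnings.warn(
            f"excluded {int((~keep).sum())} genotype(s) observed in <3 environments",
            stacklevel=2,
        )
    cell = cell.loc[keep]

    x = E.to_numpy()
    fits = {}
    complete = cell.notna().all(axis=1)
    if complete.any():
        Y = cell.loc[complete].to_numpy()
        xc = x - x.mean()
        sxx = float((xc**2).sum())
        slope = (Y - Y.mean(axis=1, keepdims=True)) @ xc / sxx
        intercept = Y.mean(axis=1) - slope * x.mean()
        resid = Y - (intercept[:, None] + np.outer(slope, x))
        sst = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(sst > 0, 1.0 - (resid**2).sum(axis=1) / sst, np.nan)
        for gid, a, b, r in zip(cell.index[complete], intercept, slope, r2):
            fits[gid] = (a, b, r, len(x))
    for gid in cell.index[~complete]:
        row = cell.loc[gid]
        mask = row.notna().to_numpy()
        xi, yi = x[mask], row.to_numpy()[mask]
        b, a = np.polyfit(xi, yi, 1)
        sst = float(((yi - yi.mean()) ** 2).sum())
        sse = float(((yi - (a + b * xi)) ** 2).sum())
        fits[gid] = (a, b, 1.0 - sse / sst if sst > 0 else np.nan, int(mask.sum()))

    out = pd.DataFrame.from_dict(
        fits, orient="index", columns=["intercept", "slope", "r2", "n_envs"]
    ).reindex(cell.index)
    out.index.name = "genotype_id"
    return FWResult(fits=out, env_effects=E.rename("E_j"), trait=trait)


@dataclass
class GGEDecomposition:
    """SVD of the environment-centered genotype x environment mean table.

    Scores carry the symmetric scaling sqrt(lambda_k) on each side, so the
    centered table is reconstructed by genotype_scores @ env_scores.T when
    all axes are kept.  ``explained_fraction`` spans every axis (it sums to
    one); ``genotype_scores``/``env_scores`` are truncated to ``n_axes``.
    """

    mu: float
    beta: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame
    env_scores: pd.DataFrame
    explained_fraction: np.ndarray
    n_axes: int
    trait: str
    _U: np.ndarray
    _Vt: np.ndarray

    def reconstruct(self, n_axes: int | None = None) -> pd.DataFrame:
        """Cell means rebuilt from mu + beta_j + the first n_axes terms."""
        k = len(self.singular_values) if n_axes is None else n_axes
        M = (self._U[:, :k] * self.singular_values[:k]) @ self._Vt[:k]
        M = M + self.mu + self.beta.to_numpy()[None, :]
        return pd.DataFrame(
            M, index=self.genotype_scores.index, columns=self.env_scores.index
        )


def gge_biplot(phenotypes: pd.DataFrame, trait: str, n_axes: int = 2) -> GGEDecomposition:
    """GGE decomposition of the genotype x environment mean table.

    Columns (environments) are centered — removing mu + beta_j and leaving
    genotype main effect plus interaction — and the centered table is
    decomposed by SVD.  Axis k explains lambda_k^2 / sum(lambda^2) of the
    genotype + G x E variation.  Missing cells raise (impute upstream).
    """
    df = _check_phenotypes(phenotypes, trait)
    cell = df.groupby(["genotype_id", "env_id"], sort=False)["y"].mean().unstack()
    if cell.isna().any().any():
        raise ValueError(
            "genotype x environment mean table has missing cells; "
            "GGE requires complete means (impute upstream)"
        )
    M = cell.to_numpy()
    env_means = M.mean(axis=0)
    mu = float(env_means.mean())
    beta = pd.Series(env_means - mu, index=cell.columns, name="beta")
    centered = M - env_means[None, :]
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    total = float((s**2).sum())
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    k = min(n_axes, len(s))
    cols = [f"Axis{i + 1}" for i in range(k)]
    sqrt_s = np.sqrt(s[:k])
    return GGEDecomposition(
        mu=mu,
        beta=beta,
        singular_values=s,
        genotype_scores=pd.DataFrame(U[:, :k] * sqrt_s, index=cell.index, columns=cols),
        env_scores=pd.DataFrame(Vt[:k].T * sqrt_s, index=cell.columns, columns=cols),
        explained_fraction=explained,
        n_axes=k,
        trait=trait,
        _U=U,
        _Vt=Vt,
    )
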