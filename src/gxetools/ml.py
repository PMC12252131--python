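"""Cross-environment evaluation of pluggable regression models.

Environments are partitioned into folds (by default 7 folds of 2
environments for a 14-environment trial); each fold's environments are held
out in turn, the model is trained on the samples from all remaining
environments, and the held-out predictions from every fold are pooled
before computing metrics — PCC, R2 and MSE are properties of the combined
prediction vector, not fold averages.

Samples are genotype x environment observations, replicate-averaged by
default; their features are environment window aggregates (identical for
all genotypes in an environment) plus genotype principal components
(identical across environments), so no phenotype information can leak from
a held-out environment into training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .env_features import is_window_key


@dataclass(frozen=True)
class EnvFoldPlan:
    """Disjoint environment groups covering all environments exactly once."""

    folds: tuple[tuple[str, ...], ...]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def all_envs(self) -> set[str]:
        return {e for fold in self.folds for e in fold}


def make_env_folds(env_ids, n_folds: int = 7, seed: int = 0) -> EnvFoldPlan:
    """Seeded uniform random partition of environments into equal folds."""
    env_ids = list(env_ids)
    if len(set(env_ids)) != len(env_ids):
        raise ValueError("duplicate environment ids")
    if len(env_ids) % n_folds != 0:
        raise ValueError(
            f"{len(env_ids)} environments cannot be split into {n_folds} equal folds"
        )
    per = len(env_ids) // n_folds
    rng = np.random.default_rng(seed)
    order = [env_ids[i] for i in rng.permutation(len(env_ids))]
    folds = tuple(
        tuple(order[i * per : (i + 1) * per]) for i in range(n_folds)
    )
    return EnvFoldPlan(folds=folds, seed=seed)


@dataclass(frozen=True)
class ModelSpec:
    """A registered learner plus hyperparameter overrides and a seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def _make_rf(params: dict, seed: int):
    from sklearn.ensemble import RandomForestRegressor

    kw = dict(
        n_estimators=500,
        criterion="squared_error",
        max_features=0.3,
        min_samples_leaf=5,
        random_state=seed,
        n_jobs=1,
    )
    kw.update(params)
    return RandomForestRegressor(**kw)


def _make_svr(params: dict, seed: int):
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR

    return make_pipeline(StandardScaler(), SVR(**params))


def _make_bayesian_ridge(params: dict, seed: int):
    from sklearn.linear_model import BayesianRidge
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return make_pipeline(StandardScaler(), BayesianRidge(**params))


def _make_elastic_net(params: dict, seed: int):
    from sklearn.linear_model import ElasticNet
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    kw = dict(random_state=seed, max_iter=5000)
    kw.update(params)
    return make_pipeline(StandardScaler(), ElasticNet(**kw))


def _make_lightgbm(params: dict, seed: int):
    import lightgbm

    kw = dict(random_state=seed, n_jobs=1, verbose=-1)
    kw.update(params)
    return lightgbm.LGBMRegressor(**kw)


def _make_xgboost(params: dict, seed: int):
    import xgboost

    kw = dict(random_state=seed, n_jobs=1, verbosity=0)
    kw.update(params)
    return xgboost.XGBRegressor(**kw)


MODEL_REGISTRY = {
    "RandomForest": _make_rf,
    "LightGBM": _make_lightgbm,
    "XGBoost": _make_xgboost,
    "SVR": _make_svr,
    "BayesianRidge": _make_bayesian_ridge,
    "ElasticNet": _make_elastic_net,
}


def build_model(spec: ModelSpec):
    if spec.name not in MODEL_REGISTRY:
        raise ValueError(
            f"unknown model {spec.name!r}; registered: {sorted(MODEL_REGISTRY)}"
        )
    return MODEL_REGISTRY[spec.name](dict(spec.params), spec.seed)


def assemble_samples(
    window_features: pd.DataFrame,
    phenotypes: pd.DataFrame,
    trait: str,
    genotype_pcs: pd.DataFrame | None = None,
    rep_average: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Join environment features and genotype PCs into a sample matrix.

    Returns (X, y) indexed by (genotype_id, env_id).  Window features are
    broadcast over genotypes; PC scores are broadcast over environments.
    With ``rep_average`` the response is the replicate mean per genotype x
    environment; otherwise rep-level rows are kept (features repeat).
    """
    if trait not in phenotypes.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")
    keys = ["genotype_id", "env_id"] if rep_average else ["genotype_id", "env_id", "rep"]
    y = phenotypes.groupby(keys, sort=False)[trait].mean()

    env_ids = y.index.get_level_values("env_id")
    missing = set(env_ids) - set(window_features.index)
    if missing:
        raise ValueError(f"environments without features: {sorted(missing)}")
    X = window_features.reindex(env_ids).set_axis(y.index)
    if genotype_pcs is not None:
        gids = y.index.get_level_values("genotype_id")
        missing_g = set(gids) - set(genotype_pcs.index)
        if missing_g:
            raise ValueError(f"genotypes without PC scores: {sorted(missing_g)[:5]}")
        X = pd.concat([X, genotype_pcs.reindex(gids).set_axis(y.index)], axis=1)
    return X, y.rename(trait)


@dataclass
class CVMetrics:
    model: str
    trait: str
    PCC: float
    R2: float
    MSE: float
    n_pooled: int


def pooled_metrics(
    pred: np.ndarray, obs: np.ndarray, model: str = "", trait: str = ""
) -> CVMetrics:
    """PCC, R2 and MSE of pooled predictions against observations.

    R2 = 1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2) with the pooled
    observed mean, so a model predicting that mean scores exactly 0 and R2
    can go negative for worse-than-mean predictions.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if len(pred) != len(obs) or len(obs) == 0:
        raise ValueError("pred and obs must have equal nonzero length")
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        raise ValueError("observed values are constant; PCC and R2 undefined")
    if np.std(pred) == 0:
        pcc = np.nan
    else:
        pcc = float(np.corrcoef(pred, obs)[0, 1])
    sse = float(((obs - pred) ** 2).sum())
    return CVMetrics(
        model=model,
        trait=trait,
        PCC=pcc,
        R2=1.0 - sse / sst,
        MSE=sse / len(obs),
        n_pooled=len(obs),
    )


@dataclass
class CVResult:
    metrics: CVMetrics
    predictions: pd.DataFrame  # genotype_id, env_id, fold, obs, pred


def cross_env_evaluate(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: pd.Series,
    folds: EnvFoldPlan,
) -> CVResult:
    """Leave-environments-out evaluation with pooled metrics.

    For each fold, the model is trained on all samples whose environment is
    not held out and predicts the held-out environments; predictions from
    all folds are concatenated and scored once.
    """
    env_level = X.index.get_level_values("env_id")
    sample_envs = set(env_level)
    plan_envs = folds.all_envs()
    if sample_envs != plan_envs:
        raise ValueError(
            f"fold plan does not match sample environments: "
            f"plan-only={sorted(plan_envs - sample_envs)}, "
            f"sample-only={sorted(sample_envs - plan_envs)}"
        )
    preds = []
    for fold_id, held_out in enumerate(folds.folds, start=1):
        test_mask = env_level.isin(held_out)
        model = build_model(spec)
        model.fit(X.loc[~test_mask].to_numpy(), y.loc[~test_mask].to_numpy())
        yhat = model.predict(X.loc[test_mask].to_numpy())
        block = pd.DataFrame(
            {
                "genotype_id": X.index.get_level_values("genotype_id")[test_mask],
                "env_id": env_level[test_mask],
                "fold": fold_id,
                "obs": y.loc[test_mask].to_numpy(),
                "pred": yhat,
            }
        )
        preds.append(block)
    predictions = pd.concat(preds, ignore_index=True)
    metrics = pooled_metrics(
        predictions["pred"].to_numpy(),
        predictions["obs"].to_numpy(),
        model=spec.name,
        trait=str(y.name),
    )
    return CVResult(metrics=metrics, predictions=predictions)


def selection_ratio(full: pd.DataFrame, selected: pd.DataFrame) -> float:
    """Share of environment-window columns retained after feature selection."""
    n_full = sum(is_window_key(c) for c in full.columns)
    n_sel = sum(is_window_key(c) for c in selected.columns)
    if n_full == 0:
        raise ValueError("no environment window columns in the full matrix")
    return n_sel / n_full


def compare_feature_sets(
    specs: list[ModelSpec],
    X_full: pd.DataFrame,
    X_selected: pd.DataFrame,
    y: pd.Series,
    folds: EnvFoldPlan,
) -> pd.DataFrame:
    """Cross-environment metrics before and after feature selection.

    One row per model with PCC/R2/MSE on the full and the selected feature
    matrices, their deltas (after minus before), and the selection ratio.
    """
    extra = set(X_selected.columns) - set(X_full.columns)
    if extra:
        raise ValueError(f"selected columns not in full matrix: {sorted(extra)[:5]}")
    if not any(is_window_key(c) for c in X_selected.columns):
        raise ValueError("selected feature set contains no environment windows")
    ratio = selection_ratio(X_full, X_selected)
    rows = []
    for spec in specs:
        before = cross_env_evaluate(spec, X_full, y, folds).metrics
        after = cross_env_evaluate(spec, X_selected, y, folds).metrics
        rows.append(
            {
                "model": spec.name,
                "PCC_full": before.PCC,
                "R2_full": before.R2,
                "MSE_full": before.MSE,
                "PCC_selected": after.PCC,
                "R2_selected": after.R2,
                "MSE_selected": after.MSE,
                "delta_PCC": after.PCC - before.PCC,
                "delta_R2": after.R2 - before.R2,
                "delta_MSE": after.MSE - before.MSE,
                "selection_ratio": ratio,
                "n_features_full": X_full.shape[1],
                "n_features_selected": X_selected.shape[1],
            }
        )
    return pd.DataFrame(rows)
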