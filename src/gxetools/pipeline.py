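"""End-to-end pipeline: simulate -> features -> decompose -> scan -> cv ->
key windows -> validation, driven by a single config with a run manifest.

Every stage is also callable on its own through the library; the pipeline
just sequences them, writes each stage's tables under the run directory and
records a manifest (stage order, inputs digested by SHA-256, outputs, wall
time, seeds) so a run can be reproduced bit-for-bit from its config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import decomposition, env_features, key_windows, ml, scan, synthetic

log = logging.getLogger("gxetools")

STAGES = ["simulate", "features", "decompose", "scan", "cv", "keyfactors", "validate"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run.

    Defaults mirror the standard study design: a 150-day season scanned
    from start days 1-145 with durations 5-150, 5-day stride-1 feature
    windows, a 500-tree squared-error forest, 7 folds of 2 environments,
    selection threshold tau = 0.10 with a 5-window smoothing span, and
    genotype PCs retained to >90% cumulative variance.
    """

    out_dir: str = "runs/run1"
    seed: int = 0
    traits: list[str] = field(default_factory=lambda: list(synthetic.TRAITS))
    # simulation (set simulate=False and the three paths to use real tables)
    simulate: bool = True
    weather_csv: str | None = None
    phenotype_csv: str | None = None
    genotype_csv: str | None = None
    archetype_counts: dict = field(
        default_factory=lambda: dict(synthetic.DEFAULT_ARCHETYPE_COUNTS)
    )
    n_lines: int = 250
    n_markers: int = 500
    n_reps: int = 3
    n_days: int = 150
    # scan grid
    start_min: int = 1
    start_max: int = 145
    dur_min: int = 5
    dur_max: int = 150
    # feature grid
    window_size: int = 5
    stride: int = 1
    # model settings
    rf_n_estimators: int = 500
    models: list[str] = field(default_factory=lambda: ["RandomForest"])
    n_folds: int = 7
    # key-window selection
    tau: float = 0.10
    span: int = 5
    combine: str = "and"
    pc_threshold: float = 0.90

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not (1 <= self.start_min <= self.start_max):
            raise ValueError("need 1 <= start_min <= start_max")
        if self.start_max > self.n_days:
            raise ValueError("start_max exceeds the weather day range")
        if not (1 <= self.dur_min <= self.dur_max):
            raise ValueError("need 1 <= dur_min <= dur_max")
        if self.dur_max > self.n_days:
            raise ValueError("dur_max exceeds the weather day range")
        if self.window_size > self.n_days:
            raise ValueError("window_size exceeds the weather day range")
        if self.span % 2 == 0 or self.span < 1:
            raise ValueError("span must be odd and >= 1")
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if not self.simulate:
            for name in ("weather_csv", "phenotype_csv"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{name} required when simulate=false")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig, out: Path):
        self.doc = {"config": asdict(config), "stages": []}
        self.out = out

    def record(self, stage: str, t0: float, inputs: list[Path], outputs: list[Path]):
        self.doc["stages"].append(
            {
                "stage": stage,
                "wall_time_s": round(time.time() - t0, 3),
                "inputs": {p.name: _sha256(p) for p in inputs},
                "outputs": [p.name for p in outputs],
            }
        )

    def write(self) -> Path:
        path = self.out / "manifest.json"
        path.write_text(json.dumps(self.doc, indent=1))
        return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the manifest dict.

    Reruns with the same config (and therefore seeds) reproduce every CSV
    byte-for-byte.  A stage failure aborts the run with the stage name.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    manifest = _Manifest(config, out)
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        log.error("stage failed: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()
    manifest.write()
    return manifest.doc


def _run_stages(config: RunConfig, out: Path, manifest: _Manifest) -> None:
    # --- simulate or load -------------------------------------------------
    t0 = time.time()
    log.info("stage simulate")
    if config.simulate:
        trial = synthetic.simulate_trial(
            archetype_counts=config.archetype_counts,
            n_lines=config.n_lines,
            n_markers=config.n_markers,
            n_reps=config.n_reps,
            n_days=config.n_days,
            seed=config.seed,
            traits=config.traits,
        )
        paths = trial.write(out)
        weather, phenotypes, genotypes = trial.weather, trial.phenotypes, trial.genotypes
        manifest.record("simulate", t0, [], list(paths.values()))
    else:
        weather = pd.read_csv(config.weather_csv)
        phenotypes = pd.read_csv(config.phenotype_csv)
        genotypes = (
            pd.read_csv(config.genotype_csv, index_col=0)
            if config.genotype_csv
            else None
        )
        manifest.record(
            "simulate", t0,
            [Path(p) for p in (config.weather_csv, config.phenotype_csv) if p], [],
        )

    # --- indices and feature matrices ------------------------------------
    t0 = time.time()
    log.info("stage features")
    table = env_features.daily_factor_table(weather)
    indices_path = out / "indices.csv"
    table.melt(id_vars=["env_id", "day"], var_name="factor", value_name="value").to_csv(
        indices_path, index=False
    )
    features = env_features.build_window_features(
        table, window_size=config.window_size, stride=config.stride
    )
    features_path = out / "features.csv"
    features.to_csv(features_path)
    pcs = None
    if config.simulate or genotypes is not None:
        pcs = env_features.genotype_pcs(genotypes, config.pc_threshold).scores
    manifest.record("features", t0, [], [indices_path, features_path])

    # --- classical decomposition ------------------------------------------
    t0 = time.time()
    log.info("stage decompose")
    outputs = []
    for trait in config.traits:
        anova = decomposition.anova_decompose(phenotypes, trait)
        fw = decomposition.fw_regression(phenotypes, trait)
        gge = decomposition.gge_biplot(phenotypes, trait)
        p1 = out / f"anova_{trait}.csv"
        anova.to_csv(p1)
        p2 = out / f"fw_{trait}.csv"
        fw.fits.to_csv(p2)
        p3 = out / f"gge_{trait}.csv"
        gge_df = pd.concat(
            [gge.genotype_scores, gge.env_scores], keys=["genotype", "environment"]
        )
        gge_df["explained_axis1"] = gge.explained_fraction[0]
        gge_df["explained_axis2"] = (
            gge.explained_fraction[1] if len(gge.explained_fraction) > 1 else 0.0
        )
        gge_df.to_csv(p3)
        outputs += [p1, p2, p3]
    manifest.record("decompose", t0, [], outputs)

    # --- sliding-window scan ----------------------------------------------
    t0 = time.time()
    log.info("stage scan")
    outputs = []
    for trait in config.traits:
        env_means = phenotypes.groupby("env_id")[trait].mean()
        result = scan.scan_windows(
            table, env_means, trait=trait,
            start_min=config.start_min, start_max=config.start_max,
            dur_min=config.dur_min, dur_max=config.dur_max,
        )
        p1 = out / f"scan_{trait}.csv"
        result.scores.to_csv(p1, index=False)
        best, _ = scan.top_windows(result)
        p2 = out / f"top_windows_{trait}.csv"
        best.to_csv(p2, index=False)
        outputs += [p1, p2]
    manifest.record("scan", t0, [features_path], outputs)

    # --- cross-environment CV ---------------------------------------------
    t0 = time.time()
    log.info("stage cv")
    folds = ml.make_env_folds(
        list(features.index), n_folds=config.n_folds, seed=config.seed
    )
    fold_path = out / "fold_plan.json"
    fold_path.write_text(json.dumps({"seed": folds.seed, "folds": folds.folds}, indent=1))
    rows = []
    sample_cache = {}
    for trait in config.traits:
        X, yv = ml.assemble_samples(features, phenotypes, trait, genotype_pcs=pcs)
        sample_cache[trait] = (X, yv)
        for name in config.models:
            spec = ml.ModelSpec(
                name,
                params={"n_estimators": config.rf_n_estimators}
                if name == "RandomForest"
                else {},
                seed=config.seed,
            )
            m = ml.cross_env_evaluate(spec, X, yv, folds).metrics
            rows.append(
                dict(model=name, trait=trait, PCC=m.PCC, R2=m.R2, MSE=m.MSE,
                     n_pooled=m.n_pooled, feature_set="full",
                     n_features=X.shape[1], seed=config.seed)
            )
    cv_path = out / "cv_metrics.csv"
    pd.DataFrame(rows).to_csv(cv_path, index=False)
    manifest.record("cv", t0, [features_path], [cv_path, fold_path])

    # --- key windows --------------------------------------------------------
    t0 = time.time()
    log.info("stage keyfactors")
    outputs = []
    key_sets = {}
    for trait in config.traits:
        X, yv = sample_cache[trait]
        model, _ = key_windows.fit_rf_for_trait(
            X, yv, n_estimators=config.rf_n_estimators, seed=config.seed
        )
        profiles = key_windows.smooth_profiles(
            key_windows.attribution_profiles(model, X, trait=trait), span=config.span
        )
        key_set = key_windows.select_key_windows(
            profiles, tau=config.tau, combine=config.combine
        )
        key_sets[trait] = key_set
        p1 = out / f"key_windows_{trait}.csv"
        key_set.entries.to_csv(p1, index=False)
        p2 = out / f"profiles_{trait}.csv"
        profiles.env_profiles.to_csv(p2, index=False)
        outputs += [p1, p2]
    manifest.record("keyfactors", t0, [features_path], outputs)

    # --- validation: before/after feature selection -------------------------
    t0 = time.time()
    log.info("stage validate")
    rows = []
    for trait in config.traits:
        X, yv = sample_cache[trait]
        key_set = key_sets[trait]
        if not key_set.selected_keys:
            log.warning("no key windows selected for %s; skipping validation", trait)
            continue
        X_sel = key_windows.selected_feature_matrix(X, key_set)
        specs = [
            ml.ModelSpec(
                name,
                params={"n_estimators": config.rf_n_estimators}
                if name == "RandomForest"
                else {},
                seed=config.seed,
            )
            for name in config.models
        ]
        cmp = ml.compare_feature_sets(specs, X, X_sel, yv, folds)
        cmp.insert(1, "trait", trait)
        rows.append(cmp)
    val_path = out / "comparison.csv"
    pd.concat(rows, ignore_index=True).to_csv(val_path, index=False)
    manifest.record("validate", t0, [features_path], [val_path])
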