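"""Synthetic multi-environment cotton trials with known ground truth.

The generator emulates a replicated multi-environment trial of recombinant
inbred lines: 14 environments drawn from three climate archetypes (arid
Northwest, semi-arid Yellow River, humid Yangtze), ~250 homozygous lines
with block-structured biallelic markers, and trait values produced by an
additive plasticity model

    y_ijk = mu + g_i + (1 + b_i) * E_j + rep_jk + eps_ijk

where the environment effect E_j is driven by planted critical time windows
of named environmental factors (window means, centered across environments
so that plasticity slopes are identifiable).  The truth record — planted
windows, genotype effects and slopes, noise levels — is returned alongside
the data so every downstream stage can be tested for recovery.

Weather is a sinusoidal seasonal baseline plus AR(1) day-to-day noise per
variable, truncated at physical bounds; precipitation is gamma-distributed
around an environment-level mean drawn from the archetype's range.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .env_features import BASE_VARS, FACTORS, daily_factor_table

TRAITS = ["BW", "LP", "SI", "FL", "FS", "FM"]

#: Trait grand means in their units (boll weight g, lint percentage %,
#: seed index g, fiber length mm, fiber strength cN/tex, micronaire).
TRAIT_MEANS = {"BW": 5.8, "LP": 38.0, "SI": 11.5, "FL": 30.5, "FS": 31.0, "FM": 4.3}

#: Genotype main-effect standard deviations (trait units).
TRAIT_GENETIC_SD = {"BW": 0.35, "LP": 2.0, "SI": 0.8, "FL": 0.9, "FS": 1.3, "FM": 0.25}

#: Residual plot-level noise standard deviations (trait units).
TRAIT_NOISE_SD = {"BW": 0.45, "LP": 1.3, "SI": 0.5, "FL": 0.9, "FS": 1.5, "FM": 0.25}


class ConfigurationError(ValueError):
    """Invalid generator configuration (unknown archetype, factor, ...)."""


@dataclass(frozen=True)
class ClimateArchetype:
    """Seasonal climate regime for one group of trial sites.

    ``pcp_mean_range`` brackets the environment-level mean daily
    precipitation (mm/day); ``radn_peak`` is the mid-season solar radiation
    peak (MJ/m2/day); ``rh_level`` the baseline relative humidity (%);
    ``temp_baseline``/``temp_amplitude`` the seasonal mean-temperature curve
    (degC); ``wind_regime`` the mean wind speed (m/s).
    """

    name: str
    pcp_mean_range: tuple[float, float]
    radn_peak: float
    rh_level: float
    temp_baseline: float
    temp_amplitude: float
    wind_regime: float
    dh_base: float = 8.0
    dtr_mean: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.pcp_mean_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("pcp_mean_range must satisfy 0 <= low <= high")
        for name in ("radn_peak", "rh_level", "temp_amplitude", "wind_regime",
                     "dh_base", "dtr_mean"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


#: Default archetypes bracketing the printed regional climate ranges:
#: arid 0.4-1.2, semi-arid 2.0-5.1 and humid 4.8-7.2 mm/day precipitation;
#: ~28 MJ/m2/day radiation and ~50% humidity in the arid Northwest versus
#: <20 MJ/m2/day and ~75% in the humid Yangtze region; weak (<2 m/s) winds
#: in the Northwest against persistent >2 m/s monsoon flow elsewhere.
ARCHETYPES: dict[str, ClimateArchetype] = {
    "arid": ClimateArchetype(
        "arid", (0.4, 1.2), radn_peak=28.0, rh_level=50.0,
        temp_baseline=21.0, temp_amplitude=6.5, wind_regime=1.6,
        dh_base=9.5, dtr_mean=13.0,
    ),
    "semi_arid": ClimateArchetype(
        "semi_arid", (2.0, 5.1), radn_peak=23.0, rh_level=63.0,
        temp_baseline=23.0, temp_amplitude=6.0, wind_regime=2.4,
        dh_base=7.5, dtr_mean=10.0,
    ),
    "humid": ClimateArchetype(
        "humid", (4.8, 7.2), radn_peak=19.0, rh_level=75.0,
        temp_baseline=24.0, temp_amplitude=5.5, wind_regime=2.3,
        dh_base=6.0, dtr_mean=8.0,
    ),
}

# AR(1) day-to-day weather noise: common persistence, per-variable
# innovation scale (realistic synoptic variability).
_AR_PHI = 0.6
_AR_SD = {"tmean": 1.3, "dtr": 1.5, "rhmean": 5.0, "radn": 2.2, "dh": 1.8, "wsmean": 0.5}
# Between-environment (site/year) offsets within an archetype.
_ENV_SD = {"tmean": 0.6, "rhmean": 2.5, "wsmean": 0.15}
_PCP_GAMMA_SHAPE = 2.0


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = _AR_PHI) -> np.ndarray:
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
    innov = rng.normal(0.0, sd, n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def get_archetype(archetype: str | ClimateArchetype) -> ClimateArchetype:
    if isinstance(archetype, ClimateArchetype):
        return archetype
    try:
        return ARCHETYPES[archetype]
    except KeyError:
        raise ConfigurationError(
            f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}"
        ) from None


def generate_weather(
    archetype: str | ClimateArchetype,
    n_days: int = 150,
    seed: int | np.random.SeedSequence = 0,
    env_id: str = "E1",
) -> pd.DataFrame:
    """Daily weather for one environment over ``n_days`` days after planting.

    Deterministic for a given (archetype, n_days, seed).  The construction
    forces tmin <= tmean <= tmax (temperatures are built from a mean curve
    and a positive diurnal range) and clips humidity to [0, 100] and the
    nonnegative variables at zero.
    """
    arch = get_archetype(archetype)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)

    t = np.arange(1, n_days + 1)
    season = np.sin(np.pi * t / (n_days + 1))  # 0 -> 1 -> 0 over the season

    off_t = rng.normal(0.0, _ENV_SD["tmean"])
    off_rh = rng.normal(0.0, _ENV_SD["rhmean"])
    off_ws = rng.normal(0.0, _ENV_SD["wsmean"])
    radn_scale = rng.normal(1.0, 0.04)

    tmean = (
        arch.temp_baseline + off_t - arch.temp_amplitude / 2.0
        + arch.temp_amplitude * season
        + _ar1(rng, n_days, _AR_SD["tmean"])
    )
    dtr = np.clip(arch.dtr_mean + _ar1(rng, n_days, _AR_SD["dtr"]), 1.0, None)
    tmax = tmean + dtr / 2.0
    tmin = tmean - dtr / 2.0

    radn = np.clip(
        radn_scale * arch.radn_peak * (0.55 + 0.45 * season)
        + _ar1(rng, n_days, _AR_SD["radn"]),
        0.5, None,
    )
    rhmean = np.clip(arch.rh_level + off_rh + _ar1(rng, n_days, _AR_SD["rhmean"]), 0.0, 100.0)
    dh = np.clip(
        arch.dh_base + 1.5 * (season - 0.5) + _ar1(rng, n_days, _AR_SD["dh"]), 0.0, 14.0
    )
    wsmean = np.clip(
        arch.wind_regime + off_ws + _ar1(rng, n_days, _AR_SD["wsmean"]), 0.05, None
    )

    pcp_mean = rng.uniform(*arch.pcp_mean_range)
    weights = 0.7 + 0.6 * season
    weights = weights / weights.mean()
    pcp = rng.gamma(
        _PCP_GAMMA_SHAPE, pcp_mean * weights / _PCP_GAMMA_SHAPE, size=n_days
    )

    return pd.DataFrame(
        {
            "env_id": env_id,
            "day": t,
            "tmax": tmax,
            "tmin": tmin,
            "tmean": tmean,
            "pcp": pcp,
            "dh": dh,
            "rhmean": rhmean,
            "radn": radn,
            "wsmean": wsmean,
        }
    )


def generate_genotypes(
    n_lines: int,
    n_markers: int,
    seed: int | np.random.SeedSequence = 0,
    n_blocks: int = 25,
    flip_rate: float = 0.05,
) -> pd.DataFrame:
    """Biallelic homozygous marker matrix with block-correlated markers.

    Lines are fully inbred, so markers are coded {0, 1} with no
    heterozygotes.  Markers come in ``n_blocks`` contiguous linkage blocks;
    within a block every marker copies the block's founder allele except for
    a small ``flip_rate`` of recombinant/error flips, so a low-dimensional
    principal-component representation exists (``flip_rate=0`` gives exactly
    ``n_blocks`` independent columns).
    """
    if n_lines < 2 or n_markers < 2:
        raise ValueError("need n_lines >= 2 and n_markers >= 2")
    n_blocks = min(n_blocks, n_markers)
    rng = np.random.default_rng(seed)
    block_of = (np.arange(n_markers) * n_blocks) // n_markers
    founder = rng.integers(0, 2, size=(n_lines, n_blocks))
    G = founder[:, block_of]
    if flip_rate > 0:
        flips = rng.random((n_lines, n_markers)) < flip_rate
        G = np.where(flips, 1 - G, G)
    idx = pd.Index([f"G{i + 1:03d}" for i in range(n_lines)], name="genotype_id")
    return pd.DataFrame(G, index=idx, columns=[f"m{j + 1}" for j in range(n_markers)])


@dataclass(frozen=True)
class PlantedWindow:
    """A planted causal time window: the named factor's mean over days
    start_day..end_day drives the environment effect of ``trait`` with the
    given effect size (trait units per unit of window mean)."""

    trait: str
    factor: str
    start_day: int
    end_day: int
    effect: float

    def days(self) -> set[int]:
        return set(range(self.start_day, self.end_day + 1))


@dataclass
class TruthRecord:
    """Ground truth behind one simulated trial."""

    planted_windows: list[PlantedWindow]
    genotype_effects: dict[str, np.ndarray]
    genotype_slopes: dict[str, np.ndarray]
    mu: dict[str, float]
    rep_effect_sd: dict[str, float]
    noise_sd: dict[str, float]
    seed: int

    def validate(self, n_days: int) -> None:
        for w in self.planted_windows:
            if not (1 <= w.start_day <= w.end_day <= n_days):
                raise ConfigurationError(
                    f"planted window {w} outside day range 1..{n_days}"
                )
            if w.factor not in FACTORS:
                raise ConfigurationError(
                    f"planted factor {w.factor!r} not among the {len(FACTORS)} factors"
                )
            if not np.isfinite(w.effect):
                raise ConfigurationError("effect sizes must be finite")
        for tr, sd in self.noise_sd.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sd for {tr} must be >= 0")

    @property
    def traits(self) -> list[str]:
        return list(self.mu)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "mu": self.mu,
            "rep_effect_sd": self.rep_effect_sd,
            "noise_sd": self.noise_sd,
            "planted_windows": [dataclasses.asdict(w) for w in self.planted_windows],
            "genotype_effects": {t: v.tolist() for t, v in self.genotype_effects.items()},
            "genotype_slopes": {t: v.tolist() for t, v in self.genotype_slopes.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        doc = json.loads(Path(path).read_text())
        return cls(
            planted_windows=[PlantedWindow(**w) for w in doc["planted_windows"]],
            genotype_effects={t: np.asarray(v) for t, v in doc["genotype_effects"].items()},
            genotype_slopes={t: np.asarray(v) for t, v in doc["genotype_slopes"].items()},
            mu=doc["mu"],
            rep_effect_sd=doc["rep_effect_sd"],
            noise_sd=doc["noise_sd"],
            seed=doc["seed"],
        )


#: Default planted critical windows: mid-to-late-season drivers of the yield
#: traits and late-season hydric drivers of the fiber traits, mirroring the
#: temporal structure this kind of trial exhibits.
DEFAULT_PLANTED_WINDOWS = [
    PlantedWindow("BW", "rhmean", 62, 71, +0.07),
    PlantedWindow("BW", "tmax", 111, 115, -0.17),
    PlantedWindow("BW", "radn", 104, 110, +0.06),
    PlantedWindow("LP", "ptq", 68, 72, +2.0),
    PlantedWindow("LP", "tmean", 138, 143, -0.5),
    PlantedWindow("SI", "tmin", 117, 146, +0.5),
    PlantedWindow("SI", "pcp", 69, 73, -0.5),
    PlantedWindow("FL", "pcp", 135, 139, +0.15),
    PlantedWindow("FL", "prdtr", 135, 139, +0.6),
    PlantedWindow("FS", "tmean", 72, 79, +0.4),
    PlantedWindow("FS", "ptq", 82, 86, -1.2),
    PlantedWindow("FM", "rhmean", 58, 64, +0.017),
    PlantedWindow("FM", "radn", 49, 55, -0.04),
]


def default_truth(
    n_lines: int,
    seed: int = 0,
    traits: list[str] | None = None,
    planted_windows: list[PlantedWindow] | None = None,
    slope_sd: float = 0.15,
    rep_effect_sd: dict[str, float] | float | None = None,
    noise_sd: dict[str, float] | float | None = None,
    n_days: int = 150,
) -> TruthRecord:
    """Draw a ground-truth record with normal genotype effects and slopes.

    Slopes b_i are centered at zero so 1 + b_i averages one, the standard
    joint-regression convention; replicate effects default to a tenth of
    the plot noise (replicate blocks contribute little variance).  Default
    planted windows falling outside a shortened season (``n_days`` < 150)
    are dropped; explicitly supplied windows are kept as given.
    """
    traits = list(traits) if traits is not None else TRAITS
    windows = (
        list(planted_windows)
        if planted_windows is not None
        else [
            w
            for w in DEFAULT_PLANTED_WINDOWS
            if w.trait in traits and w.end_day <= n_days
        ]
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    def _per_trait(value, default: dict[str, float]) -> dict[str, float]:
        if value is None:
            return {t: default[t] for t in traits}
        if np.isscalar(value):
            return {t: float(value) for t in traits}
        return {t: float(value[t]) for t in traits}

    noise = _per_trait(noise_sd, TRAIT_NOISE_SD)
    rep = _per_trait(
        rep_effect_sd, {t: 0.1 * TRAIT_NOISE_SD[t] for t in TRAITS}
    )
    return TruthRecord(
        planted_windows=windows,
        genotype_effects={
            t: rng.normal(0.0, TRAIT_GENETIC_SD[t], n_lines) for t in traits
        },
        genotype_slopes={t: rng.normal(0.0, slope_sd, n_lines) for t in traits},
        mu={t: TRAIT_MEANS[t] for t in traits},
        rep_effect_sd=rep,
        noise_sd=noise,
        seed=seed,
    )


def environment_effects(
    weather: pd.DataFrame, truth: TruthRecord
) -> pd.DataFrame:
    """Per-trait environment effects E_j implied by the planted windows.

    For each planted window, the named factor is averaged over the window in
    each environment, multiplied by the effect size, summed per trait, and
    centered across environments (mean environment effect zero, which makes
    plasticity slopes identifiable).  Returns environments x traits.
    """
    truth.validate(int(weather["day"].max()))
    table = daily_factor_table(weather)
    env_ids = list(pd.unique(weather["env_id"]))
    eff = pd.DataFrame(0.0, index=pd.Index(env_ids, name="env_id"), columns=truth.traits)
    for w in truth.planted_windows:
        if w.trait not in eff.columns:
            continue
        sel = table[(table["day"] >= w.start_day) & (table["day"] <= w.end_day)]
        means = sel.groupby("env_id")[w.factor].mean().reindex(eff.index)
        eff[w.trait] += w.effect * means
    return eff - eff.mean(axis=0)


def generate_phenotypes(
    weather: pd.DataFrame,
    truth: TruthRecord,
    n_lines: int | None = None,
    n_reps: int = 3,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Replicated phenotypes under the additive plasticity model.

    y_ijk = mu + g_i + (1 + b_i) E_j + rep_jk + eps_ijk with E_j the
    centered planted-window environment effect, rep effects drawn once per
    environment x replicate, and i.i.d. normal residuals.  Deterministic
    given the truth record's seed.
    """
    traits = truth.traits
    n_from_truth = len(next(iter(truth.genotype_effects.values())))
    if n_lines is None:
        n_lines = n_from_truth
    if n_lines != n_from_truth:
        raise ConfigurationError(
            f"n_lines={n_lines} does not match truth record ({n_from_truth})"
        )
    E = environment_effects(weather, truth)
    env_ids = list(E.index)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 202]))

    geno_ids = [f"G{i + 1:03d}" for i in range(n_lines)]
    rows = {
        "genotype_id": np.repeat(geno_ids, len(env_ids) * n_reps),
        "env_id": np.tile(np.repeat(env_ids, n_reps), n_lines),
        "rep": np.tile([f"R{r + 1}" for r in range(n_reps)], n_lines * len(env_ids)),
    }
    out = pd.DataFrame(rows)
    for trait in traits:
        g = truth.genotype_effects[trait]
        b = truth.genotype_slopes[trait]
        ej = E[trait].to_numpy()
        rep_fx = rng.normal(0.0, truth.rep_effect_sd[trait], (len(env_ids), n_reps))
        base = (
            truth.mu[trait]
            + np.repeat(g, len(env_ids) * n_reps)
            + np.repeat(1.0 + b, len(env_ids) * n_reps)
            * np.tile(np.repeat(ej, n_reps), n_lines)
            + np.tile(rep_fx.ravel(), n_lines)
        )
        eps = rng.normal(0.0, truth.noise_sd[trait], len(base))
        out[trait] = base + eps
    return out, truth


@dataclass
class SimulatedTrial:
    weather: pd.DataFrame
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: TruthRecord

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "weather": out / "weather.csv",
            "phenotype": out / "phenotype.csv",
            "genotype": out / "genotype.csv",
            "truth": out / "truth.json",
        }
        self.weather.to_csv(paths["weather"], index=False)
        self.phenotypes.to_csv(paths["phenotype"], index=False)
        self.genotypes.to_csv(paths["genotype"])
        self.truth.to_json(paths["truth"])
        return paths


#: Environment counts per archetype matching a 14-environment trial spread
#: over the three ecological regions (6 Northwest, 5 Yellow River,
#: 3 Yangtze River year-site combinations).
DEFAULT_ARCHETYPE_COUNTS = {"arid": 6, "semi_arid": 5, "humid": 3}


def simulate_trial(
    archetype_counts: dict[str, int] | None = None,
    n_lines: int = 250,
    n_markers: int = 500,
    n_reps: int = 3,
    n_days: int = 150,
    seed: int = 0,
    traits: list[str] | None = None,
    truth: TruthRecord | None = None,
) -> SimulatedTrial:
    """Simulate a full trial: weather per environment, markers, phenotypes."""
    counts = dict(archetype_counts or DEFAULT_ARCHETYPE_COUNTS)
    for name in counts:
        get_archetype(name)  # raises ConfigurationError on unknown names
    ss = np.random.SeedSequence([seed, 303])
    children = ss.spawn(sum(counts.values()) + 1)
    frames = []
    i = 0
    for name, n in counts.items():
        for k in range(n):
            frames.append(
                generate_weather(
                    name, n_days=n_days, seed=children[i], env_id=f"{name}_{k + 1}"
                )
            )
            i += 1
    weather = pd.concat(frames, ignore_index=True)
    genotypes = generate_genotypes(n_lines, n_markers, seed=children[-1])
    if truth is None:
        truth = default_truth(n_lines, seed=seed, traits=traits, n_days=n_days)
    phenotypes, truth = generate_phenotypes(weather, truth, n_reps=n_reps)
    return SimulatedTrial(weather, genotypes, phenotypes, truth)
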