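import numpy as np
import pandas as pd
import pytest

import gxetools as g


def jaccard(days_a: set, days_b: set) -> float:
    return len(days_a & days_b) / len(days_a | days_b)


@pytest.fixture(scope="session")
def small_trial() -> g.SimulatedTrial:
    """A small but complete balanced trial shared across tests."""
    return g.simulate_trial(
        archetype_counts={"arid": 2, "semi_arid": 2, "humid": 2},
        n_lines=12,
        n_markers=60,
        n_reps=3,
        n_days=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def factor_table(small_trial) -> pd.DataFrame:
    return g.daily_factor_table(small_trial.weather)


def planted_two_factor_trial(
    seed: int,
    n_lines: int,
    n_envs: int,
    planted=(("rhmean", 60, 74), ("wsmean", 88, 102)),
    env_share: float = 0.6,
    archetype: str = "semi_arid",
    n_reps: int = 3,
    trait: str = "BW",
):
    """Homogeneous-region trial whose env effect is driven by planted windows.

    Effect sizes are scaled so each planted window contributes equally and
    the total environment effect accounts for ``env_share`` of phenotypic
    variance (genotype main effects and plot noise at their defaults).
    Returns (weather, genotypes, phenotypes, truth).
    """
    ss = np.random.SeedSequence([seed, 303])
    children = ss.spawn(n_envs + 1)
    weather = pd.concat(
        [
            g.generate_weather(archetype, 150, children[i], f"env_{i + 1:02d}")
            for i in range(n_envs)
        ],
        ignore_index=True,
    )
    genotypes = g.generate_genotypes(n_lines, 300, seed=children[-1])
    table = g.daily_factor_table(weather)
    g_var = g.synthetic.TRAIT_GENETIC_SD[trait] ** 2
    e_var = g.synthetic.TRAIT_NOISE_SD[trait] ** 2
    target_each = (env_share / (1 - env_share)) * (g_var + e_var) / len(planted)
    windows = []
    for factor, start, end in planted:
        sel = table[(table.day >= start) & (table.day <= end)]
        wmean = sel.groupby("env_id")[factor].mean()
        effect = float(np.sqrt(target_each / wmean.var(ddof=0)))
        windows.append(g.PlantedWindow(trait, factor, start, end, effect))
    truth = g.default_truth(
        n_lines=n_lines, seed=seed, traits=[trait], planted_windows=windows
    )
    phenotypes, _ = g.generate_phenotypes(weather, truth, n_reps=n_reps)
    return weather, genotypes, phenotypes, truth
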