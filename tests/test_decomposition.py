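import numpy as np
import pandas as pd
import pytest

import gxetools as g
from gxetools.decomposition import DegenerateDesignError


def _balanced_design(rng, ng, ne, nr, sd_g=1.0, sd_e=1.5, sd_ge=0.5, sd=0.7):
    geff = rng.normal(0, sd_g, ng)
    eeff = rng.normal(0, sd_e, ne)
    reff = rng.normal(0, 0.2, nr)
    ge = rng.normal(0, sd_ge, (ng, ne))
    rows = []
    for i in range(ng):
        for j in range(ne):
            for k in range(nr):
                rows.append(
                    dict(genotype_id=f"G{i}", env_id=f"E{j}", rep=f"R{k}",
                         y=10 + geff[i] + eeff[j] + reff[k] + ge[i, j]
                         + rng.normal(0, sd))
                )
    return pd.DataFrame(rows)


def brute_force_anova_ss(df):
    """Textbook group-mean sums of squares for the balanced crossed design."""
    y = df.y.to_numpy()
    grand = y.mean()
    ng, ne, nr = df.genotype_id.nunique(), df.env_id.nunique(), df.rep.nunique()
    ss = {}
    ss["Genotype"] = ne * nr * sum(
        (df[df.genotype_id == i].y.mean() - grand) ** 2 for i in df.genotype_id.unique()
    )
    ss["ENVs"] = ng * nr * sum(
        (df[df.env_id == j].y.mean() - grand) ** 2 for j in df.env_id.unique()
    )
    ss["Rep"] = ng * ne * sum(
        (df[df.rep == k].y.mean() - grand) ** 2 for k in df.rep.unique()
    )
    ss_ge = 0.0
    for i in df.genotype_id.unique():
        for j in df.env_id.unique():
            cell = df[(df.genotype_id == i) & (df.env_id == j)].y.mean()
            ss_ge += (
                cell - df[df.genotype_id == i].y.mean()
                - df[df.env_id == j].y.mean() + grand
            ) ** 2
    ss["Genotype:ENVs"] = nr * ss_ge
    ss["Residuals"] = ((y - grand) ** 2).sum() - sum(ss.values())
    return ss


def test_anova_matches_group_mean_oracle_and_statsmodels():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(0)
    for _ in range(4):
        ng, ne, nr = rng.integers(3, 8), rng.integers(3, 6), rng.integers(2, 4)
        df = _balanced_design(rng, ng, ne, nr)
        table = g.anova_decompose(df, "y")
        oracle = brute_force_anova_ss(df)
        for stratum, ss in oracle.items():
            assert table.loc[stratum, "SS"] == pytest.approx(ss, rel=1e-8)
        fit = smf.ols(
            "y ~ C(genotype_id) + C(env_id) + C(rep) + C(genotype_id):C(env_id)", df
        ).fit()
        sm_tab = sm.stats.anova_lm(fit, typ=1)
        np.testing.assert_allclose(
            table.SS.to_numpy(), sm_tab.sum_sq.to_numpy(), rtol=1e-7
        )
        np.testing.assert_allclose(
            table.F.to_numpy()[:-1], sm_tab.F.to_numpy()[:-1], rtol=1e-7
        )
        assert table.variance_pct.sum() == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(table.MS, table.SS / table.Df)


def test_anova_constant_data_warns_and_zeroes():
    df = _balanced_design(np.random.default_rng(1), 3, 3, 2)
    df["y"] = 5.0
    with pytest.warns(UserWarning, match="total SS"):
        table = g.anova_decompose(df, "y")
    assert (table.variance_pct == 0).all()
    assert (table.SS.abs() < 1e-20).all()


def test_anova_unbalanced_falls_back_to_sequential_ss():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _balanced_design(np.random.default_rng(2), 4, 3, 2).iloc[:-3]
    with pytest.warns(UserWarning, match="unbalanced"):
        table = g.anova_decompose(df, "y")
    fit = smf.ols(
        "y ~ C(genotype_id) + C(env_id) + C(rep) + C(genotype_id):C(env_id)", df
    ).fit()
    sm_tab = sm.stats.anova_lm(fit, typ=1)
    np.testing.assert_allclose(table.SS.to_numpy(), sm_tab.sum_sq.to_numpy(), rtol=1e-7)


def test_anova_degenerate_designs_raise():
    rng = np.random.default_rng(3)
    single_rep = _balanced_design(rng, 3, 3, 1)
    with pytest.raises(DegenerateDesignError):
        g.anova_decompose(single_rep, "y")
    one_env = _balanced_design(rng, 3, 1, 2)
    with pytest.raises(DegenerateDesignError):
        g.anova_decompose(one_env, "y")


def test_fw_identity_and_constant_genotypes():
    rng = np.random.default_rng(4)
    envs = [f"E{j}" for j in range(5)]
    eeff = rng.normal(0, 2, 5)
    rows = []
    for j, e in enumerate(envs):
        rows.append(dict(genotype_id="tracker", env_id=e, rep="R1", y=20 + eeff[j]))
        rows.append(dict(genotype_id="flat", env_id=e, rep="R1", y=13.0))
    df = pd.DataFrame(rows)
    fw = g.fw_regression(df, "y")
    # env effects are centered
    assert fw.env_effects.sum() == pytest.approx(0.0, abs=1e-9)
    # flat genotype: slope 0; tracker absorbs double weight after centering
    assert fw.fits.loc["flat", "slope"] == pytest.approx(0.0, abs=1e-9)
    assert fw.fits.loc["tracker", "slope"] == pytest.approx(2.0, abs=1e-9)
    # a genotype equal to the environment means has slope 1, zero residual
    rows = [
        dict(genotype_id=gid, env_id=e, rep="R1",
             y=20 + eeff[j] * (1 if gid == "self" else mult))
        for j, e in enumerate(envs)
        for gid, mult in [("self", 1.0), ("other", 1.0)]
    ]
    df2 = pd.DataFrame(rows)
    fw2 = g.fw_regression(df2, "y")
    assert fw2.fits.loc["self", "slope"] == pytest.approx(1.0)
    assert fw2.fits.loc["self", "r2"] == pytest.approx(1.0)


def test_fw_excludes_sparse_genotypes_with_warning():
    df = pd.DataFrame(
        [
            dict(genotype_id="ok", env_id=f"E{j}", rep="R1", y=float(j))
            for j in range(4)
        ]
        + [dict(genotype_id="sparse", env_id="E0", rep="R1", y=1.0),
           dict(genotype_id="sparse", env_id="E1", rep="R1", y=2.0)]
    )
    with pytest.warns(UserWarning, match="<3 environments"):
        fw = g.fw_regression(df, "y")
    assert "sparse" not in fw.fits.index


def test_fw_recovers_planted_slopes_exactly_without_noise():
    truth = g.default_truth(n_lines=10, seed=6, traits=["BW"],
                            noise_sd=0.0, rep_effect_sd=0.0)
    # FW slopes are identified relative to the mean slope: center b_i
    truth.genotype_slopes["BW"] -= truth.genotype_slopes["BW"].mean()
    trial = g.simulate_trial(
        archetype_counts={"arid": 2, "semi_arid": 2, "humid": 2},
        n_lines=10, n_markers=20, n_reps=2, seed=6, traits=["BW"], truth=truth,
    )
    fw = g.fw_regression(trial.phenotypes, "BW")
    expected = 1.0 + truth.genotype_slopes["BW"]
    np.testing.assert_allclose(fw.fits.slope.to_numpy(), expected, atol=1e-9)
    np.testing.assert_allclose(fw.fits.r2.dropna(), 1.0, atol=1e-9)
    assert fw.fits.slope.mean() == pytest.approx(1.0, abs=1e-9)


def test_gge_rank_one_and_explained_fractions(small_trial):
    # rank-1 structure: one singular axis carries everything
    envs = [f"E{j}" for j in range(4)]
    rows = [
        dict(genotype_id=f"G{i}", env_id=e, rep="R1", y=5 + (i - 1.5) * (j + 1))
        for i in range(4)
        for j, e in enumerate(envs)
    ]
    gge = g.gge_biplot(pd.DataFrame(rows), "y")
    assert gge.explained_fraction[0] == pytest.approx(1.0)
    # general case: fractions sum to one, reconstruction is exact
    gge2 = g.gge_biplot(small_trial.phenotypes, "BW")
    assert gge2.explained_fraction.sum() == pytest.approx(1.0)
    cell = (
        small_trial.phenotypes.groupby(["genotype_id", "env_id"], sort=False)["BW"]
        .mean()
        .unstack()
    )
    recon = gge2.reconstruct()
    np.testing.assert_allclose(recon.to_numpy(), cell.to_numpy(), atol=1e-9)
    # scores carry the symmetric sqrt(singular value) scaling: with all axes
    # retained they multiply back to the environment-centered mean table
    full = g.gge_biplot(small_trial.phenotypes, "BW", n_axes=100)
    np.testing.assert_allclose(
        full.genotype_scores.to_numpy() @ full.env_scores.to_numpy().T,
        cell.to_numpy() - cell.mean(axis=0).to_numpy()[None, :],
        atol=1e-9,
    )


def test_gge_matches_brute_force_svd():
    rng = np.random.default_rng(8)
    rows = [
        dict(genotype_id=f"G{i}", env_id=f"E{j}", rep="R1", y=rng.normal())
        for i in range(20)
        for j in range(6)
    ]
    df = pd.DataFrame(rows)
    gge = g.gge_biplot(df, "y")
    M = df.pivot(index="genotype_id", columns="env_id", values="y")
    centered = M - M.mean(axis=0)
    s = np.linalg.svd(centered.to_numpy(), compute_uv=False)
    np.testing.assert_allclose(gge.explained_fraction, s**2 / (s**2).sum(), atol=1e-10)


def test_gge_missing_cells_raise():
    df = pd.DataFrame(
        [
            dict(genotype_id="G1", env_id="E1", rep="R1", y=1.0),
            dict(genotype_id="G1", env_id="E2", rep="R1", y=2.0),
            dict(genotype_id="G2", env_id="E1", rep="R1", y=3.0),
        ]
    )
    with pytest.raises(ValueError, match="missing"):
        g.gge_biplot(df, "y")
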