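import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gxetools as g
from conftest import jaccard, planted_two_factor_trial
from gxetools.key_windows import WindowProfiles


@pytest.fixture(scope="module")
def planted_fit():
    """One planted-signal trial with a fitted attribution forest."""
    weather, genotypes, phenotypes, truth = planted_two_factor_trial(
        seed=0, n_lines=3, n_envs=42
    )
    table = g.daily_factor_table(weather)
    feats = g.build_window_features(table)
    pcs = g.genotype_pcs(genotypes).scores
    X, y = g.assemble_samples(feats, phenotypes, "BW", genotype_pcs=pcs)
    model, train_r2 = g.fit_rf_for_trait(X, y, seed=0)
    profiles = g.smooth_profiles(g.attribution_profiles(model, X, trait="BW"))
    return X, y, model, train_r2, profiles, truth


def test_single_informative_feature_tops_importance():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(
        rng.normal(size=(80, 5)),
        columns=["tmax_1_5", "tmax_6_10", "pcp_1_5", "pcp_6_10", "PC1"],
    )
    y = pd.Series(3 * X["pcp_1_5"].to_numpy() + rng.normal(0, 0.1, 80))
    model, train_r2 = g.fit_rf_for_trait(X, y, n_estimators=100, seed=0)
    imp = pd.Series(model.feature_importances_, index=X.columns)
    assert imp.idxmax() == "pcp_1_5"
    assert train_r2 > 0.6
    # same seed, same predictions
    model2, _ = g.fit_rf_for_trait(X, y, n_estimators=100, seed=0)
    np.testing.assert_array_equal(model.predict(X), model2.predict(X))
    with pytest.raises(ValueError, match="50 samples"):
        g.fit_rf_for_trait(X.iloc[:20], y.iloc[:20])


def test_smooth_profile_examples_and_oracle():
    const = np.full(30, 2.5)
    np.testing.assert_allclose(g.smooth_profile(const, 5), const)
    impulse = np.zeros(21)
    impulse[10] = 1.0
    sm = g.smooth_profile(impulse, 5)
    np.testing.assert_allclose(sm[8:13], 0.2)
    assert sm[7] == 0 and sm[13] == 0
    # loop oracle with edge shrinkage
    rng = np.random.default_rng(1)
    vals = rng.normal(size=17)
    sm = g.smooth_profile(vals, 5)
    for i in range(17):
        lo, hi = max(0, i - 2), min(17, i + 3)
        assert sm[i] == pytest.approx(vals[lo:hi].mean())
    with pytest.raises(ValueError, match="odd"):
        g.smooth_profile(vals, span=4)


def _profiles_from(env_rows):
    env = pd.DataFrame(
        env_rows, columns=["key", "factor", "start", "end", "importance",
                           "mean_abs_shap", "mean_shap"]
    )
    return WindowProfiles(
        trait="BW",
        env_profiles=env,
        other_importance=pd.Series(dtype=float),
        shap_values=pd.DataFrame(),
        expected_value=0.0,
    )


def test_select_single_dominant_window():
    rows = [
        (g.feature_key("tmax", s, s + 4), "tmax", s, s + 4,
         1.0 if s == 50 else 0.0, 1.0 if s == 50 else 0.0, 0.0)
        for s in range(1, 146)
    ]
    # without smoothing the dominant window is the only significant one
    key_set = g.select_key_windows(_profiles_from(rows), tau=0.10, span=1)
    assert len(key_set.entries) == 1
    entry = key_set.entries.iloc[0]
    assert (entry.factor, entry.start_day, entry.end_day) == ("tmax", 50, 54)
    assert key_set.selected_keys == ["tmax_50_54"]


def test_overlapping_significant_windows_merge():
    rows = [
        (g.feature_key("tmax", s, s + 4), "tmax", s, s + 4,
         1.0 if 111 <= s <= 115 else 0.0, 1.0 if 111 <= s <= 115 else 0.0, 0.0)
        for s in range(1, 146)
    ]
    key_set = g.select_key_windows(_profiles_from(rows), tau=0.10, span=1)
    assert len(key_set.entries) == 1
    entry = key_set.entries.iloc[0]
    assert (entry.start_day, entry.end_day) == (111, 119)
    assert entry.n_windows == 5


def test_merge_matches_interval_union_oracle():
    rng = np.random.default_rng(3)
    rows = []
    sig_starts = {}
    for factor in ("tmax", "pcp"):
        starts = sorted(rng.choice(np.arange(1, 140), size=12, replace=False))
        sig_starts[factor] = set(starts)
        rows += [
            (g.feature_key(factor, s, s + 4), factor, s, s + 4,
             1.0 if s in sig_starts[factor] else 0.0,
             1.0 if s in sig_starts[factor] else 0.0, 0.0)
            for s in range(1, 146)
        ]
    key_set = g.select_key_windows(_profiles_from(rows), tau=0.5, span=1)
    for factor in ("tmax", "pcp"):
        # oracle: union of [s, s+4] intervals, merged when overlapping/adjacent
        intervals = []
        for s in sorted(sig_starts[factor]):
            if intervals and s <= intervals[-1][1] + 1:
                intervals[-1][1] = max(intervals[-1][1], s + 4)
            else:
                intervals.append([s, s + 4])
        got = key_set.entries.query("factor == @factor")[["start_day", "end_day"]]
        assert sorted(map(tuple, got.to_numpy().tolist())) == sorted(
            map(tuple, intervals)
        )
        # entries never overlap after merging
        spans = sorted(map(tuple, got.to_numpy().tolist()))
        assert all(b[0] > a[1] + 1 for a, b in zip(spans, spans[1:]))


def test_all_zero_profiles_warn_and_return_empty():
    rows = [
        (g.feature_key("tmax", s, s + 4), "tmax", s, s + 4, 0.0, 0.0, 0.0)
        for s in range(1, 146)
    ]
    with pytest.warns(UserWarning, match="zero"):
        key_set = g.select_key_windows(_profiles_from(rows))
    assert key_set.entries.empty and key_set.selected_keys == []


def test_local_accuracy_on_attribution_forest(planted_fit):
    X, y, model, train_r2, profiles, _ = planted_fit
    base = profiles.expected_value
    pred = model.predict(X.to_numpy())
    err = np.abs(base + profiles.shap_values.sum(axis=1).to_numpy() - pred).max()
    assert err < 1e-8
    assert np.isfinite(profiles.env_profiles.mean_abs_shap).all()
    # impurity importances sum to one over all features
    total = profiles.env_profiles.importance.sum() + profiles.other_importance.sum()
    assert total == pytest.approx(1.0)


def test_causal_window_outranks_noise(planted_fit):
    X, y, model, train_r2, profiles, truth = planted_fit
    env = profiles.env_profiles.set_index("key")
    causal = env.loc["rhmean_60_64", "mean_abs_shap"]
    noise = env.loc["dtr_20_24", "mean_abs_shap"]
    assert causal > noise
    assert train_r2 > 0.5
    # genotype PCs are profiled separately and never eligible as windows
    assert all(not k.startswith("PC") for k in env.index)
    assert any(k.startswith("PC") for k in profiles.other_importance.index)


def test_selection_recovers_planted_factors(planted_fit):
    X, y, model, train_r2, profiles, truth = planted_fit
    key_set = g.select_key_windows(profiles, tau=0.10)
    for w in truth.planted_windows:
        ent = key_set.entries.query("factor == @w.factor")
        assert not ent.empty
        best = max(
            jaccard(set(range(w.start_day, w.end_day + 1)),
                    set(range(int(r.start_day), int(r.end_day) + 1)))
            for _, r in ent.iterrows()
        )
        assert best >= 0.5


def test_selection_is_scale_free(planted_fit):
    X, y, model, train_r2, profiles, _ = planted_fit
    X_scaled = X.copy()
    rh_cols = [c for c in X.columns if c.startswith("rhmean_")]
    X_scaled[rh_cols] = X_scaled[rh_cols] * 1000.0
    model2, _ = g.fit_rf_for_trait(X_scaled, y, seed=0)
    profiles2 = g.smooth_profiles(g.attribution_profiles(model2, X_scaled, trait="BW"))
    a = g.select_key_windows(profiles, tau=0.10).entries
    b = g.select_key_windows(profiles2, tau=0.10).entries
    pd.testing.assert_frame_equal(
        a[["factor", "start_day", "end_day"]], b[["factor", "start_day", "end_day"]]
    )


def test_selected_feature_matrix_subsets(planted_fit):
    X, y, model, train_r2, profiles, _ = planted_fit
    key_set = g.select_key_windows(profiles, tau=0.10)
    X_sel = g.selected_feature_matrix(X, key_set)
    assert set(key_set.selected_keys) <= set(X_sel.columns)
    assert all(c in X.columns for c in X_sel.columns)
    assert any(c.startswith("PC") for c in X_sel.columns)


def test_shap_dependence_export(planted_fit):
    X, y, model, train_r2, profiles, truth = planted_fit
    w = truth.planted_windows[0]
    key = g.feature_key(w.factor, w.start_day, w.start_day + 4)
    table = g.shap_dependence_export(model, X, key, profiles=profiles)
    assert len(table) == len(X)
    rho = stats.spearmanr(table.value, table.shap).statistic
    assert np.sign(rho) == np.sign(w.effect)
    with pytest.raises(KeyError):
        g.shap_dependence_export(model, X, "tmax_999_1003", profiles=profiles)
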