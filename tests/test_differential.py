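import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duomics.datatypes import ValidationError
from duomics import differential as dm

from conftest import two_group_frame


def test_fit_contrast_exact_two_point_case():
    X = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], index=["f"], columns=list("abcd"))
    groups = pd.Series(["control", "control", "alcohol", "alcohol"], index=list("abcd"))
    fit = dm.fit_contrast(X, groups)
    assert fit.loc["f", "effect"] == 1.0
    assert fit.loc["f", "sigma2"] == 0.0
    assert fit.loc["f", "df"] == 2


def test_unit_weights_reproduce_pooled_two_sample_estimator(rng):
    X, groups = two_group_frame(rng, n_features=20)
    fit = dm.fit_contrast(X, groups)
    w = pd.DataFrame(1.0, index=X.index, columns=X.columns)
    fit_w = dm.fit_contrast(X, groups, weights=w)
    pd.testing.assert_frame_equal(fit, fit_w)
    # classical pooled t equals effect / (se_unscaled * sigma)
    a = X.loc[:, (groups == "alcohol").to_numpy()]
    c = X.loc[:, (groups == "control").to_numpy()]
    t_ref = stats.ttest_ind(a, c, axis=1).statistic
    t_ours = (fit["effect"] / (fit["se_unscaled"] * np.sqrt(fit["sigma2"]))).to_numpy()
    np.testing.assert_allclose(t_ours, t_ref, rtol=1e-10)


def test_fit_contrast_sample_order_invariant(rng):
    X, groups = two_group_frame(rng, n_features=10)
    perm = rng.permutation(X.columns)
    fit1 = dm.fit_contrast(X, groups)
    fit2 = dm.fit_contrast(X[perm], groups.loc[perm])
    pd.testing.assert_frame_equal(fit1, fit2)


def test_fit_contrast_needs_two_per_group():
    X = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=list("abc"))
    groups = pd.Series(["control", "alcohol", "alcohol"], index=list("abc"))
    with pytest.raises(ValidationError):
        dm.fit_contrast(X, groups)


def test_moderate_limits(rng):
    X, groups = two_group_frame(rng, n_features=200)
    fit = dm.fit_contrast(X, groups)
    # d0 = 0 degrades to the ordinary t
    mod0 = dm.moderate(fit, prior_df=0.0)
    t_ord = fit["effect"] / (fit["se_unscaled"] * np.sqrt(fit["sigma2"]))
    np.testing.assert_allclose(mod0["t"].to_numpy(), t_ord.to_numpy(), rtol=1e-12)
    # d0 = inf uses the prior variance everywhere
    mod_inf = dm.moderate(fit, prior_df=np.inf, prior_var=0.25)
    t_pool = fit["effect"] / (fit["se_unscaled"] * 0.5)
    np.testing.assert_allclose(mod_inf["t"].to_numpy(), t_pool.to_numpy(), rtol=1e-12)


def test_moderate_identical_variances_pools_with_warning(rng):
    X, groups = two_group_frame(rng, n_features=5)
    fit = dm.fit_contrast(X, groups)
    fit["sigma2"] = 0.25
    with pytest.warns(UserWarning):
        mod = dm.moderate(fit)
    # fully pooled: one shared posterior variance near the common value
    # (the log-scale moment estimate carries a small upward bias term)
    assert mod["s2_post"].nunique() == 1
    np.testing.assert_allclose(mod["s2_post"].to_numpy(), 0.25, rtol=0.1)


def test_moderated_p_uniform_under_null(rng):
    """Gaussian null data, 2000 features: raw moderated p is ~uniform."""
    X, groups = two_group_frame(rng, n_features=2000, effect=0.0)
    fit = dm.fit_contrast(X, groups)
    mod = dm.moderate(fit)
    ks = stats.kstest(mod["p_value"].to_numpy(), "uniform").statistic
    assert ks < 0.05


def _bh_oracle(p):
    """Step-up oracle: literal definition, O(m^2)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def test_bh_matches_oracle_on_all_small_permutations():
    base = np.array([0.01, 0.02, 0.04, 0.3, 0.7, 1.0])
    for k in range(1, len(base) + 1):
        for perm in itertools.permutations(base[:k]):
            p = np.array(perm)
            np.testing.assert_allclose(dm.bh_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_worked_example_and_validation():
    np.testing.assert_allclose(dm.bh_adjust(np.array([0.02, 0.04, 0.01])),
                               [0.03, 0.04, 0.03])
    np.testing.assert_allclose(dm.bh_adjust(np.array([0.2])), [0.2])
    with pytest.raises(ValidationError):
        dm.bh_adjust(np.array([-0.1, 0.5]))


def _toy_table():
    return pd.DataFrame({
        "feature_id": [f"f{i}" for i in range(6)],
        "t": [3.0, 2.5, -4.0, -0.5, 1.0, -2.0],
        "adj_p": [0.01, 0.05, 0.001, 0.9, 0.4, 0.09],
    }, index=[f"f{i}" for i in range(6)])


def test_call_and_rank_direction_rule():
    out = dm.call_and_rank(_toy_table(), alpha=0.1, k=10)
    assert out.loc["f0", "direction"] == "up"
    assert out.loc["f2", "direction"] == "down"
    assert out.loc["f3", "direction"] == "ns"
    assert out.loc["f4", "direction"] == "ns"
    # direction is ns exactly when adj_p > alpha
    assert ((out["direction"] == "ns") == (out["adj_p"] > 0.1)).all()


def test_call_and_rank_topk_truncates_to_called():
    out = dm.call_and_rank(_toy_table(), alpha=0.1, k=10)
    up_ranked = out.dropna(subset=["rank_up"])
    assert len(up_ranked) == 2          # only 2 up-called features exist
    assert out.loc["f0", "rank_up"] == 1.0
    none = dm.call_and_rank(_toy_table().assign(adj_p=0.5), alpha=0.1)
    assert (none["direction"] == "ns").all()


def test_call_and_rank_tie_break_deterministic():
    tab = _toy_table()
    tab.loc["f0", "t"] = 2.5   # tie with f1 on |t|
    out = dm.call_and_rank(tab, alpha=0.1, k=10)
    assert out.loc["f0", "rank_up"] == 1.0  # lexicographic f0 before f1
    assert out.loc["f1", "rank_up"] == 2.0


def test_analysis_fit_summary(rng):
    X, groups = two_group_frame(rng, n_features=100, effect=1.0)
    res = dm.DifferentialAnalysis(X, groups, tissue="liver", layer="proteome").fit()
    assert set(res.table.columns) >= {"feature_id", "effect", "t", "p_value",
                                      "adj_p", "direction"}
    s = res.summary()
    assert "prior_df" in s["field"].to_list()
    assert (res.table["adj_p"] <= 1).all() and (res.table["adj_p"] >= 0).all()
    # a uniform planted shift of +1 should be called up far more often than down
    assert len(res.called("up")) > 10 * max(1, len(res.called("down")))
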