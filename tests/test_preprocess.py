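import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from duomics.datatypes import ConfigurationError, ValidationError
from duomics import preprocess as prep


def toy_counts():
    cols = ["l1", "l2", "m1", "m2", "m3"]
    groups = pd.Series(["liver", "liver", "muscle", "muscle", "muscle"], index=cols)
    counts = pd.DataFrame(
        [
            [0, 0, 0, 0, 0],          # all-zero: removed
            [100, 120, 90, 80, 110],  # high everywhere: kept
            [100, 120, 0, 0, 0],      # high in every liver sample: kept
            [100, 0, 0, 0, 0],        # high in only 1 of 2 liver: fails min_prop=1
            [3, 2, 4, 3, 2],          # under the CPM cutoff: removed
        ],
        index=[f"g{i}" for i in range(5)],
        columns=cols,
        dtype=float,
    )
    # pad every sample's library so cutoffs are stable
    counts.loc["pad"] = 5000.0
    return counts, groups


def test_expression_filter_stated_rule():
    counts, groups = toy_counts()
    kept = prep.filter_low_expression(counts, groups, min_count=10, min_prop=1.0, min_total=15)
    assert list(kept.index) == ["g1", "g2", "pad"]


def test_expression_filter_min_prop_one_strict():
    """One below-cutoff sample in a group disqualifies that group."""
    counts, groups = toy_counts()
    kept = prep.filter_low_expression(counts, groups)
    assert "g3" not in kept.index
    # relaxing min_prop rescues the feature via the liver group
    kept_half = prep.filter_low_expression(counts, groups, min_prop=0.5)
    assert "g3" in kept_half.index


def test_tmm_identical_and_depth_scaled_columns():
    rng = np.random.default_rng(0)
    base = rng.integers(10, 1000, size=200).astype(float)
    counts = pd.DataFrame({"a": base, "b": base}, index=[f"g{i}" for i in range(200)])
    f = prep.tmm_factors(counts)
    np.testing.assert_allclose(f.to_numpy(), [1.0, 1.0], atol=1e-12)

    counts2 = pd.DataFrame({"a": base, "b": 2 * base}, index=counts.index)
    f2 = prep.tmm_factors(counts2)
    # pure depth difference carries no composition change
    np.testing.assert_allclose(f2.to_numpy(), [1.0, 1.0], atol=1e-9)


def test_tmm_factors_geometric_mean_one():
    rng = np.random.default_rng(1)
    counts = pd.DataFrame(
        rng.negative_binomial(5, 0.01, size=(300, 6)).astype(float),
        index=[f"g{i}" for i in range(300)], columns=list("abcdef"))
    f = prep.tmm_factors(counts)
    assert abs(np.mean(np.log(f))) < 1e-12
    assert (f > 0).all()


def test_voom_log2cpm_offset_formula(rng):
    counts = pd.DataFrame(
        rng.poisson(100, size=(50, 6)).astype(float),
        index=[f"g{i}" for i in range(50)], columns=list("abcdef"))
    counts.iloc[0, 0] = 7.0
    lib = counts.sum(axis=0)
    factors = pd.Series(1.0, index=counts.columns)
    # rescale library of sample a to 749,999 via the padding gene
    counts.loc["pad"] = 0.0
    counts.loc["pad", "a"] = 749_999 - lib["a"] - 7 + counts.iloc[0, 0]
    counts.loc["pad", list("bcdef")] = 500.0
    groups = pd.Series(["x", "x", "x", "y", "y", "y"], index=counts.columns)
    log2cpm, weights = prep.voom_transform(counts, factors, groups)
    expect = np.log2((7 + 0.5) / (counts.sum(axis=0)["a"] + 1) * 1e6)
    assert log2cpm.loc["g0", "a"] == pytest.approx(expect)
    assert np.isfinite(log2cpm.to_numpy()).all()       # zeros stay finite
    assert (weights.to_numpy() > 0).all()


def test_voom_constant_variance_near_flat_weights():
    rng = np.random.default_rng(7)
    n, s = 300, 12
    lam = 2.0 ** rng.uniform(6, 10, size=n)
    counts = pd.DataFrame(
        (lam[:, None] * rng.lognormal(0.0, 0.05, size=(n, s))).round(),
        index=[f"g{i}" for i in range(n)], columns=[f"s{j}" for j in range(s)])
    groups = pd.Series(["x"] * 6 + ["y"] * 6, index=counts.columns)
    factors = prep.tmm_factors(counts)
    _, weights = prep.voom_transform(counts, factors, groups)
    w = weights.to_numpy()
    assert w.max() / w.min() < 2.0


def test_missingness_filter_fractions_and_strictness():
    cols = [f"q{i}" for i in range(4)] + [f"e{i}" for i in range(5)]
    qc_mask = pd.Series([True] * 4 + [False] * 5, index=cols)
    vals = pd.DataFrame(1.0, index=["full", "qc75", "qc50", "exp100"], columns=cols)
    vals.loc["qc75", ["q0", "q1", "q2"]] = np.nan        # 75% QC missing -> removed
    vals.loc["qc50", ["q0", "q1"]] = np.nan              # exactly 50% -> retained
    vals.loc["exp100", ["e0", "e1", "e2", "e3", "e4"]] = np.nan  # 100% exp -> removed
    out = prep.filter_missingness(vals, qc_mask=qc_mask, qc_max=0.5, exp_max=0.8)
    assert list(out.index) == ["full", "qc50"]

    # proteome rule: overall fraction, strict
    vals2 = pd.DataFrame(1.0, index=["a", "b"], columns=cols[:4])
    vals2.loc["b", ["q0", "q1", "q2"]] = np.nan
    out2 = prep.filter_missingness(vals2, overall_max=0.5)
    assert list(out2.index) == ["a"]


def test_knn_identity_on_complete(rng):
    df = pd.DataFrame(rng.normal(size=(10, 5)), index=[f"f{i}" for i in range(10)])
    out, n = prep.impute_knn(df, k=3)
    pd.testing.assert_frame_equal(out, df)
    assert n == 0


def test_knn_single_neighbor_oracle():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0]],
        index=["f1", "f2", "f3"], columns=["a", "b", "c"])
    out, n = prep.impute_knn(df, k=1)
    assert out.loc["f2", "c"] == pytest.approx(3.0)
    assert n == 1


def test_knn_imputed_values_within_neighbor_range(rng):
    df = pd.DataFrame(rng.normal(10, 2, size=(30, 8)))
    mask = rng.random(df.shape) < 0.1
    df = df.mask(mask & (df.notna().sum(axis=1) > 2).to_numpy()[:, None])
    df = df.dropna(how="all")
    out, _ = prep.impute_knn(df, k=5)
    assert out.notna().all().all()
    assert out.to_numpy().min() >= df.min().min() - 1e-9
    assert out.to_numpy().max() <= df.max().max() + 1e-9


def test_pqn_recovers_planted_dilution(rng):
    ref = pd.Series(rng.lognormal(3, 1, size=40), index=[f"f{i}" for i in range(40)])
    mat = pd.DataFrame({"s1": ref * 2.0, "s2": ref, "s3": ref * 0.5})
    out, factors = prep.pqn_normalize(mat, reference=ref)
    np.testing.assert_allclose(factors.to_numpy(), [2.0, 1.0, 0.5])
    for c in out.columns:
        np.testing.assert_allclose(out[c].to_numpy(), ref.to_numpy())


def test_pqn_identity_when_equal_to_reference(rng):
    ref = pd.Series(rng.lognormal(3, 1, size=30), index=[f"f{i}" for i in range(30)])
    mat = pd.DataFrame({"s1": ref, "s2": ref})
    out, factors = prep.pqn_normalize(mat, reference=ref)
    np.testing.assert_allclose(factors.to_numpy(), [1.0, 1.0])
    pd.testing.assert_frame_equal(out, mat)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pqn_median_quotient_one_after_correction(seed):
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.lognormal(2, 1, size=(21, 5)),
                       index=[f"f{i}" for i in range(21)])
    out, _ = prep.pqn_normalize(mat)
    ref = prep.replace_zeros_half_min(mat).median(axis=1)
    med_q = out.div(ref, axis=0).median(axis=0)
    np.testing.assert_allclose(med_q.to_numpy(), 1.0, rtol=1e-9)


def _drift_run(rng, rate=0.01, qc_noise=0.0, n_feat=20):
    order = pd.Series(np.arange(1, 24), index=[f"s{i}" for i in range(23)])
    qc = pd.Series([i % 4 == 0 for i in range(23)], index=order.index)
    base = rng.lognormal(5, 0.5, size=n_feat)
    drift = 1.0 + rate * order.to_numpy()
    vals = pd.DataFrame(np.outer(base, drift), index=[f"f{i}" for i in range(n_feat)],
                        columns=order.index)
    noise = rng.normal(0, qc_noise, size=vals.shape)
    vals = vals * np.exp(noise)
    return vals, order, qc


def test_qc_rlsc_identity_without_drift(rng):
    vals, order, qc = _drift_run(rng, rate=0.0)
    out = prep.qc_rlsc(vals, order, qc)
    np.testing.assert_allclose(out.to_numpy(), vals.to_numpy(), rtol=1e-6)


def test_qc_rlsc_removes_linear_drift(rng):
    vals, order, qc = _drift_run(rng, rate=0.01)
    before = vals.loc[:, qc.to_numpy()]
    cv_before = (before.std(axis=1, ddof=1) / before.mean(axis=1)).median()
    out = prep.qc_rlsc(vals, order, qc)
    after = out.loc[:, qc.to_numpy()]
    cv_after = (after.std(axis=1, ddof=1) / after.mean(axis=1)).median()
    assert cv_after < 0.01
    assert cv_after < cv_before


def test_qc_rlsc_preserves_sample_rank_order(rng):
    vals, order, qc = _drift_run(rng, rate=0.01, qc_noise=0.0)
    # inject sample-level signal on one feature, monotone in an arbitrary order
    exp = ~qc
    sig = np.linspace(1.0, 2.0, int(exp.sum()))
    perm = rng.permutation(len(sig))
    vals.iloc[0, np.flatnonzero(exp.to_numpy())] *= sig[perm]
    out = prep.qc_rlsc(vals, order, qc)
    # after removing the drift, sample ranks equal the true signal's ranks
    true_rank = np.argsort(sig[perm])
    after_rank = np.argsort(out.iloc[0, np.flatnonzero(exp.to_numpy())].to_numpy())
    np.testing.assert_array_equal(true_rank, after_rank)


def test_qc_rlsc_skips_with_few_qcs(rng):
    vals, order, qc = _drift_run(rng, rate=0.01)
    qc[:] = False
    qc.iloc[[0, 10]] = True
    out = prep.qc_rlsc(vals, order, qc, min_qc=5)
    pd.testing.assert_frame_equal(out, vals)


def test_cv_filter_boundaries():
    cols = ["q1", "q2", "q3", "e1"]
    qc = pd.Series([True, True, True, False], index=cols)
    vals = pd.DataFrame(
        [
            [5.0, 5.0, 5.0, 9.0],     # CV 0: kept
            [1.0, 2.0, 3.0, 9.0],     # CV 50%: removed
        ],
        index=["const", "wide"], columns=cols)
    out = prep.cv_filter(vals, qc, max_cv=0.30)
    assert list(out.index) == ["const"]
    # strict "larger than": a feature sitting exactly at the cutoff is kept
    qc_vals = vals.loc["wide", ["q1", "q2", "q3"]]
    cv_exact = float(qc_vals.std(ddof=1) / qc_vals.mean())
    at_cutoff = prep.cv_filter(vals, qc, max_cv=cv_exact)
    assert "wide" in at_cutoff.index
    with pytest.raises(ConfigurationError):
        prep.cv_filter(vals, pd.Series([True, False, False, False], index=cols))


def test_kegg_filter_contract():
    vals = pd.DataFrame(np.ones((5, 2)), index=[f"m{i}" for i in range(5)])
    flags = pd.Series([True, False, True, False, True], index=vals.index)
    out = prep.kegg_filter(vals, flags)
    assert list(out.index) == ["m0", "m2", "m4"]
    assert prep.kegg_filter(vals, pd.Series(True, index=vals.index)).equals(vals)
    assert prep.kegg_filter(vals, pd.Series(False, index=vals.index)).empty


def test_aggregate_columns_mean_and_passthrough():
    a = pd.DataFrame({"s1": [4.0, 1.0], "s2": [2.0, 3.0]}, index=["shared", "only_a"])
    b = pd.DataFrame({"s1": [6.0, 7.0], "s2": [4.0, 8.0]}, index=["shared", "only_b"])
    merged, prov = prep.aggregate_columns(a, b)
    assert merged.loc["shared", "s1"] == 5.0
    assert merged.loc["only_a", "s1"] == 1.0
    assert merged.loc["only_b", "s2"] == 8.0
    assert prov.to_dict() == {"shared": "both", "only_a": "a", "only_b": "b"}
    again, _ = prep.aggregate_columns(a, a)
    pd.testing.assert_frame_equal(again, a.sort_index())
    with pytest.raises(ValidationError):
        prep.aggregate_columns(a, b.rename(columns={"s2": "s9"}))


def test_pcpe_ratio_forced_arithmetic_and_scale_invariance():
    classes = pd.Series(["PC", "PC", "PE", "TG"], index=["l1", "l2", "l3", "l4"])
    vals = pd.DataFrame({"s1": [6.0, 4.0, 5.0, 85.0], "s2": [6.0, 4.0, 5.0, 85.0]},
                        index=classes.index)
    vals["s2"] *= 3.0
    out = prep.pcpe_ratio(vals, classes)
    assert out.loc["s1", "pc_percent"] == pytest.approx(10.0)
    assert out.loc["s1", "pe_percent"] == pytest.approx(5.0)
    assert out.loc["s1", "pc_pe_ratio"] == pytest.approx(2.0)
    assert out.loc["s2", "pc_pe_ratio"] == pytest.approx(out.loc["s1", "pc_pe_ratio"])


def test_pcpe_ratio_zero_pe_is_error():
    classes = pd.Series(["PC", "PE"], index=["l1", "l2"])
    vals = pd.DataFrame({"s1": [1.0, 0.0]}, index=classes.index)
    with pytest.raises(ValidationError):
        prep.pcpe_ratio(vals, classes)


def test_metabolome_cascade_near_identity_on_clean_data():
    """With no drift and near-noiseless QCs, everything downstream of PQN
    (drift correction, CV/KEGG filters, log2, aggregation) barely moves a
    single-column feature's group-difference t-statistic."""
    from scipy import stats
    from conftest import small_sim_config
    from duomics.simulate import generate_study
    from duomics.preprocess import preprocess_metabolome, pqn_normalize

    cfg = small_sim_config(seed=9, drift_amplitude=0.0, intensity_noise_sd=0.3,
                           qc_noise_sd=0.001, kegg_frac=1.0)
    bundle = generate_study(cfg)
    out, provenance, _ = preprocess_metabolome(
        bundle.layers["metabolome_c18"], bundle.layers["metabolome_amide"],
        bundle.samples, bundle.features.kegg_flags())
    meta = bundle.samples.experimental("liver")
    cols = [c for c in meta["sample_id"] if c in out.values.columns]
    groups = meta.set_index("sample_id").loc[cols, "group"]
    alc = (groups == "alcohol").to_numpy()
    raw = bundle.layers["metabolome_c18"].values
    qc_mask = bundle.samples.for_samples(raw.columns)["role"] == "qc"
    baseline = np.log2(pqn_normalize(raw, qc_mask=qc_mask)[0])
    a_only = [f for f in out.values.index if provenance[f] == "a"]
    assert len(a_only) >= 10
    for f in a_only:
        x_base = baseline.loc[f, cols].to_numpy()
        x_out = out.values.loc[f, cols].to_numpy()
        t_base = stats.ttest_ind(x_base[alc], x_base[~alc]).statistic
        t_out = stats.ttest_ind(x_out[alc], x_out[~alc]).statistic
        assert abs(t_base - t_out) < max(0.01, 1e-3 * abs(t_base))
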