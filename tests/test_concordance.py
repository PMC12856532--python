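import math

import numpy as np
import pandas as pd
import pytest

from duomics.datatypes import ValidationError
from duomics import concordance as cc


def _paired_lists(rng, n=20):
    idx = [f"s{i:03d}" for i in range(n)]
    t1 = pd.Series(rng.normal(size=n), index=idx)
    return t1


def test_intersect_layers_one_to_one_only():
    gene = pd.DataFrame({"feature_id": ["g1", "g2", "g3"], "t": [1.0, 2.0, 3.0]})
    prot = pd.DataFrame({"feature_id": ["p1", "p2", "p3"], "t": [1.5, 2.5, 3.5]})
    gsym = pd.Series(["A", "B", "C"], index=["g1", "g2", "g3"])
    psym = pd.Series(["A", "B", "B"], index=["p1", "p2", "p3"])  # B ambiguous
    with pytest.raises(ValidationError):
        cc.intersect_layers(gene, prot, gsym, psym)   # only 1 pair -> degenerate


def test_intersect_layers_idempotent(rng):
    n = 30
    ids = [f"g{i}" for i in range(n)]
    tab = pd.DataFrame({"feature_id": ids, "t": rng.normal(size=n)})
    sym = pd.Series([f"S{i}" for i in range(n)], index=ids)
    paired = cc.intersect_layers(tab, tab, sym, sym)
    np.testing.assert_allclose(paired["t_gene"], paired["t_protein"])
    assert len(paired) == n


def test_intersect_layers_disjoint_symbols_error():
    n = 15
    g = pd.DataFrame({"feature_id": [f"g{i}" for i in range(n)], "t": np.arange(n, dtype=float)})
    p = pd.DataFrame({"feature_id": [f"p{i}" for i in range(n)], "t": np.arange(n, dtype=float)})
    gs = pd.Series([f"GA{i}" for i in range(n)], index=g["feature_id"])
    ps = pd.Series([f"PB{i}" for i in range(n)], index=p["feature_id"])
    with pytest.raises(ValidationError):
        cc.intersect_layers(g, p, gs, ps)


def test_rrho_identical_lists_corner_value(rng):
    t = _paired_lists(rng, n=20)
    m = cc.rrho(t, t.copy(), step=10)
    # grid point (10, 10): overlap forced to 10, P(X >= 10) = 1 / C(20, 10)
    i = list(m.thresholds).index(10)
    assert m.overlap[i, i] == 10
    expect = -math.log10(1 / math.comb(20, 10))
    assert m.signed_log_p[i, i] == pytest.approx(expect, abs=1e-9)
    assert expect == pytest.approx(5.2666, abs=1e-3)


def test_rrho_reversed_list_under_enrichment(rng):
    t = _paired_lists(rng, n=20)
    m = cc.rrho(t, -t, step=10)
    i = list(m.thresholds).index(10)
    assert m.overlap[i, i] == 0
    assert m.signed_log_p[i, i] < 0     # under-enrichment sign


def test_rrho_full_list_corner_is_p_one(rng):
    t = _paired_lists(rng, n=30)
    m = cc.rrho(t, pd.Series(np.random.default_rng(1).normal(size=30), index=t.index), step=5)
    assert m.overlap[-1, -1] == 30
    assert m.signed_log_p[-1, -1] == pytest.approx(0.0, abs=1e-12)


def test_rrho_symmetric_under_list_swap(rng):
    t1 = _paired_lists(rng, n=40)
    t2 = pd.Series(rng.normal(size=40), index=t1.index)
    m12 = cc.rrho(t1, t2, step=8)
    m21 = cc.rrho(t2, t1, step=8)
    np.testing.assert_allclose(m12.signed_log_p, m21.signed_log_p.T, atol=1e-12)


def test_rrho_grid_matches_exact_tails(rng):
    from scipy import stats
    t1 = _paired_lists(rng, n=24)
    t2 = pd.Series(rng.normal(size=24), index=t1.index)
    m = cc.rrho(t1, t2, step=6)
    r1 = pd.Series(np.arange(1, 25), index=sorted(t1.index, key=lambda f: (-t1[f], f)))
    r2 = pd.Series(np.arange(1, 25), index=sorted(t2.index, key=lambda f: (-t2[f], f)))
    for a, na in enumerate(m.thresholds):
        for b, nb in enumerate(m.thresholds):
            k = sum((r1[f] <= na) and (r2[f] <= nb) for f in t1.index)
            assert m.overlap[a, b] == k
            dist = stats.hypergeom(24, na, nb)
            expect = min(dist.sf(k - 1), dist.cdf(k))
            assert abs(m.signed_log_p[a, b]) == pytest.approx(
                -math.log10(max(expect, 1e-320)), abs=1e-9)


def test_rrho_step_validation(rng):
    t = _paired_lists(rng, n=10)
    with pytest.raises(ValidationError):
        cc.rrho(t, t, step=10)


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _es_bruteforce(t_sorted_desc, member_mask, weight):
    """O(N) literal running sum; also reports whether the positive and
    negative extremes tie in magnitude (the sign is then ambiguous)."""
    N = len(t_sorted_desc)
    S = member_mask.sum()
    w = np.abs(t_sorted_desc[member_mask]) ** weight
    total = w.sum() if w.sum() > 0 else S
    if w.sum() == 0:
        w = np.ones(S)
    run = 0.0
    best = 0.0
    hi, lo = 0.0, 0.0
    wi = 0
    for i in range(N):
        if member_mask[i]:
            run += w[wi] / total
            wi += 1
        else:
            run -= 1.0 / (N - S)
        hi, lo = max(hi, run), min(lo, run)
        if abs(run) > abs(best):
            best = run
    tied = abs(hi - (-lo)) < 1e-9
    return best, tied


def test_es_single_member_rank_one_weight_zero():
    abs_t = np.linspace(5, 0.1, 10)
    es = cc.enrichment_score(abs_t, np.array([0]), weight=0.0)
    assert es == pytest.approx(1.0)


def test_es_matches_bruteforce_oracle(rng):
    for _ in range(200):
        N = int(rng.integers(10, 200))
        t = np.sort(rng.normal(size=N))[::-1]
        S = int(rng.integers(1, max(2, N // 3)))
        pos = rng.choice(N, size=S, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[pos] = True
        for weight in (0.0, 1.0):
            expect, tied = _es_bruteforce(t, mask, weight)
            got = cc.enrichment_score(np.abs(t), np.flatnonzero(mask), weight)
            assert abs(got) == pytest.approx(abs(expect), abs=1e-9)
            if not tied:
                assert got == pytest.approx(expect, abs=1e-9)


def test_gsea_planted_top_set_has_highest_abs_nes(rng):
    n = 150
    idx = [f"g{i:03d}" for i in range(n)]
    t = pd.Series(np.sort(rng.normal(size=n))[::-1], index=idx)
    sets = {"planted": set(idx[:12])}
    for i in range(20):
        sets[f"decoy{i:02d}"] = set(rng.choice(idx, size=12, replace=False))
    res = cc.gsea_preranked(t, sets, n_perm=500, seed=5)
    best = res.reindex(res["nes"].abs().sort_values(ascending=False).index).iloc[0]
    assert best["set_name"] == "planted"
    assert best["nes"] > 0
    assert bool(best["significant"])


def test_gsea_rejects_flat_scores():
    t = pd.Series(1.0, index=[f"g{i}" for i in range(20)])
    with pytest.raises(ValidationError):
        cc.gsea_preranked(t, {"s": set(t.index[:5])})


def test_gsea_seed_reproducible(rng):
    idx = [f"g{i}" for i in range(60)]
    t = pd.Series(rng.normal(size=60), index=idx)
    sets = {"a": set(idx[:10]), "b": set(idx[20:35])}
    r1 = cc.gsea_preranked(t, sets, n_perm=100, seed=3)
    r2 = cc.gsea_preranked(t, sets, n_perm=100, seed=3)
    pd.testing.assert_frame_equal(r1, r2)


def test_cross_layer_heatmap_rules():
    def frame(sig, nes):
        return pd.DataFrame({"set_name": ["S"], "nes": [nes], "significant": [sig]})

    results = {
        ("liver", "G"): frame(True, 2.0),
        ("liver", "P"): frame(True, 1.5),
        ("muscle", "G"): frame(False, 0.5),
        ("muscle", "P"): frame(False, -0.5),
    }
    out = cc.cross_layer_heatmap(results)
    assert list(out["set_name"]) == ["S"]            # concordant in liver
    assert out.loc[0, "liver_G"] == 1 and out.loc[0, "liver_P"] == 1

    results[("liver", "P")] = frame(False, 1.5)       # significance lost at P
    out2 = cc.cross_layer_heatmap(results)
    assert out2.empty

    results[("liver", "P")] = frame(True, -1.5)       # opposite signs
    out3 = cc.cross_layer_heatmap(results)
    assert out3.empty
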