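"""Threshold-free transcriptome-proteome concordance.

Two tools on the intersected gene/protein space, both rank-based on
moderated t-scores:

* a signed rank-rank hypergeometric overlap (RRHO) map: for every pair of
  rank cutoffs the overlap of the two top lists is scored with exact
  hypergeometric tails, signed -log10 of the smaller tail (positive =
  over-enrichment), with Benjamini-Yekutieli correction over the grid;
* preranked gene-set enrichment (GSEA): weighted Kolmogorov-Smirnov-like
  running-sum enrichment scores, normalized against a set-size-preserving
  label-sampling null, significant at BH-adjusted p <= 0.1 with sign from
  the normalized score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError

log = logging.getLogger("duomics")


def intersect_layers(gene_table: pd.DataFrame, protein_table: pd.DataFrame,
                     gene_symbols: pd.Series, protein_symbols: pd.Series) -> pd.DataFrame:
    """Pair gene and protein t-scores over one-to-one shared symbols.

    Features whose symbol maps to more than one feature within a layer are
    dropped (with a logged count); the result holds one row per shared
    symbol with ``t_gene`` and ``t_protein``.
    """
    def unique_map(table, symbols, col):
        m = symbols.reindex(table["feature_id"]).dropna()
        dup = m.duplicated(keep=False)
        if dup.any():
            log.info("dropping %d features with ambiguous symbols", int(dup.sum()))
        m = m[~dup]
        t = table.set_index("feature_id").loc[m.index, "t"]
        return pd.DataFrame({col: t.to_numpy()}, index=m.to_numpy())

    g = unique_map(gene_table, gene_symbols, "t_gene")
    p = unique_map(protein_table, protein_symbols, "t_protein")
    paired = g.join(p, how="inner")
    if len(paired) < 10:
        raise ValidationError(f"only {len(paired)} intersected features; map degenerate")
    paired.index.name = "symbol"
    return paired.sort_index()


@dataclass
class RRHOMap:
    """Signed rank-rank hypergeometric overlap map on a step grid."""

    step: int
    thresholds: np.ndarray       # rank cutoffs along each axis
    overlap: np.ndarray          # overlap counts, list1 cutoffs x list2 cutoffs
    signed_log_p: np.ndarray     # signed -log10 raw smaller-tail p
    signed_log_p_adj: np.ndarray # same after BY correction over the grid
    boundary1: int               # index of the t=0 sign change in list 1
    boundary2: int

    def quadrant_max(self) -> dict:
        b1 = np.searchsorted(self.thresholds, self.boundary1, side="right")
        b2 = np.searchsorted(self.thresholds, self.boundary2, side="right")
        # ranking is descending in t, so small cutoffs are the up-regulated end
        s = self.signed_log_p_adj
        return {
            "up_up": float(s[:b1, :b2].max()) if b1 and b2 else np.nan,
            "up_down": float(s[:b1, b2:].max()) if b1 and b2 < s.shape[1] else np.nan,
            "down_up": float(s[b1:, :b2].max()) if b1 < s.shape[0] and b2 else np.nan,
            "down_down": float(s[b1:, b2:].max()) if b1 < s.shape[0] and b2 < s.shape[1] else np.nan,
        }


def rrho(t1: pd.Series, t2: pd.Series, step: int | None = None) -> RRHOMap:
    """Rank-rank hypergeometric overlap of two paired t-score lists.

    Both lists are ranked descending (strongest up-regulation first) with
    lexicographic tie-break.  At grid point (i, j) the overlap k of the two
    top lists is scored with P(X >= k) and P(X <= k); the map records the
    signed -log10 of the smaller tail (negative = under-enrichment) and its
    Benjamini-Yekutieli-corrected counterpart.
    """
    if not t1.index.equals(t2.index):
        t2 = t2.reindex(t1.index)
    if t2.isna().any():
        raise ValidationError("lists are not paired over the same features")
    N = len(t1)
    if step is None:
        step = int(np.ceil(N / 100))
    if step < 1 or step >= N:
        raise ValidationError(f"step must be in [1, N); got {step} for N={N}")

    def ranks(t):
        order = sorted(t.index, key=lambda f: (-t[f], f))
        return pd.Series(np.arange(1, N + 1), index=order)

    r1, r2 = ranks(t1), ranks(t2)
    thresholds = np.arange(step, N + 1, step)
    if thresholds[-1] != N:
        thresholds = np.append(thresholds, N)
    # 2-D cumulative count of features by (rank1, rank2); half-offset edges
    # so a rank exactly at a cutoff counts toward that cutoff
    edges = np.r_[0, thresholds] + 0.5
    H, _, _ = np.histogram2d(r1[t1.index], r2[t1.index], bins=[edges, edges])
    overlap = H.cumsum(axis=0).cumsum(axis=1)
    n_grid = len(thresholds)
    signed = np.zeros((n_grid, n_grid))
    pvals = np.ones((n_grid, n_grid))
    for a in range(n_grid):
        na = thresholds[a]
        for b in range(n_grid):
            nb = thresholds[b]
            k = int(overlap[a, b])
            dist = stats.hypergeom(N, na, nb)
            p_over = dist.sf(k - 1)
            p_under = dist.cdf(k)
            if p_over <= p_under:
                pvals[a, b] = p_over
                signed[a, b] = 1.0
            else:
                pvals[a, b] = p_under
                signed[a, b] = -1.0
    with np.errstate(divide="ignore"):
        logp = -np.log10(np.maximum(pvals, 1e-320))
    adj = multipletests(pvals.ravel(), method="fdr_by")[1].reshape(pvals.shape)
    with np.errstate(divide="ignore"):
        log_adj = -np.log10(np.maximum(adj, 1e-320))
    boundary1 = int((t1.sort_values(ascending=False) > 0).sum())
    boundary2 = int((t2.sort_values(ascending=False) > 0).sum())
    return RRHOMap(step=step, thresholds=thresholds, overlap=overlap.astype(int),
                   signed_log_p=signed * logp, signed_log_p_adj=signed * log_adj,
                   boundary1=boundary1, boundary2=boundary2)


# --------------------------------------------------------------------------
# preranked GSEA
# --------------------------------------------------------------------------

def enrichment_score(ranked_abs_t: np.ndarray, hit_positions: np.ndarray,
                     weight: float = 1.0) -> float:
    """ES of a set from its 0-based positions in the ranked list.

    Hit increments are |t|^weight normalized over the set; miss increments
    are 1/(N - |S|).  ES is the running-sum value of maximal absolute
    deviation from zero.
    """
    N = len(ranked_abs_t)
    S = len(hit_positions)
    if S == 0 or S >= N:
        raise ValidationError("set size must be in (0, N)")
    pos = np.sort(hit_positions)
    w = ranked_abs_t[pos] ** weight
    total = w.sum()
    if total == 0:
        w = np.ones(S)
        total = float(S)
    miss = 1.0 / (N - S)
    cum_hit = np.cumsum(w) / total
    # running sum just after each hit, and just before each hit; interleaved
    # in temporal order so argmax reproduces a left-to-right scan's tie-break
    after = cum_hit - (pos + 1 - np.arange(1, S + 1)) * miss
    before = np.concatenate([[0.0], cum_hit[:-1]]) - (pos - np.arange(S)) * miss
    candidates = np.empty(2 * S)
    candidates[0::2] = before
    candidates[1::2] = after
    return float(candidates[np.argmax(np.abs(candidates))])


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    adj_p: float
    leading_edge: list
    size: int
    significant: bool


def gsea_preranked(t: pd.Series, sets: dict, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0, min_size: int = 5,
                   alpha: float = 0.1) -> pd.DataFrame:
    """Preranked GSEA for every set against one ranked t-score list.

    The null distribution preserves set size by sampling random member
    labels from the list (the sample-permutation null is unavailable at
    n = 9 vs 14, so label sampling is used); NES = ES / mean(|null ES| of
    matching sign); permutation p is two-sided by sign.
    """
    if t.nunique() <= 1:
        raise ValidationError("all-equal t vector cannot be ranked")
    order = sorted(t.index, key=lambda f: (-t[f], f))
    ranked = t.reindex(order)
    abs_t = np.abs(ranked.to_numpy())
    index_of = {f: i for i, f in enumerate(order)}
    N = len(order)
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for set_name in sorted(sets):
        members = [f for f in sets[set_name] if f in index_of]
        S = len(members)
        if S < min_size:
            log.warning("set %s has %d members in list (< %d): skipped", set_name, S, min_size)
            continue
        pos = np.array(sorted(index_of[f] for f in members))
        es = enrichment_score(abs_t, pos, weight)
        if S not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                rpos = rng.choice(N, size=S, replace=False)
                null[b] = enrichment_score(abs_t, rpos, weight)
            null_cache[S] = null
        null = null_cache[S]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes = 0.0
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same))
            p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
        # leading edge: members at or before (after, for negative ES) the peak
        if es >= 0:
            peak = _peak_position(abs_t, pos, weight, es)
            leading = [order[i] for i in pos if i <= peak]
        else:
            peak = _peak_position(abs_t, pos, weight, es)
            leading = [order[i] for i in pos if i >= peak]
        rows.append(dict(set_name=set_name, es=es, nes=nes, p_value=p,
                         size=S, leading_edge=";".join(sorted(leading))))
    if not rows:
        return pd.DataFrame(columns=["set_name", "es", "nes", "p_value", "adj_p",
                                     "size", "leading_edge", "significant"])
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["adj_p"] <= alpha
    return out


def _peak_position(abs_t: np.ndarray, pos: np.ndarray, weight: float, es: float) -> int:
    """Ranked-list index at which the running sum attains the ES."""
    N = len(abs_t)
    S = len(pos)
    w = abs_t[np.sort(pos)] ** weight
    total = w.sum() if w.sum() > 0 else float(S)
    if w.sum() == 0:
        w = np.ones(S)
    miss = 1.0 / (N - S)
    run = 0.0
    best_i, best_val = 0, 0.0
    spos = np.sort(pos)
    j = 0
    for i in range(N):
        if j < S and i == spos[j]:
            run += w[j] / total
            j += 1
        else:
            run -= miss
        if abs(run) > abs(best_val):
            best_val, best_i = run, i
    return best_i


def cross_layer_heatmap(results: dict, alpha: float = 0.1) -> pd.DataFrame:
    """Concordantly regulated sets across gene and protein levels.

    ``results`` maps (tissue, layer_tag) -> GSEA frame with layer_tag in
    {"G", "P"}.  A set is retained when it is significant with matching NES
    sign at both layers in at least one tissue; the output grid carries the
    signed significance per tissue x layer.
    """
    tissues = sorted({t for t, _ in results})
    tables = {key: df.set_index("set_name") for key, df in results.items()}
    all_sets = sorted(set().union(*[set(df.index) for df in tables.values()]))
    rows = []
    for s in all_sets:
        rec = {"set_name": s}
        keep = False
        for t in tissues:
            signs = {}
            for tag in ("G", "P"):
                df = tables.get((t, tag))
                if df is not None and s in df.index and bool(df.loc[s, "significant"]):
                    signs[tag] = int(np.sign(df.loc[s, "nes"]))
                    rec[f"{t}_{tag}"] = signs[tag]
                else:
                    rec[f"{t}_{tag}"] = 0
            if len(signs) == 2 and signs["G"] == signs["P"] and signs["G"] != 0:
                keep = True
        if keep:
            rows.append(rec)
    return pd.DataFrame(rows, columns=["set_name"] + [f"{t}_{tag}" for t in tissues
                                                      for tag in ("G", "P")])
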