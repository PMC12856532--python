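"""Per-tissue alcohol-vs-control differential analysis.

The model is a two-group linear contrast per feature on the log2 scale
(optionally with precision weights from the count-layer transform), whose
residual variances are shrunk toward a common prior by empirical Bayes:
the prior degrees of freedom d0 and prior variance s0^2 are estimated by
method of moments on the log residual variances, the posterior variance is

    s_post^2 = (d0 * s0^2 + df * s^2) / (d0 + df),

and the moderated t-statistic effect / (unscaled-se * s_post) is referred
to a t distribution on d0 + df degrees of freedom.  P-values are adjusted
by Benjamini-Hochberg within each layer x tissue family, direction calls
are made at adjusted p <= 0.1, and the top-k per direction are ranked by
|t| (the volcano annotation rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError


def fit_contrast(matrix_log2: pd.DataFrame, groups: pd.Series,
                 weights: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-feature two-group (weighted) linear fit.

    Returns a frame with ``effect`` (alcohol - control), the unscaled
    standard error, residual ``sigma2`` and degrees of freedom n - 2.
    Unit weights reproduce the classical pooled two-sample estimator.
    """
    groups = groups.loc[matrix_log2.columns]
    counts = groups.value_counts()
    if set(counts.index) != {"control", "alcohol"} or (counts < 2).any():
        raise ValidationError("need >=2 samples in each of control and alcohol")
    X = matrix_log2.to_numpy(dtype=float)
    if weights is None:
        W = np.ones_like(X)
    else:
        W = weights.loc[matrix_log2.index, matrix_log2.columns].to_numpy(dtype=float)
    ga = (groups == "alcohol").to_numpy()
    gc = ~ga
    wa, wc = W[:, ga], W[:, gc]
    xa, xc = X[:, ga], X[:, gc]
    swa, swc = wa.sum(axis=1), wc.sum(axis=1)
    ma = (wa * xa).sum(axis=1) / swa
    mc = (wc * xc).sum(axis=1) / swc
    effect = ma - mc
    rss = (wa * (xa - ma[:, None]) ** 2).sum(axis=1) + \
          (wc * (xc - mc[:, None]) ** 2).sum(axis=1)
    df = X.shape[1] - 2
    sigma2 = rss / df
    se_unscaled = np.sqrt(1.0 / swa + 1.0 / swc)
    return pd.DataFrame(
        {"effect": effect, "se_unscaled": se_unscaled, "sigma2": sigma2, "df": df},
        index=matrix_log2.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) / x < 1e-10:
            break
    return float(x)


def estimate_prior(sigma2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments empirical-Bayes prior (d0, s0^2) on log variances.

    Matches the standard scaled-F derivation: with z = log s^2, the prior
    degrees of freedom solve trigamma(d0/2) = var(z) - trigamma(df/2), and
    s0^2 follows from the mean of z.  When the observed variances carry no
    excess spread the prior is infinite (fully pooled) with a warning.
    """
    s2 = np.asarray(sigma2, dtype=float)
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0 or not np.isfinite(evar):
        warnings.warn("no excess variance spread: prior df set to infinity (fully pooled)")
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s02)


def moderate(fit: pd.DataFrame, prior_df: float | None = None,
             prior_var: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated t and raw p per feature.

    ``prior_df``/``prior_var`` override the estimated prior; prior_df = 0
    degrades to the ordinary t-statistic, prior_df = inf fully pools the
    variance at the prior.
    """
    df = float(fit["df"].iloc[0])
    sigma2 = fit["sigma2"].to_numpy(dtype=float)
    if prior_df is None:
        d0, s02 = estimate_prior(sigma2, df)
    else:
        d0 = float(prior_df)
        s02 = float(prior_var) if prior_var is not None else estimate_prior(sigma2, df)[1]
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * sigma2) / (d0 + df)
        df_total = d0 + df
    if d0 == 0:
        s2_post = sigma2.copy()
        df_total = df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit["effect"].to_numpy() / (fit["se_unscaled"].to_numpy() * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t"] = t
    out["p_value"] = p
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    return out


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValidationError("p-values must lie in [0, 1]")
    if len(arr) == 0:
        return arr
    return multipletests(arr, method="fdr_bh")[1]


def call_and_rank(table: pd.DataFrame, alpha: float = 0.1, k: int = 10) -> pd.DataFrame:
    """Direction calls at adjusted p <= alpha and top-k ranking by |t|.

    Direction is ``up``/``down`` by the sign of t among significant
    features, ``ns`` otherwise.  ``rank_up``/``rank_down`` number the top-k
    called features per direction by decreasing |t| with lexicographic
    feature-id tie-break.
    """
    out = table.copy()
    sig = out["adj_p"] <= alpha
    out["direction"] = np.where(sig & (out["t"] > 0), "up",
                       np.where(sig & (out["t"] < 0), "down", "ns"))
    for direction in ("up", "down"):
        col = f"rank_{direction}"
        out[col] = np.nan
        called = out[out["direction"] == direction]
        ordered = called.reindex(
            called.assign(abs_t=called["t"].abs())
                  .sort_values(["abs_t", "feature_id"], ascending=[False, True])
                  .index
        )
        top = ordered.index[:k]
        out.loc[top, col] = np.arange(1, len(top) + 1, dtype=float)
    return out


@dataclass
class DifferentialResults:
    """Fitted differential table plus the prior that produced it."""

    table: pd.DataFrame
    tissue: str
    layer: str
    prior_df: float
    prior_var: float
    alpha: float

    def called(self, direction: str) -> list[str]:
        return sorted(self.table.loc[self.table["direction"] == direction, "feature_id"])

    def top(self, direction: str, k: int = 10) -> pd.DataFrame:
        col = f"rank_{direction}"
        sub = self.table.dropna(subset=[col]).sort_values(col)
        return sub.head(k)

    def summary(self) -> pd.DataFrame:
        n = len(self.table)
        up = int((self.table["direction"] == "up").sum())
        down = int((self.table["direction"] == "down").sum())
        return pd.DataFrame(
            [
                ("layer", self.layer), ("tissue", self.tissue),
                ("features", n), ("up", up), ("down", down),
                ("prior_df", round(self.prior_df, 3)),
                ("prior_var", round(self.prior_var, 5)),
                ("alpha", self.alpha),
            ],
            columns=["field", "value"],
        )


class DifferentialAnalysis:
    """Two-group moderated differential model for one layer x tissue.

    Parameters
    ----------
    matrix_log2 : DataFrame
        Features x experimental samples (one tissue), log2 scale.
    groups : Series
        ``control`` / ``alcohol`` per sample.
    weights : DataFrame, optional
        Observation precision weights (transcriptome only).
    """

    def __init__(self, matrix_log2: pd.DataFrame, groups: pd.Series,
                 weights: pd.DataFrame | None = None,
                 tissue: str = "", layer: str = ""):
        self.matrix = matrix_log2
        self.groups = groups
        self.weights = weights
        self.tissue = tissue
        self.layer = layer

    def fit(self, alpha: float = 0.1, k: int = 10,
            prior_df: float | None = None) -> DifferentialResults:
        fitted = fit_contrast(self.matrix, self.groups, self.weights)
        mod = moderate(fitted, prior_df=prior_df)
        table = mod.reset_index().rename(columns={"index": "feature_id"})
        if "feature_id" not in table.columns:
            table = table.rename(columns={table.columns[0]: "feature_id"})
        table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
        table = table.set_index("feature_id", drop=False)
        table.index.name = None
        table = call_and_rank(table, alpha=alpha, k=k)
        return DifferentialResults(
            table=table.reset_index(drop=True),
            tissue=self.tissue, layer=self.layer,
            prior_df=mod.attrs["prior_df"], prior_var=mod.attrs["prior_var"],
            alpha=alpha,
        )
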