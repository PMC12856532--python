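"""Layer-specific preprocessing from raw matrices to analysis-ready log2
abundances.

Cascade order is fixed and logged per layer:

* transcriptome: expression filter (grouped by tissue) -> TMM factors ->
  voom log2-CPM with precision weights;
* proteome (arrives log2): missingness filter (>50% overall removed) ->
  feature-space kNN imputation;
* metabolome, per chromatography column: PQN -> QC-RLSC drift correction ->
  QC CV filter -> KEGG-ID filter -> log2 -> mean aggregation of the two
  columns;
* lipidome: missingness filters (QC >50% OR experimental >80%) -> kNN
  imputation -> PQN -> QC-RLSC -> QC CV filter -> log2, with PC/PE percent
  content and the PC:PE ratio computed on the pre-log linear matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .datatypes import ConfigurationError, OmicsLayer, ValidationError

log = logging.getLogger("duomics")


@dataclass
class PreprocessReport:
    """Bookkeeping of every filter, imputation and normalization step."""

    layer: str
    steps: list = field(default_factory=list)
    dilution_factors: dict = field(default_factory=dict)
    qc_cv_before: float | None = None
    qc_cv_after: float | None = None
    imputed_entries: int = 0

    def record(self, step: str, n_in: int, n_out: int, **params) -> None:
        if n_out > n_in or n_in < 0:
            raise ValidationError("inconsistent filter accounting")
        self.steps.append(dict(step=step, n_in=n_in, n_out=n_out,
                               n_removed=n_in - n_out, **params))
        log.info("%s/%s: %d -> %d features %s", self.layer, step, n_in, n_out, params)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


# --------------------------------------------------------------------------
# transcriptome
# --------------------------------------------------------------------------

def filter_low_expression(counts: pd.DataFrame, groups: pd.Series,
                          min_count: float = 10.0, min_prop: float = 1.0,
                          min_total: float = 15.0) -> pd.DataFrame:
    """Keep a gene iff, in at least one group, at least
    ceil(min_prop * group size) samples reach the CPM equivalent of
    ``min_count`` at the median library size, and its total count is at
    least ``min_total``.  Feature order is preserved."""
    groups = groups.loc[counts.columns]
    if groups.isna().any() or (groups.value_counts() == 0).any():
        raise ConfigurationError("empty or missing groups in expression filter")
    lib = counts.sum(axis=0)
    cpm = counts * 1e6 / lib
    cutoff = min_count / np.median(lib) * 1e6
    keep_group = pd.Series(False, index=counts.index)
    for g, members in groups.groupby(groups).groups.items():
        need = int(np.ceil(min_prop * len(members)))
        n_ok = (cpm[list(members)] >= cutoff).sum(axis=1)
        keep_group |= n_ok >= need
    keep = keep_group & (counts.sum(axis=1) >= min_total)
    return counts.loc[keep]


def tmm_factors(counts: pd.DataFrame, m_trim: float = 0.30, a_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values composition normalization factors.

    Reference sample: upper quartile (of CPM) closest to the mean upper
    quartile.  Per sample, M (log ratio) and A (average log abundance) are
    computed against the reference over genes expressed in both; the M
    values are doubly trimmed (30% on M, 5% on A) and averaged with
    inverse-asymptotic-variance weights.  Factors are rescaled to geometric
    mean 1.
    """
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValidationError("sample with all-zero counts")
    cpm = counts * 1e6 / lib
    uq = cpm.apply(lambda col: np.percentile(col[col > 0], 75) if (col > 0).any() else 0.0)
    ref_name = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy(dtype=float)
    nref = lib[ref_name]
    factors = {}
    for s in counts.columns:
        obs = counts[s].to_numpy(dtype=float)
        ns = lib[s]
        ok = (obs > 0) & (ref > 0)
        if s == ref_name or ok.sum() == 0:
            factors[s] = 1.0
            continue
        o, r = obs[ok], ref[ok]
        m = np.log2((o / ns) / (r / nref))
        a = 0.5 * np.log2((o / ns) * (r / nref))
        # asymptotic (delta-method) variance of M
        v = (ns - o) / (ns * o) + (nref - r) / (nref * r)
        finite = np.isfinite(m) & np.isfinite(a)
        m, a, v = m[finite], a[finite], v[finite]
        if len(m) == 0 or np.max(np.abs(m)) < 1e-6:
            factors[s] = 1.0
            continue
        n = len(m)
        lo_m, hi_m = np.floor(n * m_trim) + 1, n + 1 - (np.floor(n * m_trim) + 1)
        lo_a, hi_a = np.floor(n * a_trim) + 1, n + 1 - (np.floor(n * a_trim) + 1)
        rank_m = pd.Series(m).rank(method="average").to_numpy()
        rank_a = pd.Series(a).rank(method="average").to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0:
            factors[s] = 1.0
            continue
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        factors[s] = 2.0 ** f
    out = pd.Series(factors)[counts.columns]
    out = out / np.exp(np.mean(np.log(out)))
    return out


def voom_transform(counts: pd.DataFrame, factors: pd.Series, groups: pd.Series,
                   span: float = 0.5):
    """Log2-CPM with precision weights from the mean-variance trend.

    log2-CPM uses count + 0.5 over effective library size + 1.  A preliminary
    unweighted two-group fit per gene yields residual standard deviations;
    sqrt(sd) is smoothed against average log2 count by lowess, and each
    observation's weight is the inverse fourth power of the trend's predicted
    sqrt-sd at its fitted log-count.
    """
    if (factors <= 0).any():
        raise ValidationError("non-positive normalization factor")
    groups = groups.loc[counts.columns]
    if len(counts.columns) < 3:
        raise ValidationError("fewer samples than model coefficients")
    eff_lib = counts.sum(axis=0) * factors
    log2cpm = np.log2((counts + 0.5).div(eff_lib + 1.0, axis=1) * 1e6)

    # preliminary unweighted group-means fit
    gm = log2cpm.T.groupby(groups).mean().T       # genes x groups
    fitted = gm[groups.to_numpy()]
    fitted.columns = counts.columns
    resid = log2cpm - fitted
    df_resid = len(counts.columns) - groups.nunique()
    sigma = np.sqrt((resid ** 2).sum(axis=1) / df_resid)
    sqrt_sd = np.sqrt(sigma)

    # average log2 count (log2-CPM shifted back to the count scale)
    mean_log2_count = log2cpm.mean(axis=1) + np.mean(np.log2(eff_lib + 1.0)) - np.log2(1e6)

    lo = sm_lowess(sqrt_sd.to_numpy(), mean_log2_count.to_numpy(),
                   frac=span, it=3, return_sorted=True)
    lx, ly = lo[:, 0], np.maximum(lo[:, 1], 1e-6)

    # predicted sqrt-sd at each observation's fitted log-count
    fitted_count = fitted.add(np.log2(eff_lib + 1.0) - np.log2(1e6), axis=1)
    pred = np.interp(fitted_count.to_numpy(), lx, ly)
    weights = pd.DataFrame(1.0 / pred ** 4, index=counts.index, columns=counts.columns)
    if not np.all(np.isfinite(weights.to_numpy())) or (weights.to_numpy() <= 0).any():
        raise ValidationError("voom produced non-finite or non-positive weights")
    return log2cpm, weights


# --------------------------------------------------------------------------
# missingness and imputation
# --------------------------------------------------------------------------

def filter_missingness(values: pd.DataFrame, qc_mask: pd.Series | None = None,
                       qc_max: float = 0.5, exp_max: float = 0.8,
                       overall_max: float | None = None) -> pd.DataFrame:
    """Remove features by missing fraction.

    With ``overall_max`` set (proteome rule), a feature is removed when its
    overall missing fraction exceeds it.  Otherwise (lipidome rule) a
    feature is removed when its QC missing fraction exceeds ``qc_max`` OR
    its experimental missing fraction exceeds ``exp_max`` — both strict.
    """
    if overall_max is not None:
        frac = values.isna().mean(axis=1)
        return values.loc[frac <= overall_max]
    if qc_mask is None or not qc_mask.any():
        raise ConfigurationError("QC-based missingness filter needs QC samples")
    qc_mask = qc_mask.reindex(values.columns).fillna(False).astype(bool)
    qc_frac = values.loc[:, qc_mask.to_numpy()].isna().mean(axis=1)
    exp_frac = values.loc[:, (~qc_mask).to_numpy()].isna().mean(axis=1)
    remove = (qc_frac > qc_max) | (exp_frac > exp_max)
    return values.loc[~remove]


def impute_knn(values: pd.DataFrame, k: int = 10) -> tuple[pd.DataFrame, int]:
    """Feature-space k-nearest-neighbour imputation.

    For each feature with missing entries, neighbours are other features,
    ranked by Euclidean distance over mutually observed samples (normalized
    per-sample to compare across overlap sizes), restricted to features
    observed at the target's missing positions.  Each missing entry becomes
    the unweighted mean of the k nearest neighbours' values at that sample;
    if no neighbour is eligible the feature's own mean is used.
    """
    X = values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (obs.sum(axis=1) == 0).any():
        raise ValidationError("feature with zero observed entries reached imputation")
    out = X.copy()
    incomplete = np.flatnonzero(~obs.all(axis=1))
    n_imputed = 0
    for i in incomplete:
        target_obs = obs[i]
        miss_cols = np.flatnonzero(~target_obs)
        # distance over mutually observed samples, mean-squared to normalize
        shared = obs & target_obs
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X - X[i], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = np.where(n_shared > 0, (diff ** 2).sum(axis=1) / n_shared, np.inf)
        d2[i] = np.inf
        for j in miss_cols:
            eligible = np.flatnonzero(obs[:, j] & np.isfinite(d2))
            if len(eligible) == 0:
                out[i, j] = X[i, target_obs].mean()
            else:
                nearest = eligible[np.argsort(d2[eligible], kind="stable")[:k]]
                out[i, j] = X[nearest, j].mean()
            n_imputed += 1
    return pd.DataFrame(out, index=values.index, columns=values.columns), n_imputed


# --------------------------------------------------------------------------
# linear-scale normalization and drift correction
# --------------------------------------------------------------------------

def replace_zeros_half_min(values: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros by half the feature's minimum positive value."""
    X = values.to_numpy(dtype=float).copy()
    for i in range(X.shape[0]):
        row = X[i]
        zero = row == 0
        if zero.any():
            pos = row[row > 0]
            if len(pos) == 0:
                raise ValidationError(f"feature {values.index[i]} is all-zero")
            X[i, zero] = pos.min() / 2.0
    return pd.DataFrame(X, index=values.index, columns=values.columns)


def pqn_normalize(values: pd.DataFrame, reference: pd.Series | None = None,
                  qc_mask: pd.Series | None = None):
    """Probabilistic quotient normalization on a strictly positive linear
    matrix.  Reference defaults to the median QC profile (median profile of
    all samples when no QC mask is given).  Returns the corrected matrix and
    the per-sample dilution factors (median quotients)."""
    X = replace_zeros_half_min(values)
    if reference is None:
        if qc_mask is not None and qc_mask.any():
            qc_mask = qc_mask.reindex(X.columns).fillna(False).astype(bool)
            reference = X.loc[:, qc_mask.to_numpy()].median(axis=1)
        else:
            reference = X.median(axis=1)
    reference = reference.reindex(X.index)
    if (reference <= 0).any() or reference.isna().any():
        raise ValidationError("PQN reference has non-positive or missing entries")
    quotients = X.div(reference, axis=0)
    factors = quotients.median(axis=0)
    if (factors <= 0).any():
        raise ValidationError("non-positive dilution factor")
    return X.div(factors, axis=1), factors


def qc_rlsc(values: pd.DataFrame, injection_order: pd.Series, qc_mask: pd.Series,
            span: float = 0.75, min_qc: int = 5, robust_iters: int = 2) -> pd.DataFrame:
    """Quality-control-based robust LOESS signal correction.

    Per feature, a robust locally weighted regression of QC intensity on
    injection order is fit; the curve is interpolated to every injection
    (constant beyond the QC range), each value is divided by its
    interpolated fit, and the feature is rescaled by its median QC
    intensity.  Runs with fewer than ``min_qc`` QCs are left uncorrected
    with a warning.
    """
    qc_mask = qc_mask.reindex(values.columns).fillna(False).astype(bool)
    order = injection_order.reindex(values.columns)
    if order.isna().any():
        raise ConfigurationError("missing injection order for some samples")
    n_qc = int(qc_mask.sum())
    if n_qc < min_qc:
        log.warning("only %d QCs (< %d): drift correction skipped", n_qc, min_qc)
        return values.copy()
    qc_orders = order[qc_mask].to_numpy(dtype=float)
    all_orders = order.to_numpy(dtype=float)
    X = values.to_numpy(dtype=float)
    qc_idx = qc_mask.to_numpy()
    out = np.empty_like(X)
    sort_qc = np.argsort(qc_orders)
    xs = qc_orders[sort_qc]
    for i in range(X.shape[0]):
        ys = X[i, qc_idx][sort_qc]
        if np.nanstd(ys) == 0 or np.isnan(ys).any():
            fit_at_qc = np.full_like(ys, np.nanmean(ys))
        else:
            sm = sm_lowess(ys, xs, frac=min(1.0, span), it=robust_iters, return_sorted=True)
            fit_at_qc = sm[:, 1]
        fit_all = np.interp(all_orders, xs, fit_at_qc)
        med_qc = np.median(X[i, qc_idx])
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = X[i] / fit_all * med_qc
        bad = ~np.isfinite(corr)
        corr[bad] = X[i][bad]
        out[i] = corr
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def cv_filter(values: pd.DataFrame, qc_mask: pd.Series, max_cv: float = 0.30) -> pd.DataFrame:
    """Remove features whose QC coefficient of variation (sample sd / mean)
    is strictly larger than ``max_cv``."""
    qc_mask = qc_mask.reindex(values.columns).fillna(False).astype(bool)
    if qc_mask.sum() < 2:
        raise ConfigurationError("CV filter needs at least 2 QC samples")
    qc = values.loc[:, qc_mask.to_numpy()]
    cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    return values.loc[cv <= max_cv]


def kegg_filter(values: pd.DataFrame, kegg_present: pd.Series) -> pd.DataFrame:
    flags = kegg_present.reindex(values.index).fillna(False).astype(bool)
    out = values.loc[flags]
    if out.empty:
        log.warning("KEGG filter removed every metabolite")
    return out


def aggregate_columns(a: pd.DataFrame, b: pd.DataFrame):
    """Mean-aggregate two normalized log2 metabolite matrices (the two
    chromatography columns) over identical samples.  Shared features are
    averaged entrywise; column-unique features pass through unchanged.
    Returns the merged matrix and a provenance Series (a / b / both)."""
    if set(a.columns) != set(b.columns):
        raise ValidationError("column aggregation requires identical sample sets")
    b = b[a.columns]
    shared = a.index.intersection(b.index)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    merged = pd.concat([
        (a.loc[shared] + b.loc[shared]) / 2.0,
        a.loc[only_a],
        b.loc[only_b],
    ])
    merged = merged.sort_index()
    provenance = pd.Series("both", index=merged.index)
    provenance.loc[only_a] = "a"
    provenance.loc[only_b] = "b"
    return merged, provenance


def pcpe_ratio(values_linear: pd.DataFrame, lipid_class: pd.Series) -> pd.DataFrame:
    """Percent content of the PC and PE classes and their ratio, per sample.

    Percent content of a class = sum of the class's relative peak values in
    the sample divided by the sample's total peak value.  Computed on the
    pre-log2, PQN-normalized linear matrix; scale-invariant per sample.
    """
    cls = lipid_class.reindex(values_linear.index)
    total = values_linear.sum(axis=0)
    pc = values_linear.loc[(cls == "PC").to_numpy()].sum(axis=0)
    pe = values_linear.loc[(cls == "PE").to_numpy()].sum(axis=0)
    if (pe == 0).any():
        bad = pe.index[pe == 0].tolist()
        raise ValidationError(f"PE class sum is zero in samples {bad[:5]}")
    out = pd.DataFrame({
        "pc_percent": 100.0 * pc / total,
        "pe_percent": 100.0 * pe / total,
    })
    out["pc_pe_ratio"] = out["pc_percent"] / out["pe_percent"]
    out.index.name = "sample_id"
    return out


# --------------------------------------------------------------------------
# full cascades
# --------------------------------------------------------------------------

def _qc_cv(values: pd.DataFrame, qc_mask: pd.Series) -> float:
    qc_mask = qc_mask.reindex(values.columns).fillna(False).astype(bool)
    qc = values.loc[:, qc_mask.to_numpy()]
    cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    return float(cv.median())


def preprocess_transcriptome(layer: OmicsLayer, meta, min_count: float = 10.0,
                             min_prop: float = 1.0, min_total: float = 15.0):
    """Expression filter (grouped by tissue) -> TMM -> voom."""
    report = PreprocessReport("transcriptome")
    exp = meta.experimental()
    counts = layer.values[exp["sample_id"]]
    n0 = len(counts)
    counts = filter_low_expression(counts, exp["tissue"], min_count, min_prop, min_total)
    report.record("expression_filter", n0, len(counts),
                  min_count=min_count, min_prop=min_prop, min_total=min_total)
    factors = tmm_factors(counts)
    report.dilution_factors = {s: float(f) for s, f in factors.items()}
    log2cpm, weights = voom_transform(counts, factors, exp["tissue"] + ":" + exp["group"])
    report.record("voom", len(counts), len(counts))
    out = OmicsLayer("transcriptome", log2cpm, "log2")
    return out, weights, report


def preprocess_proteome(layer: OmicsLayer, meta, overall_max: float = 0.5, k: int = 10):
    """Missingness filter (>50% overall) -> feature-space kNN imputation."""
    report = PreprocessReport("proteome")
    exp = meta.experimental()
    vals = layer.values[exp["sample_id"]]
    n0 = len(vals)
    vals = filter_missingness(vals, overall_max=overall_max)
    report.record("missingness_filter", n0, len(vals), overall_max=overall_max)
    vals, n_imp = impute_knn(vals, k=k)
    report.imputed_entries = n_imp
    report.record("knn_imputation", len(vals), len(vals), k=k, imputed=n_imp)
    return OmicsLayer("proteome", vals, "log2"), report


def _metabolome_column(values: pd.DataFrame, meta, report: PreprocessReport,
                       span: float, max_cv: float):
    qc_mask = meta.for_samples(values.columns)["role"] == "qc"
    order = meta.for_samples(values.columns)["injection_order"]
    report.qc_cv_before = _qc_cv(values, qc_mask)
    normed, factors = pqn_normalize(values, qc_mask=qc_mask)
    for s, f in factors.items():
        report.dilution_factors[s] = float(f)
    corrected = qc_rlsc(normed, order, qc_mask, span=span)
    report.qc_cv_after = _qc_cv(corrected, qc_mask)
    n0 = len(corrected)
    filtered = cv_filter(corrected, qc_mask, max_cv=max_cv)
    report.record("cv_filter", n0, len(filtered), max_cv=max_cv)
    return filtered, qc_mask


def preprocess_metabolome(layer_a: OmicsLayer, layer_b: OmicsLayer, meta,
                          kegg_present: pd.Series, span: float = 0.75,
                          max_cv: float = 0.30):
    """PQN -> QC-RLSC -> CV filter -> KEGG filter -> log2 per column, then
    mean aggregation of the two columns; QCs dropped from the output."""
    logs = []
    reports = []
    for name, lay in (("c18", layer_a), ("amide", layer_b)):
        report = PreprocessReport(f"metabolome_{name}")
        filtered, qc_mask = _metabolome_column(lay.values, meta, report, span, max_cv)
        n0 = len(filtered)
        filtered = kegg_filter(filtered, kegg_present)
        report.record("kegg_filter", n0, len(filtered))
        exp_cols = [c for c in filtered.columns if not qc_mask.get(c, False)]
        logs.append(np.log2(filtered[exp_cols]))
        reports.append(report)
    merged, provenance = aggregate_columns(logs[0], logs[1])
    return OmicsLayer("metabolome", merged, "log2"), provenance, reports


def preprocess_lipidome(layer: OmicsLayer, meta, lipid_class: pd.Series,
                        qc_max: float = 0.5, exp_max: float = 0.8, k: int = 10,
                        span: float = 0.75, max_cv: float = 0.30):
    """Missingness filters -> kNN imputation -> PQN -> QC-RLSC -> CV filter
    -> log2, with PC/PE percent content computed pre-log."""
    report = PreprocessReport("lipidome")
    vals = layer.values
    sub = meta.for_samples(vals.columns)
    qc_mask = sub["role"] == "qc"
    order = sub["injection_order"]
    n0 = len(vals)
    vals = filter_missingness(vals, qc_mask=qc_mask, qc_max=qc_max, exp_max=exp_max)
    report.record("missingness_filter", n0, len(vals), qc_max=qc_max, exp_max=exp_max)
    vals, n_imp = impute_knn(vals, k=k)
    report.imputed_entries = n_imp
    report.record("knn_imputation", len(vals), len(vals), k=k, imputed=n_imp)
    report.qc_cv_before = _qc_cv(vals, qc_mask)
    normed, factors = pqn_normalize(vals, qc_mask=qc_mask)
    report.dilution_factors = {s: float(f) for s, f in factors.items()}
    corrected = qc_rlsc(normed, order, qc_mask, span=span)
    report.qc_cv_after = _qc_cv(corrected, qc_mask)
    n1 = len(corrected)
    filtered = cv_filter(corrected, qc_mask, max_cv=max_cv)
    report.record("cv_filter", n1, len(filtered), max_cv=max_cv)
    exp_cols = [c for c in filtered.columns if not qc_mask.get(c, False)]
    ratios = pcpe_ratio(filtered[exp_cols], lipid_class)
    out = OmicsLayer("lipidome", np.log2(filtered[exp_cols]), "log2")
    return out, ratios, report
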