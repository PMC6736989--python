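"""Negative-binomial differential expression: dispersions, Wald, LRT.

Dispersion is estimated gene-wise by method of moments within groups and
shrunk 50% toward a fitted mean-dispersion trend alpha(mu) = a0 + a1/mu.
Pairwise tests are NB GLM Wald z-tests (group indicator + log size-factor
offset); the multi-group test is a likelihood-ratio test of ~group against
~1 with chi-square reference (df = groups - 1).  Gene calls use the nominal
p < 0.05 rule with no multiple-testing correction; no independent
filtering, outlier handling or fold-change shrinkage is applied.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import _nbglm
from .counts_io import CountMatrix, SampleSheet, ValidationError

LN2 = np.log(2.0)


def estimate_dispersion(
    counts: CountMatrix,
    size_factors: pd.Series,
    sample_sheet: SampleSheet | None = None,
    shrink: float = 0.5,
) -> pd.DataFrame:
    """Gene-wise method-of-moments NB dispersion with trend shrinkage.

    Within each group (all samples as one group when no sheet is given) the
    moments estimate is alpha = (var - c*mean) / mean^2 with c the mean
    inverse size factor (Poisson part on the normalized scale); estimates
    are floored at 0, then shrunk ``shrink`` of the way toward a robust
    trend fit alpha(mu) = a0 + a1/mu.  All-zero genes get NaN and method
    'excluded'.
    """
    sf = size_factors.loc[counts.samples].to_numpy(dtype=float)
    q = counts.values.to_numpy(dtype=float) / sf[None, :]
    genes = counts.genes
    n = q.shape[1]

    if sample_sheet is not None:
        groups = sample_sheet.group_of().loc[counts.samples].to_numpy()
        levels = [g for g in dict.fromkeys(groups)]
    else:
        groups = np.array(["all"] * n)
        levels = ["all"]

    num = np.zeros(q.shape[0])
    den = 0.0
    for lvl in levels:
        mask = groups == lvl
        ng = int(mask.sum())
        if ng < 2:
            continue
        m = q[:, mask].mean(axis=1)
        v = q[:, mask].var(axis=1, ddof=1)
        c = float(np.mean(1.0 / sf[mask]))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - c * m) / np.square(m)
        a = np.where(m > 0, a, np.nan)
        w = ng - 1
        num += w * np.nan_to_num(a, nan=0.0)
        den += w
    if den == 0:
        raise ValidationError("need at least one group with >= 2 samples")
    alpha_raw = np.maximum(num / den, 0.0)

    base_mean = q.mean(axis=1)
    excluded = base_mean <= 0
    alpha_raw[excluded] = np.nan

    trend = _fit_dispersion_trend(base_mean, alpha_raw)
    alpha = (1.0 - shrink) * alpha_raw + shrink * trend
    alpha = np.maximum(alpha, 0.0)

    method = np.where(excluded, "excluded", "trend-shrunk")
    return pd.DataFrame(
        {
            "alpha": alpha,
            "alpha_genewise": alpha_raw,
            "alpha_trend": trend,
            "base_mean": base_mean,
            "method": method,
        },
        index=pd.Index(genes, name="gene"),
    )


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Robust-ish least squares of alpha on [1, 1/mu], trimming outliers."""
    use = np.isfinite(alpha) & (alpha > 0) & (mu > 0)
    if use.sum() < 10:
        fallback = np.nanmedian(alpha[np.isfinite(alpha)]) if np.isfinite(alpha).any() else 0.0
        return np.full_like(mu, max(fallback, 0.0))
    X = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
    y = alpha[use]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    for _ in range(2):  # trim gross outliers and refit
        resid = y - X @ coef
        mad = np.median(np.abs(resid - np.median(resid))) + 1e-12
        keep = np.abs(resid - np.median(resid)) < 4.0 * 1.4826 * mad
        if keep.sum() < 10 or keep.all():
            break
        coef, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        X, y = X[keep], y[keep]
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.where(mu > 0, mu, np.nan)
    return np.maximum(np.nan_to_num(trend, nan=0.0), 1e-8)


def _alpha_vector(dispersions: pd.DataFrame | Mapping[str, float], genes: list[str]) -> np.ndarray:
    if isinstance(dispersions, pd.DataFrame):
        s = dispersions["alpha"]
    else:
        s = pd.Series(dispersions)
    alpha = s.reindex(genes).to_numpy(dtype=float)
    return np.nan_to_num(alpha, nan=0.0)


def _covariate_matrix(
    covariates: pd.DataFrame | None, sample_ids: list[str]
) -> np.ndarray | None:
    if covariates is None:
        return None
    return covariates.loc[sample_ids].to_numpy(dtype=float)


def wald_test(
    counts: CountMatrix,
    size_factors: pd.Series,
    sample_sheet: SampleSheet,
    contrast: tuple[str, str],
    dispersions: pd.DataFrame | Mapping[str, float],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pairwise NB Wald test for ``contrast = (groupA, groupB)``.

    log2_fold_change is A relative to B.  Optional sample-level covariates
    (e.g. an unwanted-variation factor) are added to the design.  Genes for
    which the GLM fails return NaN statistics, never a crash.
    """
    group_a, group_b = contrast
    ids = [
        s
        for s in counts.samples
        if sample_sheet.group_of().get(s) in (group_a, group_b)
    ]
    sub_groups = sample_sheet.group_of().loc[ids]
    for g in contrast:
        if (sub_groups == g).sum() < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
    y = counts.values.loc[:, ids].to_numpy(dtype=float)
    sf = size_factors.loc[ids].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(ids)), (sub_groups == group_a).to_numpy(dtype=float)]
    )
    cov = _covariate_matrix(covariates, ids)
    if cov is not None:
        X = np.hstack([X, cov])
    alpha = _alpha_vector(dispersions, counts.genes)

    fit = _nbglm.fit_nb_glm(y, X, np.log(sf), alpha)
    beta = fit["beta"][:, 1]
    se = fit["se"][:, 1]
    usable = fit["ok"] & fit["converged"] & (se > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(usable, beta / se, np.nan)
    pval = np.where(np.isfinite(stat), 2.0 * stats.norm.sf(np.abs(stat)), np.nan)
    base_mean = (y / sf[None, :]).mean(axis=1)
    return pd.DataFrame(
        {
            "comparison": f"{group_a}_vs_{group_b}",
            "base_mean": base_mean,
            "log2_fold_change": np.where(fit["ok"], beta / LN2, np.nan),
            "stat": stat,
            "pvalue": pval,
            "converged": usable,
        },
        index=pd.Index(counts.genes, name="gene"),
    )


def lrt_test(
    counts: CountMatrix,
    size_factors: pd.Series,
    sample_sheet: SampleSheet,
    dispersions: pd.DataFrame | Mapping[str, float],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Multi-group likelihood-ratio test (~group vs ~1), chi2 df = groups-1.

    log2_fold_change reports the last-vs-first group level for reference.
    """
    ids = counts.samples
    sample_sheet.check_matches(counts)
    groups = sample_sheet.group_of().loc[ids]
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups for the LRT")
    y = counts.values.to_numpy(dtype=float)
    sf = size_factors.loc[ids].to_numpy(dtype=float)
    offset = np.log(sf)
    cov = _covariate_matrix(covariates, ids)

    X_red = np.ones((len(ids), 1))
    X_full = np.ones((len(ids), len(levels)))
    for j, lvl in enumerate(levels[1:], start=1):
        X_full[:, j] = (groups == lvl).to_numpy(dtype=float)
    if cov is not None:
        X_red = np.hstack([X_red, cov])
        X_full = np.hstack([X_full, cov])

    alpha = _alpha_vector(dispersions, counts.genes)
    fit_full = _nbglm.fit_nb_glm(y, X_full, offset, alpha)
    fit_red = _nbglm.fit_nb_glm(y, X_red, offset, alpha)
    stat = 2.0 * (fit_full["loglik"] - fit_red["loglik"])
    stat = np.maximum(stat, 0.0)
    df = len(levels) - 1
    usable = fit_full["ok"] & fit_red["ok"] & fit_full["converged"] & fit_red["converged"]
    stat = np.where(usable, stat, np.nan)
    pval = np.where(np.isfinite(stat), stats.chi2.sf(stat, df), np.nan)
    base_mean = (y / sf[None, :]).mean(axis=1)
    lfc = fit_full["beta"][:, len(levels) - 1] / LN2
    return pd.DataFrame(
        {
            "comparison": "LRT",
            "base_mean": base_mean,
            "log2_fold_change": np.where(fit_full["ok"], lfc, np.nan),
            "stat": stat,
            "pvalue": pval,
            "converged": usable,
        },
        index=pd.Index(counts.genes, name="gene"),
    )


def call_degs(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Genes with nominal p-value strictly below ``alpha`` (no FDR correction)."""
    if results.empty:
        raise ValidationError("empty results table")
    p = results["pvalue"]
    return set(results.index[p < alpha])


def deg_union(results_tables: Iterable[pd.DataFrame], alpha: float = 0.05) -> set[str]:
    """Union of DEG calls over several tables (pairwise Wald tests + LRT)."""
    out: set[str] = set()
    for t in results_tables:
        out |= call_degs(t, alpha)
    return out
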