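"""Size-factor normalization, one-factor unwanted-variation removal, VST.

Size factors use the median-of-ratios method (per-sample median of counts
divided by the gene-wise geometric mean, over genes positive in every
sample).  Unwanted variation is estimated RUVr-style: deviance residuals
from a per-gene NB regression on the known groups are decomposed by SVD and
the first k right singular vectors are regressed out of the log-scale
normalized counts.  The variance-stabilizing transform is a shifted log of
size-factor-normalized counts: log2(count/factor + pseudocount); this is a
deliberate, monotone simplification of dispersion-calibrated transforms and
is adequate for the rank-based (Spearman) downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nbglm
from .counts_io import CountMatrix, SampleSheet, ValidationError


@dataclass
class NormalizeConfig:
    ruv_k: int = 1
    vst_pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.ruv_k < 0:
            raise ValidationError("ruv_k must be >= 0")
        if self.vst_pseudocount <= 0:
            raise ValidationError("vst_pseudocount must be > 0")


def drop_all_zero_genes(counts: CountMatrix, min_total: int = 1) -> CountMatrix:
    """Drop genes whose total count is below ``min_total`` (default: all-zero)."""
    keep = counts.values.sum(axis=1) >= min_total
    return CountMatrix(counts.values.loc[keep])


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference).

    factor_j = median over genes g of count_gj / geomean_g(count_g.),
    restricted to genes with all-positive counts.
    """
    arr = counts.values.to_numpy(dtype=float)
    if arr.shape[1] == 1:
        return pd.Series([1.0], index=counts.samples, name="size_factor")
    allpos = np.all(arr > 0, axis=1)
    if not allpos.any():
        raise ValidationError(
            "no gene has positive counts in every sample; filter low-count "
            "genes or samples before computing size factors"
        )
    logs = np.log(arr[allpos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.samples, name="size_factor")


def _group_design(sheet: SampleSheet, sample_ids: list[str]) -> np.ndarray:
    groups = sheet.group_of().loc[sample_ids]
    levels = list(dict.fromkeys(groups))
    X = np.ones((len(sample_ids), len(levels)))
    for j, lvl in enumerate(levels[1:], start=1):
        X[:, j] = (groups == lvl).to_numpy(dtype=float)
    return X


def remove_unwanted_variation(
    counts: CountMatrix,
    sample_sheet: SampleSheet,
    k: int = 1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Estimate and remove ``k`` unwanted-variation factors (RUVr-style).

    Per-gene NB GLMs on the known group design yield deviance residuals;
    their first ``k`` sample-space singular vectors are taken as unwanted
    factors and regressed out of log2 normalized counts.  Returns rounded
    nonnegative corrected counts and the estimated factors (samples x k).
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(counts.samples)
    if k >= n:
        raise ValidationError(f"k={k} must be < number of samples ({n})")
    sample_sheet.check_matches(counts)

    filtered = drop_all_zero_genes(counts)
    sf = size_factors(filtered)
    y = filtered.values.to_numpy(dtype=float)
    offset = np.log(sf.to_numpy())
    X = _group_design(sample_sheet, filtered.samples)

    from .diffexp import estimate_dispersion  # local import to avoid cycle

    disp = estimate_dispersion(filtered, sf, sample_sheet)
    alpha = disp["alpha"].to_numpy()

    fit = _nbglm.fit_nb_glm(y, X, offset, alpha)
    resid = _nbglm.nb_deviance_residuals(y, fit["mu"], alpha)
    resid = np.where(np.isfinite(resid), resid, 0.0)
    resid = resid - resid.mean(axis=1, keepdims=True)

    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    W = vt[:k].T  # samples x k
    # deterministic sign: orient each factor so its largest-|.| entry is positive
    for j in range(k):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]

    # regress log-scale normalized counts on [group design, W]; remove W part
    norm = y / sf.to_numpy()[None, :]
    L = np.log2(norm + 1.0)
    D = np.hstack([X, W])
    coef, *_ = np.linalg.lstsq(D, L.T, rcond=None)
    gamma = coef[X.shape[1] :, :].T  # genes x k
    L_corr = L - gamma @ W.T
    corrected = np.rint(np.maximum(np.exp2(L_corr) - 1.0, 0.0) * sf.to_numpy()[None, :])
    corrected_cm = CountMatrix(
        pd.DataFrame(corrected.astype(np.int64), index=filtered.genes, columns=filtered.samples)
    )
    factors = pd.DataFrame(
        W, index=filtered.samples, columns=[f"W{j + 1}" for j in range(k)]
    )
    return corrected_cm, factors


def vst(
    counts: CountMatrix,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(count/size_factor + pseudocount)."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    if factors is None:
        factors = size_factors(counts)
    f = factors.loc[counts.samples].to_numpy(dtype=float)
    if np.any(f <= 0):
        raise ValidationError("size factors must be positive")
    arr = counts.values.to_numpy(dtype=float) / f[None, :]
    out = pd.DataFrame(
        np.log2(arr + pseudocount), index=counts.genes, columns=counts.samples
    )
    return out
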