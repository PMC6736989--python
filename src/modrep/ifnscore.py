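"""qPCR relative-expression math and the composite five-gene IFN-score.

Delta-Ct normalizes each target to the mean of the GAPDH/GUSB housekeeping
Cts; fold changes follow FC = 2**-(ddCt).  The IFN-score is the mean of the
per-gene Z-scores of log2 relative expression (-dCt, so higher expression
gives a higher score) against the healthy-control mean and SD, divided by
the number of genes scored (five when all are usable).
"""

from __future__ import annotations

import warnings
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import ValidationError
from .synthio import HOUSEKEEPING_GENES, IFN_GENES


def delta_ct(
    records: pd.DataFrame,
    housekeeping: Sequence[str] = HOUSEKEEPING_GENES,
) -> pd.DataFrame:
    """Per sample-gene delta-Ct table (samples x target genes).

    dCt = Ct_target - mean(Ct_housekeeping).  Replicate rows are averaged.
    Samples missing any housekeeping gene are excluded with a warning.
    """
    required = {"sample", "gene", "Ct"}
    if not required <= set(records.columns):
        raise ValidationError(f"qPCR table needs columns {sorted(required)}")
    ct = records.groupby(["sample", "gene"])["Ct"].mean().unstack()
    hk = [g for g in housekeeping if g in ct.columns]
    if len(hk) != len(housekeeping):
        raise ValidationError(f"housekeeping gene(s) missing entirely: "
                              f"{sorted(set(housekeeping) - set(hk))}")
    ok = ct[hk].notna().all(axis=1)
    if not ok.all():
        dropped = list(ct.index[~ok])
        warnings.warn(f"excluding {len(dropped)} sample(s) missing housekeeping Ct: "
                      f"{dropped[:5]}")
        ct = ct.loc[ok]
    hk_mean = ct[hk].mean(axis=1)
    targets = [g for g in ct.columns if g not in housekeeping]
    return ct[targets].sub(hk_mean, axis=0)


def fold_change(dct_sample, dct_reference):
    """FC = 2**-(dCt_sample - dCt_reference); vectorized."""
    ddct = np.asarray(dct_sample, dtype=float) - np.asarray(dct_reference, dtype=float)
    out = np.exp2(-ddct)
    return float(out) if out.ndim == 0 else out


def ifn_score(
    dct: pd.DataFrame,
    hc_samples: Sequence[str],
    genes: Sequence[str] = IFN_GENES,
) -> pd.DataFrame:
    """Composite IFN-score: mean per-gene Z of log2 relative expression vs HC.

    Z-scores use -dCt (log2 relative expression, higher = more expressed)
    with HC mean and SD (ddof=1).  Genes with zero HC SD are excluded and
    the divisor adjusted.  Returns per-gene Z columns plus 'score'.
    """
    hc = [s for s in hc_samples if s in dct.index]
    if len(hc) < 2:
        raise ValidationError("need >= 2 HC samples with usable dCt")
    genes = [g for g in genes if g in dct.columns]
    if not genes:
        raise ValidationError("none of the score genes present in the dCt table")
    rel = -dct[genes]  # log2 relative expression
    mu = rel.loc[hc].mean()
    sd = rel.loc[hc].std(ddof=1)
    usable = [g for g in genes if sd[g] > 0]
    dropped = sorted(set(genes) - set(usable))
    if dropped:
        warnings.warn(f"zero HC SD; excluding gene(s) {dropped} from the score")
    if not usable:
        raise ValidationError("no gene with positive HC SD")
    z = (rel[usable] - mu[usable]) / sd[usable]
    out = z.copy()
    out.columns = [f"Z_{g}" for g in usable]
    out["score"] = z.mean(axis=1)
    out["n_genes"] = len(usable)
    return out


def positivity_threshold(scores: pd.Series, hc_samples: Sequence[str], n_sd: float = 2.0) -> float:
    """Default IFN-positivity cutoff: HC mean + n_sd * HC SD (assumption)."""
    hc = scores.loc[[s for s in hc_samples if s in scores.index]]
    return float(hc.mean() + n_sd * hc.std(ddof=1))


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho with exact permutation p for n <= 9, t-approximation above.

    Two-sided.  Constant input returns (nan, nan) with a warning.  The
    exact path enumerates all rank permutations; it requires tie-free data
    and falls back to the approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValidationError("need paired vectors with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; Spearman correlation undefined")
        return float("nan"), float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 9 and not ties:
        rx = stats.rankdata(x)
        null = np.array(
            [np.corrcoef(rx, perm)[0, 1] for perm in permutations(stats.rankdata(y))]
        )
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
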