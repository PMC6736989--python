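"""Preranked gene-set enrichment with permutation p-values and BH FDR.

The enrichment score is the weighted Kolmogorov-Smirnov running-sum
statistic: walking down the ranked list, hits increment by |score|^weight
(normalized to total 1 over set members) and misses decrement by 1/(N - m);
ES is the maximum-magnitude deviation.  Significance comes from a
gene-permutation null (random same-size gene subsets); p-values are
computed against same-sign null scores with the add-one rule, NES divides
ES by the mean |same-sign null ES|, and FDR is Benjamini-Hochberg across
gene sets within a call.  Directional runs split the query by fold-change
sign and analyse each half separately.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .counts_io import GeneSetCollection, ValidationError


def rank_genes(de_results: pd.DataFrame, stat_col: str = "stat") -> pd.Series:
    """Rank genes by signed statistic, descending; ties break lexicographically.

    NA statistics are dropped (count reported via a warning).  Returns a
    Series indexed by gene, ordered for preranked GSEA.
    """
    s = de_results[stat_col]
    n_na = int(s.isna().sum())
    if n_na:
        warnings.warn(f"dropping {n_na} gene(s) with NA ranking statistic")
        s = s.dropna()
    if s.index.has_duplicates:
        raise ValidationError("duplicate genes in ranking input")
    df = s.rename("score").reset_index()
    df = df.sort_values(["score", df.columns[0]], ascending=[False, True])
    return df.set_index(df.columns[0])["score"]


def enrichment_score(
    ranked: pd.Series, gene_set: Sequence[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running-sum profile."""
    n = len(ranked)
    hit = ranked.index.isin(set(gene_set)).astype(bool)
    m = int(hit.sum())
    if m == 0:
        raise ValidationError("gene set does not overlap the ranked list")
    if m == n:
        raise ValidationError("gene set equals the full ranked list (degenerate)")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    wsum = w[hit].sum()
    if wsum <= 0:
        w = np.ones(n)
        wsum = float(m)
    steps = np.where(hit, w / wsum, 0.0) - np.where(hit, 0.0, 1.0 / (n - m))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(np.clip(running[i], -1.0, 1.0)), running


def _es_batch(positions: np.ndarray, w_full: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for B same-size hit-position sets; positions (B, m)."""
    P = np.sort(positions, axis=1)
    w = w_full[P]
    W = w.sum(axis=1, keepdims=True)
    uniform = (W <= 0).ravel()
    if uniform.any():
        w[uniform] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1)
    m = P.shape[1]
    step = 1.0 / (n - m)
    misses_before = P - np.arange(m)[None, :]
    after = cumw / W - misses_before * step
    before = (cumw - w) / W - misses_before * step
    max_after = after.max(axis=1)
    min_before = before.min(axis=1)
    return np.clip(np.where(max_after > -min_before, max_after, min_before), -1.0, 1.0)


def permutation_test(
    ranked: pd.Series,
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 10000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Gene-permutation GSEA for every set; returns one row per set.

    Null scores come from random same-size subsets of the ranked list.
    p = (1 + #{same-sign null with |ES_null| >= |ES|}) / (1 + #same-sign null);
    the add-one rule keeps p >= 1/(n_perm + 1).  Sets with no overlap are
    flagged with NaN scores.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    items = gene_sets.items() if hasattr(gene_sets, "items") else gene_sets
    n = len(ranked)
    w_full = np.abs(ranked.to_numpy(dtype=float)) ** weight
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in items:
        overlap = ranked.index.isin(set(members))
        m = int(overlap.sum())
        if m == 0:
            rows.append((name, np.nan, np.nan, np.nan, m, n_perm))
            continue
        if m >= n:
            raise ValidationError(f"gene set {name!r} covers the whole ranked list")
        es, _ = enrichment_score(ranked, members, weight)
        null = np.empty(n_perm)
        done = 0
        chunk = max(1, min(n_perm, int(2e6 // max(n, 1)) or 1))
        while done < n_perm:
            b = min(chunk, n_perm - done)
            pos = np.empty((b, m), dtype=np.int64)
            for i in range(b):
                pos[i] = rng.choice(n, size=m, replace=False)
            null[done : done + b] = _es_batch(pos, w_full, n)
            done += b
        same = null >= 0 if es >= 0 else null <= 0
        n_same = int(same.sum())
        exceed = int((np.abs(null[same]) >= abs(es)).sum())
        p = (1.0 + exceed) / (1.0 + n_same)
        denom = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append((name, es, nes, p, m, n_perm))
    out = pd.DataFrame(
        rows, columns=["set", "ES", "NES", "p_perm", "n_overlap", "n_perm"]
    ).set_index("set")
    valid = out["p_perm"].notna()
    fdr = pd.Series(np.nan, index=out.index)
    if valid.any():
        fdr[valid] = false_discovery_control(out.loc[valid, "p_perm"], method="bh")
    out["fdr"] = fdr
    return out


def run_directional(
    de_query: pd.DataFrame,
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 10000,
    seed: int = 0,
    stat_col: str = "stat",
    lfc_col: str = "log2_fold_change",
) -> dict[str, pd.DataFrame]:
    """Run GSEA separately on the up- and down-regulated halves of the query.

    Each half is ranked by |statistic| descending; FDR is computed within
    each direction.  An empty direction yields an empty table (logged).
    """
    out: dict[str, pd.DataFrame] = {}
    for direction, mask in (
        ("up", de_query[lfc_col] > 0),
        ("down", de_query[lfc_col] < 0),
    ):
        sub = de_query.loc[mask & de_query[stat_col].notna()].copy()
        if sub.empty:
            warnings.warn(f"no {direction}-regulated query genes; skipping direction")
            out[direction] = pd.DataFrame(
                columns=["ES", "NES", "p_perm", "n_overlap", "n_perm", "fdr"]
            )
            continue
        sub["_absstat"] = sub[stat_col].abs()
        ranked = rank_genes(sub, stat_col="_absstat")
        out[direction] = permutation_test(
            ranked, gene_sets, n_perm=n_perm, seed=seed, weight=1.0
        )
    return out
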