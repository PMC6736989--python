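"""Unsigned Spearman co-expression network: adjacency, modules, connectivity.

Adjacency is |spearman rho|^beta (beta = 6 by default, chosen against the
scale-free topology criterion).  Modules come from topological-overlap
dissimilarity + average-linkage hierarchical clustering with a static cut
and a minimum module size; clusters whose eigengenes are highly correlated
are merged.  Eigengenes are first principal components of the standardized
module submatrix, sign-oriented to correlate positively with mean module
expression.  Intramodular connectivity is the sum of adjacency to module
co-members, min-max normalized to [0, 1] within each module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .counts_io import ValidationError

BACKGROUND = "background"


@dataclass
class NetworkConfig:
    power: float = 6.0
    min_module_size: int = 30
    cut_height: float = 0.93
    merge_height: float = 0.25
    kme_threshold: float = 0.7

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValidationError("power must be > 0")
        if not (0 < self.cut_height <= 1):
            raise ValidationError("cut_height must be in (0, 1]")


@dataclass
class ModuleAssignment:
    """Gene -> module label map plus per-module eigengene profiles."""

    labels: pd.Series  # index gene, value module label or BACKGROUND
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # samples x modules

    @property
    def module_labels(self) -> list[str]:
        return [m for m in self.labels.unique() if m != BACKGROUND]

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> pd.Series:
        counts = self.labels[self.labels != BACKGROUND].value_counts()
        return counts.sort_values(ascending=False)


def correlation_matrix(vsd: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene-gene Spearman correlation (mid-ranked ties, diagonal 1).

    Constant genes have undefined rank correlation and are dropped with a
    warning.
    """
    if genes is not None:
        genes = [g for g in genes if g in vsd.index]
        vsd = vsd.loc[genes]
    if vsd.shape[1] < 4:
        raise ValidationError("need >= 4 samples for a rank correlation network")
    arr = vsd.to_numpy(dtype=float)
    const = arr.std(axis=1) == 0
    if const.any():
        dropped = list(vsd.index[const])
        warnings.warn(f"dropping {len(dropped)} constant gene(s): {dropped[:5]}")
        vsd = vsd.loc[~const]
        arr = arr[~const]
    ranks = np.apply_along_axis(rankdata, 1, arr)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    cor = (ranks @ ranks.T) / np.outer(norm, norm)
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=vsd.index, columns=vsd.index)


def adjacency(cor: pd.DataFrame, power: float = 6.0) -> pd.DataFrame:
    """Unsigned adjacency a_ij = |cor_ij| ** power."""
    arr = np.abs(cor.to_numpy(dtype=float)) ** power
    np.fill_diagonal(arr, 1.0)
    return pd.DataFrame(arr, index=cor.index, columns=cor.columns)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression over binned degrees.

    Returns NaN for degenerate (all-equal-degree) networks.
    """
    if adj.shape[0] < 20:
        raise ValidationError("need >= 20 genes for a scale-free fit")
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    if np.allclose(k, k[0]):
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            log_k.append(np.log10(mean_k))
            log_p.append(np.log10(freq))
    if len(log_k) < 3:
        return float("nan")
    log_k = np.asarray(log_k)
    log_p = np.asarray(log_p)
    r = np.corrcoef(log_k, log_p)[0, 1]
    return float(r**2)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix; diagonal 1."""
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    L = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def module_eigengene(vsd: pd.DataFrame, module_genes: Sequence[str]) -> pd.Series:
    """First principal component of the standardized module submatrix.

    Unit L2 norm; sign oriented to correlate positively with the module's
    mean standardized expression profile.
    """
    genes = [g for g in module_genes if g in vsd.index]
    if len(genes) < 2 or vsd.shape[1] < 2:
        raise ValidationError("eigengene needs >= 2 genes and >= 2 samples")
    sub = vsd.loc[genes].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    # samples x genes for PCA over samples
    u, s, vt = np.linalg.svd(z.T, full_matrices=False)
    pc = u[:, 0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    nrm = np.linalg.norm(pc)
    if nrm > 0:
        pc = pc / nrm
    return pd.Series(pc, index=vsd.columns, name="eigengene")


def detect_modules(
    adj: pd.DataFrame,
    config: NetworkConfig | None = None,
    vsd: pd.DataFrame | None = None,
) -> ModuleAssignment:
    """TOM dissimilarity + average-linkage clustering with tree cut and rescue.

    The tree is cut conservatively (module cores form well below the cut;
    cross-module cluster merges happen above it); clusters below
    ``min_module_size`` become background.  When ``vsd`` is given, modules
    whose eigengenes correlate above 1 - merge_height are merged, and
    unassigned genes with eigengene correlation (kME) above
    ``kme_threshold`` are rescued into their best-matching module.  Labels
    are M1, M2, ... ordered by decreasing size.
    """
    config = config or NetworkConfig()
    genes = list(adj.index)
    if len(genes) < config.min_module_size:
        return ModuleAssignment(pd.Series(BACKGROUND, index=pd.Index(genes, name="gene")))

    diss = 1.0 - tom_similarity(adj).to_numpy()
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    flat = hierarchy.fcluster(link, t=config.cut_height, criterion="distance")

    labels = pd.Series(flat, index=pd.Index(genes, name="gene"))
    sizes = labels.value_counts()
    keep = sizes.index[sizes >= config.min_module_size]
    assigned = labels.where(labels.isin(keep), other=-1)

    if vsd is not None and len(keep) > 1:
        assigned = _merge_close_modules(assigned, vsd, config.merge_height)
    if vsd is not None and (assigned != -1).any():
        assigned = _rescue_by_kme(assigned, vsd, config.kme_threshold)
        assigned = _refine_by_kme(assigned, vsd)

    # relabel by decreasing size
    final = pd.Series(BACKGROUND, index=assigned.index)
    order = assigned[assigned != -1].value_counts().index
    for rank, old in enumerate(order, start=1):
        final[assigned == old] = f"M{rank}"

    eig = {}
    if vsd is not None:
        for m in [f"M{r}" for r in range(1, len(order) + 1)]:
            members = list(final.index[final == m])
            if len(members) >= 2:
                eig[m] = module_eigengene(vsd, members)
    eigengenes = pd.DataFrame(eig) if eig else pd.DataFrame()
    return ModuleAssignment(final, eigengenes)


def _merge_close_modules(
    assigned: pd.Series, vsd: pd.DataFrame, merge_height: float
) -> pd.Series:
    """Iteratively merge module pairs whose eigengene dissimilarity < merge_height."""
    assigned = assigned.copy()
    while True:
        mods = [m for m in assigned.unique() if m != -1]
        if len(mods) < 2:
            return assigned
        eigs = {}
        for m in mods:
            members = list(assigned.index[assigned == m])
            eigs[m] = module_eigengene(vsd, members).to_numpy()
        best = None
        for i, mi in enumerate(mods):
            for mj in mods[i + 1 :]:
                c = np.corrcoef(eigs[mi], eigs[mj])[0, 1]
                d = 1.0 - c
                if d < merge_height and (best is None or d < best[0]):
                    best = (d, mi, mj)
        if best is None:
            return assigned
        _, mi, mj = best
        assigned[assigned == mj] = mi


def _rescue_by_kme(assigned: pd.Series, vsd: pd.DataFrame, threshold: float) -> pd.Series:
    """Assign leftover genes whose eigengene correlation exceeds the threshold."""
    assigned = assigned.copy()
    mods = [m for m in assigned.unique() if m != -1]
    eigs = {}
    for m in mods:
        eigs[m] = module_eigengene(vsd, list(assigned.index[assigned == m])).to_numpy()
    loose = [g for g in assigned.index[assigned == -1] if g in vsd.index]
    if not loose or not mods:
        return assigned
    sub = vsd.loc[loose].to_numpy(dtype=float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(sub, axis=1)
    norms[norms == 0] = 1.0
    kme = np.empty((len(loose), len(mods)))
    for j, m in enumerate(mods):
        e = eigs[m] - eigs[m].mean()
        kme[:, j] = (sub @ e) / (norms * np.linalg.norm(e))
    best = np.argmax(kme, axis=1)
    best_val = kme[np.arange(len(loose)), best]
    for g, j, v in zip(loose, best, best_val):
        if v > threshold:
            assigned[g] = mods[j]
    return assigned


def _refine_by_kme(assigned: pd.Series, vsd: pd.DataFrame, margin: float = 0.1) -> pd.Series:
    """Move a gene to another module when its eigengene fit is clearly better."""
    assigned = assigned.copy()
    mods = [m for m in assigned.unique() if m != -1]
    if len(mods) < 2:
        return assigned
    eigs = {m: module_eigengene(vsd, list(assigned.index[assigned == m])).to_numpy()
            for m in mods}
    genes = [g for g in assigned.index if assigned[g] != -1 and g in vsd.index]
    sub = vsd.loc[genes].to_numpy(dtype=float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(sub, axis=1)
    norms[norms == 0] = 1.0
    kme = np.empty((len(genes), len(mods)))
    for j, m in enumerate(mods):
        e = eigs[m] - eigs[m].mean()
        kme[:, j] = (sub @ e) / (norms * np.linalg.norm(e))
    col_of = {m: j for j, m in enumerate(mods)}
    best = np.argmax(kme, axis=1)
    for i, g in enumerate(genes):
        own = col_of[assigned[g]]
        if best[i] != own and kme[i, best[i]] > kme[i, own] + margin:
            assigned[g] = mods[best[i]]
    return assigned


def connectivity(adj: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """Per-gene raw and [0,1]-normalized intramodular connectivity.

    k_raw is the sum of adjacency to same-module co-members; k_norm maps the
    module's k_raw range onto [0, 1] (all-equal connectivities map to 0 by
    convention).  Single-gene modules are excluded.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    genes = list(adj.index)
    labels = assignment.labels.reindex(genes)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValidationError(f"assignment missing genes: {missing[:5]}")
    records = []
    for m in assignment.module_labels:
        idx = np.flatnonzero((labels == m).to_numpy())
        if idx.size < 2:
            warnings.warn(f"module {m!r} has < 2 genes; connectivity undefined")
            continue
        sub = a[np.ix_(idx, idx)]
        k_raw = sub.sum(axis=1)
        span = k_raw.max() - k_raw.min()
        k_norm = (k_raw - k_raw.min()) / span if span > 0 else np.zeros_like(k_raw)
        for j, gi in enumerate(idx):
            records.append((genes[gi], m, k_raw[j], k_norm[j]))
    out = pd.DataFrame(records, columns=["gene", "module", "k_raw", "k_norm"])
    return out.set_index("gene")
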