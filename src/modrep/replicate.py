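"""Cross-cohort module replication, signatures, hubs, concordance.

Module pairs from two independently constructed networks are scored with a
one-sided (enrichment) Fisher exact test over the shared gene universe.
Pairs below the p threshold define replicated signatures: the pair
intersection restricted to genes differentially expressed in both cohorts.
Several discovery modules may map onto one replication module; their
contributions are merged into a single signature.  Hub genes are signature
members whose normalized intramodular connectivity strictly exceeds the
signature-wise 75th percentile in BOTH cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coexnet import ModuleAssignment
from .counts_io import ValidationError


@dataclass
class ModuleOverlapTable:
    counts: pd.DataFrame  # rows = cohort-A modules, cols = cohort-B modules
    pvalues: pd.DataFrame
    universe_size: int


@dataclass
class Signature:
    label: str
    genes: list[str]
    direction: str  # majority direction: "up" | "down" | "mixed"
    gene_direction: dict[str, str] = field(default_factory=dict)
    hub_genes: list[str] = field(default_factory=list)
    source_modules_a: list[str] = field(default_factory=list)
    source_modules_b: list[str] = field(default_factory=list)


def fisher_overlap_p(n_universe: int, n_a: int, n_b: int, n_overlap: int) -> float:
    """One-sided enrichment p: P(overlap >= observed) under hypergeometric."""
    if n_overlap > min(n_a, n_b) or n_a > n_universe or n_b > n_universe:
        raise ValidationError("inconsistent 2x2 table")
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


def module_overlap(
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    universe: Iterable[str],
) -> ModuleOverlapTable:
    """Cross-tabulate modules of two cohorts with Fisher enrichment p-values."""
    universe = set(universe)
    if not universe:
        raise ValidationError("empty gene universe")
    la = assign_a.labels[assign_a.labels.index.isin(universe)]
    lb = assign_b.labels[assign_b.labels.index.isin(universe)]
    mods_a = [m for m in assign_a.module_labels if (la == m).any()]
    mods_b = [m for m in assign_b.module_labels if (lb == m).any()]
    n = len(universe)
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b, dtype=int)
    pvals = pd.DataFrame(1.0, index=mods_a, columns=mods_b, dtype=float)
    members_a = {m: set(la.index[la == m]) for m in mods_a}
    members_b = {m: set(lb.index[lb == m]) for m in mods_b}
    for ma in mods_a:
        for mb in mods_b:
            k = len(members_a[ma] & members_b[mb])
            counts.loc[ma, mb] = k
            pvals.loc[ma, mb] = fisher_overlap_p(n, len(members_a[ma]), len(members_b[mb]), k)
    return ModuleOverlapTable(counts, pvals, n)


def replicated_signatures(
    overlap: ModuleOverlapTable,
    assign_a: ModuleAssignment,
    assign_b: ModuleAssignment,
    degs_a: set[str],
    degs_b: set[str],
    lfc_a: Mapping[str, float],
    lfc_b: Mapping[str, float],
    p_threshold: float = 1e-20,
) -> list[Signature]:
    """Extract replicated signatures from significantly overlapping module pairs.

    Pairs with p < p_threshold are grouped by cohort-B module (many-to-one
    pairing allowed); each signature holds the replicated DEGs of the pooled
    intersections.  Per-gene direction uses the sign of log2FC where the two
    cohorts agree; discordant genes are tagged "discordant".
    """
    replicated_degs = degs_a & degs_b
    sigs: list[Signature] = []
    sig_idx = 0
    for mb in overlap.pvalues.columns:
        paired_a = [ma for ma in overlap.pvalues.index if overlap.pvalues.loc[ma, mb] < p_threshold]
        if not paired_a:
            continue
        members_b = set(assign_b.members(mb))
        genes: set[str] = set()
        for ma in paired_a:
            genes |= set(assign_a.members(ma)) & members_b
        genes &= replicated_degs
        if not genes:
            continue
        gene_dir: dict[str, str] = {}
        for g in sorted(genes):
            sa = np.sign(lfc_a.get(g, 0.0))
            sb = np.sign(lfc_b.get(g, 0.0))
            if sa == sb and sa != 0:
                gene_dir[g] = "up" if sa > 0 else "down"
            else:
                gene_dir[g] = "discordant"
        n_up = sum(1 for d in gene_dir.values() if d == "up")
        n_down = sum(1 for d in gene_dir.values() if d == "down")
        if n_up and not n_down:
            direction = "up"
        elif n_down and not n_up:
            direction = "down"
        elif n_up or n_down:
            direction = "up" if n_up >= n_down else "down"
        else:
            direction = "mixed"
        sig_idx += 1
        sigs.append(
            Signature(
                label=f"S{sig_idx}",
                genes=sorted(genes),
                direction=direction,
                gene_direction=gene_dir,
                source_modules_a=sorted(paired_a),
                source_modules_b=[mb],
            )
        )
    return sigs


def hub_genes(
    conn_a: pd.DataFrame,
    conn_b: pd.DataFrame,
    signature_genes: Sequence[str],
    percentile: float = 75.0,
) -> set[str]:
    """Signature genes above the signature-wise connectivity percentile in both cohorts.

    The percentile (linear interpolation) is computed over the signature
    members' k_norm within each cohort; strict inequality, so all-equal
    connectivities yield no hubs.
    """
    genes = [g for g in signature_genes if g in conn_a.index and g in conn_b.index]
    if len(genes) < 4:
        warnings.warn(f"signature has {len(genes)} usable genes (<4); no hubs called")
        return set()
    ka = conn_a.loc[genes, "k_norm"].astype(float)
    kb = conn_b.loc[genes, "k_norm"].astype(float)
    ta = np.percentile(ka.to_numpy(), percentile)
    tb = np.percentile(kb.to_numpy(), percentile)
    return set(ka.index[(ka > ta) & (kb > tb)])


@dataclass
class ConcordanceReport:
    comparison: str
    n_shared: int
    fraction_same_sign: float  # NaN when n_shared == 0


def directionality_concordance(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    alpha: float = 0.05,
    comparison: str = "",
) -> ConcordanceReport:
    """Fraction of genes significant in both tables with matching log2FC sign.

    Genes with a zero fold-change in either table are excluded.
    """
    sig_a = de_a.index[de_a["pvalue"] < alpha]
    sig_b = de_b.index[de_b["pvalue"] < alpha]
    shared = sig_a.intersection(sig_b)
    la = de_a.loc[shared, "log2_fold_change"]
    lb = de_b.loc[shared, "log2_fold_change"]
    nonzero = (la != 0) & (lb != 0) & la.notna() & lb.notna()
    la, lb = la[nonzero], lb[nonzero]
    n = len(la)
    frac = float(np.mean(np.sign(la) == np.sign(lb))) if n else float("nan")
    return ConcordanceReport(comparison=comparison, n_shared=n, fraction_same_sign=frac)
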