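"""End-to-end orchestration: normalize -> diffexp -> network -> replicate
-> gsea -> stratify, with a provenance manifest.

Inputs are either on-disk count matrices + sample sheets for the two
cohorts or a :class:`modrep.synthio.SimConfig` to generate them.  Unwanted
variation is corrected per cohort for the differential-expression/network
stages and jointly across cohorts for the classifier stage.  Every output
is a plain-text table; the manifest records the seed, parameters and a
sha256 of each written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import coexnet, counts_io, diffexp, gsea, normalize, replicate, stratify, synthio
from .coexnet import NetworkConfig
from .counts_io import CountMatrix, GeneSetCollection, SampleSheet, ValidationError

log = logging.getLogger("modrep")

PAIRWISE = [("nSS", "HC"), ("pSS", "HC"), ("pSS", "nSS")]


@dataclass
class RunConfig:
    out_dir: str | Path
    counts_paths: Mapping[str, str] | None = None  # cohort -> TSV path
    samples_paths: Mapping[str, str] | None = None  # cohort -> CSV path
    sim: synthio.SimConfig | None = None
    ruv_k: int = 1
    deg_alpha: float = 0.05
    network: NetworkConfig = field(default_factory=NetworkConfig)
    p_threshold: float = 1e-20
    hub_percentile: float = 75.0
    gsea_sets_path: str | None = None
    gsea_n_perm: int = 1000
    folds: int = 10
    seed: int = 1

    def validate(self) -> None:
        if self.sim is None:
            if not self.counts_paths or not self.samples_paths:
                raise ValidationError("need either sim config or counts+samples paths")
            for label, path in list(self.counts_paths.items()) + list(
                self.samples_paths.items()
            ):
                if not Path(path).exists():
                    raise ValidationError(f"missing input for cohort {label!r}: {path}")
            if set(self.counts_paths) != set(self.samples_paths):
                raise ValidationError("counts and samples cohorts differ")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class CohortResult:
    counts: CountMatrix
    sheet: SampleSheet
    corrected: CountMatrix
    vsd: pd.DataFrame
    de_tables: dict[str, pd.DataFrame]
    degs: set[str]
    assignment: coexnet.ModuleAssignment
    connectivity: pd.DataFrame
    adjacency: pd.DataFrame


def _analyze_cohort(
    counts: CountMatrix, sheet: SampleSheet, cfg: RunConfig, out: Path, label: str
) -> CohortResult:
    corrected, factors = normalize.remove_unwanted_variation(counts, sheet, k=cfg.ruv_k)
    sf = normalize.size_factors(corrected)
    vsd = normalize.vst(corrected, sf)
    counts_io.write_counts(corrected, out / f"{label}_corrected_counts.tsv")
    factors.to_csv(out / f"{label}_ruv_factors.csv")
    counts_io.write_matrix_tsv(vsd, out / f"{label}_vsd.tsv")

    # tests run on the uncorrected (filtered) counts with the estimated
    # unwanted factor as a design covariate; the corrected counts feed the
    # rank-based network stage
    filtered = normalize.drop_all_zero_genes(counts)
    sf_raw = normalize.size_factors(filtered)
    disp = diffexp.estimate_dispersion(filtered, sf_raw, sheet)
    tables: dict[str, pd.DataFrame] = {}
    for a, b in PAIRWISE:
        tables[f"{a}_vs_{b}"] = diffexp.wald_test(
            filtered, sf_raw, sheet, (a, b), disp, covariates=factors
        )
    tables["LRT"] = diffexp.lrt_test(filtered, sf_raw, sheet, disp, covariates=factors)
    de_all = pd.concat(tables.values())
    de_all.to_csv(out / f"{label}_diffexp.tsv", sep="\t")
    degs = diffexp.deg_union(tables.values(), cfg.deg_alpha)

    net_genes = sorted(degs & set(vsd.index))
    cor = coexnet.correlation_matrix(vsd, net_genes)
    adj = coexnet.adjacency(cor, cfg.network.power)
    assignment = coexnet.detect_modules(adj, cfg.network, vsd=vsd)
    conn = coexnet.connectivity(adj, assignment)
    assignment.labels.rename("module").to_csv(out / f"{label}_modules.tsv", sep="\t")
    if not assignment.eigengenes.empty:
        assignment.eigengenes.to_csv(out / f"{label}_eigengenes.csv")
    conn.to_csv(out / f"{label}_connectivity.tsv", sep="\t")
    return CohortResult(counts, sheet, corrected, vsd, tables, degs, assignment, conn, adj)


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    manifest: dict = {
        "seed": cfg.seed,
        "parameters": {
            "ruv_k": cfg.ruv_k,
            "deg_alpha": cfg.deg_alpha,
            "power": cfg.network.power,
            "min_module_size": cfg.network.min_module_size,
            "cut_height": cfg.network.cut_height,
            "p_threshold": cfg.p_threshold,
            "hub_percentile": cfg.hub_percentile,
            "gsea_n_perm": cfg.gsea_n_perm,
            "folds": cfg.folds,
            "fisher_sidedness": "one-sided enrichment",
            "tree_cut": "static TOM-dissimilarity cut (assumed defaults)",
        },
        "stages": stages,
        "files": {},
    }

    # ---- inputs
    data: dict[str, tuple[CountMatrix, SampleSheet]] = {}
    if cfg.sim is not None:
        for label, (cm, sheet, truth) in synthio.generate_two_cohorts(cfg.sim).items():
            counts_io.write_counts(cm, out / f"{label}_counts.tsv")
            counts_io.write_sample_sheet(sheet, out / f"{label}_samples.csv")
            truth.to_json(out / f"{label}_truth.json")
            data[label] = (cm, sheet)
    else:
        for label in cfg.counts_paths:
            cm = counts_io.read_counts(cfg.counts_paths[label])
            sheet = counts_io.read_sample_sheet(cfg.samples_paths[label])
            sheet.check_matches(cm)
            data[label] = (cm, sheet)
    cohort_labels = sorted(data)
    if len(cohort_labels) != 2:
        raise ValidationError(f"expected exactly 2 cohorts, got {cohort_labels}")
    ca, cb = cohort_labels  # "discovery" < "replication" sorts correctly

    # ---- per-cohort normalize / diffexp / network
    results: dict[str, CohortResult] = {}
    for label in cohort_labels:
        log.info("analyzing cohort %s", label)
        results[label] = _analyze_cohort(*data[label], cfg, out, label)
    stages += ["normalize", "diffexp", "network"]

    # ---- replication
    ra, rb = results[ca], results[cb]
    universe = (ra.degs & set(ra.vsd.index)) & (rb.degs & set(rb.vsd.index))
    overlap = replicate.module_overlap(ra.assignment, rb.assignment, universe)
    lfc_a = ra.de_tables["pSS_vs_HC"]["log2_fold_change"].to_dict()
    lfc_b = rb.de_tables["pSS_vs_HC"]["log2_fold_change"].to_dict()
    sigs = replicate.replicated_signatures(
        overlap, ra.assignment, rb.assignment, ra.degs, rb.degs,
        lfc_a, lfc_b, cfg.p_threshold,
    )
    for sig in sigs:
        sig.hub_genes = sorted(
            replicate.hub_genes(ra.connectivity, rb.connectivity, sig.genes,
                                cfg.hub_percentile)
        )
    concord = replicate.directionality_concordance(
        ra.de_tables["pSS_vs_HC"], rb.de_tables["pSS_vs_HC"],
        cfg.deg_alpha, comparison="pSS_vs_HC",
    )
    overlap.counts.to_csv(out / "module_overlap_counts.tsv", sep="\t")
    overlap.pvalues.to_csv(out / "module_overlap_pvalues.tsv", sep="\t")
    sig_coll = GeneSetCollection()
    for sig in sigs:
        sig_coll.add(sig.label, sig.genes, f"direction={sig.direction}")
    if len(sig_coll):
        counts_io.write_gmt(sig_coll, out / "signatures.gmt")
    hubs_rows = [
        (sig.label, g) for sig in sigs for g in sig.hub_genes
    ]
    pd.DataFrame(hubs_rows, columns=["signature", "gene"]).to_csv(
        out / "hub_genes.tsv", sep="\t", index=False
    )
    with open(out / "concordance.json", "w") as fh:
        json.dump(
            {"comparison": concord.comparison, "n_shared": concord.n_shared,
             "fraction_same_sign": concord.fraction_same_sign},
            fh, indent=1,
        )
    stages.append("replicate")

    # ---- GSEA: replication-cohort ranking against external (or signature) sets
    if cfg.gsea_sets_path:
        sets = counts_io.read_gmt(cfg.gsea_sets_path)
    else:
        sets = sig_coll  # internal replication check when no external sets given
    gsea_out: dict[str, pd.DataFrame] = {}
    if len(sets):
        gsea_out = gsea.run_directional(
            rb.de_tables["pSS_vs_HC"], sets, n_perm=cfg.gsea_n_perm, seed=cfg.seed
        )
        for direction, table in gsea_out.items():
            table.to_csv(out / f"gsea_{direction}.tsv", sep="\t")
    stages.append("gsea")

    # ---- stratify: joint correction across cohorts, classifier on pSS vs HC
    shared_genes = ra.counts.values.index.intersection(rb.counts.values.index)
    joint_counts = CountMatrix(
        pd.concat(
            [ra.counts.values.loc[shared_genes], rb.counts.values.loc[shared_genes]],
            axis=1,
        )
    )
    joint_sheet = SampleSheet(
        pd.concat([ra.sheet.table, rb.sheet.table], ignore_index=True)
    )
    joint_corr, _ = normalize.remove_unwanted_variation(
        joint_counts, joint_sheet, k=cfg.ruv_k
    )
    joint_vsd = normalize.vst(joint_corr, normalize.size_factors(joint_corr))
    groups = joint_sheet.group_of()
    train_ids = [s for s in joint_vsd.columns if groups[s] in ("pSS", "HC")]
    labels = groups.loc[train_ids]
    candidates = sorted(
        {g for sig in sigs for g in sig.genes} & set(joint_vsd.index)
    )
    strat_report: dict = {}
    if candidates and len(set(labels)) == 2:
        features = stratify.select_features(
            joint_vsd, labels, candidates, folds=cfg.folds, seed=cfg.seed
        )
        proba, metrics = stratify.fit_predict_cv(
            joint_vsd, labels, features, folds=cfg.folds, seed=cfg.seed
        )
        bundle = stratify.train_classifier(joint_vsd, labels, features, seed=cfg.seed)
        nss_ids = [s for s in joint_vsd.columns if groups[s] == "nSS"]
        calls = stratify.classify_intermediate(bundle, joint_vsd, nss_ids)
        proba.to_csv(out / "classifier_oof_probabilities.csv")
        calls.to_csv(out / "nss_stratification.csv")
        strat_report = {
            "n_features": len(features),
            "features": features[:50],
            **metrics,
            "n_pss_like": int((calls["label"] == "pSS-like").sum()),
        }
    with open(out / "stratify_report.json", "w") as fh:
        json.dump(strat_report, fh, indent=1)
    stages.append("stratify")

    # ---- manifest
    manifest["signatures"] = {
        s.label: {
            "n_genes": len(s.genes),
            "direction": s.direction,
            "hubs": s.hub_genes,
            "source_a": s.source_modules_a,
            "source_b": s.source_modules_b,
        }
        for s in sigs
    }
    manifest["concordance"] = concord.fraction_same_sign
    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
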