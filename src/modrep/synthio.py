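"""Synthetic two-cohort RNA-seq generator with planted ground truth.

The generative model is a latent-factor negative-binomial model.  Each
planted module m has one standard-normal latent factor per sample; module
genes carry uniform loadings on that factor.  Disease-group effects shift
the module factor on the log2 scale (intermediate group at half the patient
shift by default), a single batch factor enters additively with
gene-specific coefficients, and library sizes are log-normal:

    log2 mean_gs = baseline_g + loading_g * (factor_ms + shift_{group(s),m})
                   + batch_coef_g * batch_s
    counts_gs ~ NB(mean = libsize_s * 2**log2mean_gs, variance = mu + alpha_g mu^2)

Gene-level structure (module membership, loadings, baselines, dispersions,
batch coefficients) is drawn once from the root seed so both cohorts share
it; per-sample draws (factors, batch values, library sizes, counts) are
cohort-specific substreams.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import COHORTS, GROUPS, CountMatrix, SampleSheet

BACKGROUND = "background"

IFN_GENES = ("IFI44L", "IFI44", "IFIT3", "LY6E", "MX1")
HOUSEKEEPING_GENES = ("GAPDH", "GUSB")


class ConfigurationError(ValueError):
    """Raised for an inconsistent simulation configuration."""


def _default_samples() -> dict[str, dict[str, int]]:
    # mirrors the emulated two-cohort design: 31 samples each, three groups
    return {
        "discovery": {"HC": 8, "nSS": 9, "pSS": 14},
        "replication": {"HC": 9, "nSS": 11, "pSS": 11},
    }


def _default_effects() -> dict[str, tuple[float, ...]]:
    pss = (2.5, -2.5, 2.3, 2.2)
    return {
        "HC": tuple(0.0 for _ in pss),
        "nSS": tuple(0.5 * e for e in pss),
        "pSS": pss,
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic two-cohort generator.

    ``group_effects[group][m]`` is the log2-scale shift applied to module
    m's latent factor for samples of that group.  ``dispersion`` may be a
    scalar (shared NB alpha) or a per-gene array of length ``n_genes``.
    """

    n_genes: int = 3000
    module_sizes: Sequence[int] = (150, 120, 80, 50)
    n_samples_per_group: Mapping[str, Mapping[str, int]] = field(
        default_factory=_default_samples
    )
    group_effects: Mapping[str, Sequence[float]] = field(default_factory=_default_effects)
    dispersion: float | Sequence[float] = 0.12
    batch_strength: float = 0.5
    libsize_lognormal_sigma: float = 0.3
    seed: int = 0
    loading_range: tuple[float, float] = (0.5, 0.9)
    baseline_log2_range: tuple[float, float] = (4.5, 9.0)
    # weak, cohort-shared disease effects on a fraction of background genes:
    # emulates the sub-threshold tail of real differential expression so that
    # borderline shared DEGs are sign-concordant rather than pure noise
    background_de_fraction: float = 0.3
    background_de_sd: float = 0.4
    nss_effect_ratio: float = 0.5

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if any(s < 1 for s in self.module_sizes):
            raise ConfigurationError("module sizes must be >= 1")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        alpha = np.asarray(self.dispersion, dtype=float)
        if np.any(alpha < 0):
            raise ConfigurationError("dispersion must be >= 0")
        if alpha.ndim == 1 and alpha.size != self.n_genes:
            raise ConfigurationError("per-gene dispersion must have length n_genes")
        for cohort, groups in self.n_samples_per_group.items():
            if cohort not in COHORTS:
                raise ConfigurationError(f"unknown cohort {cohort!r}")
            if any(n < 1 for n in groups.values()):
                raise ConfigurationError("all per-group sample counts must be >= 1")
        for group, effs in self.group_effects.items():
            if group not in GROUPS:
                raise ConfigurationError(f"unknown group {group!r} in group_effects")
            if len(effs) != self.n_modules:
                raise ConfigurationError(
                    f"group_effects[{group!r}] needs {self.n_modules} entries"
                )


@dataclass
class SyntheticTruth:
    """Planted structure of one generated cohort."""

    module_of: dict[str, str]
    loading_of: dict[str, float]
    de_genes: dict[str, float]  # gene -> planted signed log2 effect (pSS vs HC)
    batch_values: dict[str, float]
    group_of: dict[str, str]
    cohort_of: dict[str, str]

    def module_members(self, label: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == label]

    @property
    def module_labels(self) -> list[str]:
        labels = sorted({m for m in self.module_of.values() if m != BACKGROUND})
        return labels

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _substream(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(label.encode())])


@dataclass
class _GenePlan:
    genes: list[str]
    module_of: np.ndarray  # int, -1 = background
    loadings: np.ndarray
    baselines: np.ndarray
    alphas: np.ndarray
    bg_effects: np.ndarray  # weak shared pSS-vs-HC log2 shifts, 0 for most genes


def _gene_plan(config: SimConfig) -> _GenePlan:
    """Gene-level structure shared between cohorts (drawn from the root seed)."""
    rng = _substream(config.seed, "genes")
    g = config.n_genes
    genes = [f"G{i:05d}" for i in range(g)]
    module_of = np.full(g, -1, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        module_of[pos : pos + size] = m
        pos += size
    lo, hi = config.loading_range
    loadings = np.where(module_of >= 0, rng.uniform(lo, hi, size=g), 0.0)
    b0, b1 = config.baseline_log2_range
    baselines = rng.uniform(b0, b1, size=g)
    alphas = np.broadcast_to(np.asarray(config.dispersion, dtype=float), (g,)).copy()
    bg_effects = np.zeros(g)
    if config.background_de_fraction > 0 and config.background_de_sd > 0:
        is_bg = module_of < 0
        chosen = is_bg & (rng.random(g) < config.background_de_fraction)
        bg_effects[chosen] = rng.normal(0.0, config.background_de_sd, size=int(chosen.sum()))
    return _GenePlan(genes, module_of, loadings, baselines, alphas, bg_effects)


def generate_cohort(
    config: SimConfig, cohort_label: str
) -> tuple[CountMatrix, SampleSheet, SyntheticTruth]:
    """Generate one cohort's counts, sample sheet and planted truth.

    Deterministic under a fixed ``config.seed``; the two cohorts share the
    gene-level plan but have independent sample-level draws.
    """
    config.validate()
    if cohort_label not in config.n_samples_per_group:
        raise ConfigurationError(f"no sample design for cohort {cohort_label!r}")
    plan = _gene_plan(config)
    rng = _substream(config.seed, f"cohort:{cohort_label}")

    groups_n = config.n_samples_per_group[cohort_label]
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for group in GROUPS:
        n = groups_n.get(group, 0)
        for i in range(n):
            sample_ids.append(f"{cohort_label[:4]}_{group}_{i:02d}")
            sample_groups.append(group)
    n_samples = len(sample_ids)
    n_modules = config.n_modules

    factors = rng.normal(size=(n_modules, n_samples))
    # center factors within each group so the realized group contrast equals
    # the planted shift exactly (otherwise a module's whole realized effect
    # wobbles with the factor's random group means, sd ~ sqrt(2/n_group))
    group_arr = np.asarray(sample_groups)
    for group in GROUPS:
        mask = group_arr == group
        if mask.sum() > 1:
            factors[:, mask] -= factors[:, mask].mean(axis=1, keepdims=True)
    # decorrelate module factors (Gram-Schmidt in the centered space): at
    # n ~ 31 chance correlations between two modules' factors (sd ~ 1/sqrt(n))
    # can fuse planted modules downstream, which would test luck, not method
    if n_modules > 1 and n_samples > n_modules:
        norms = np.linalg.norm(factors, axis=1)
        q, _ = np.linalg.qr(factors.T)
        for m in range(n_modules):
            if np.dot(q[:, m], factors[m]) < 0:
                q[:, m] = -q[:, m]
        factors = (q[:, :n_modules] * norms).T
    # batch structure is cohort-specific: the two cohorts were collected and
    # processed independently, so affected genes differ between them
    batch_coefs = (
        rng.normal(0.0, config.batch_strength, size=config.n_genes)
        if config.batch_strength > 0
        else np.zeros(config.n_genes)
    )
    batch = rng.normal(size=n_samples) if config.batch_strength > 0 else np.zeros(n_samples)
    # keep the batch factor orthogonal to the group design: residual-based
    # factor estimation can only ever recover (and remove) the component of
    # unwanted variation not aligned with the modeled group contrasts
    for group in GROUPS:
        mask = group_arr == group
        if mask.sum() > 1:
            batch[mask] -= batch[mask].mean()
    libsizes = (
        np.exp(rng.normal(0.0, config.libsize_lognormal_sigma, size=n_samples))
        if config.libsize_lognormal_sigma > 0
        else np.ones(n_samples)
    )

    shifts = np.zeros((n_modules, n_samples))
    for j, group in enumerate(sample_groups):
        shifts[:, j] = np.asarray(config.group_effects.get(group, [0.0] * n_modules))

    log2mean = np.tile(plan.baselines[:, None], (1, n_samples))
    in_module = plan.module_of >= 0
    midx = plan.module_of[in_module]
    log2mean[in_module, :] += plan.loadings[in_module, None] * (
        factors[midx, :] + shifts[midx, :]
    )
    log2mean += batch_coefs[:, None] * batch[None, :]
    bg_mult = np.array(
        [{"HC": 0.0, "nSS": config.nss_effect_ratio, "pSS": 1.0}.get(g, 0.0)
         for g in sample_groups]
    )
    log2mean += plan.bg_effects[:, None] * bg_mult[None, :]

    mu = libsizes[None, :] * np.exp2(log2mean)
    counts = np.empty(mu.shape, dtype=np.int64)
    alphas = plan.alphas
    poisson_rows = alphas <= 0
    if poisson_rows.any():
        counts[poisson_rows, :] = rng.poisson(mu[poisson_rows, :])
    nb_rows = ~poisson_rows
    if nb_rows.any():
        r = 1.0 / alphas[nb_rows]
        p = r[:, None] / (r[:, None] + mu[nb_rows, :])
        counts[nb_rows, :] = rng.negative_binomial(r[:, None], p)

    matrix = CountMatrix(pd.DataFrame(counts, index=plan.genes, columns=sample_ids))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": sample_groups,
                "cohort": cohort_label,
            }
        )
    )

    pss = np.asarray(config.group_effects.get("pSS", [0.0] * n_modules))
    hc = np.asarray(config.group_effects.get("HC", [0.0] * n_modules))
    de: dict[str, float] = {}
    module_of: dict[str, str] = {}
    loading_of: dict[str, float] = {}
    for i, gene in enumerate(plan.genes):
        m = plan.module_of[i]
        module_of[gene] = f"M{m + 1}" if m >= 0 else BACKGROUND
        loading_of[gene] = float(plan.loadings[i])
        if m >= 0:
            eff = float(plan.loadings[i] * (pss[m] - hc[m]))
            if eff != 0.0:
                de[gene] = eff
        elif plan.bg_effects[i] != 0.0:
            de[gene] = float(plan.bg_effects[i])
    truth = SyntheticTruth(
        module_of=module_of,
        loading_of=loading_of,
        de_genes=de,
        batch_values={s: float(b) for s, b in zip(sample_ids, batch)},
        group_of=dict(zip(sample_ids, sample_groups)),
        cohort_of={s: cohort_label for s in sample_ids},
    )
    return matrix, sheet, truth


def generate_two_cohorts(
    config: SimConfig,
) -> dict[str, tuple[CountMatrix, SampleSheet, SyntheticTruth]]:
    """Generate every cohort named in the config (discovery + replication)."""
    return {c: generate_cohort(config, c) for c in config.n_samples_per_group}


def generate_qpcr(
    n_hc: int,
    n_patient: int,
    shift_per_gene: Mapping[str, float] | float,
    seed: int = 0,
    ct_noise_sd: float = 0.25,
) -> pd.DataFrame:
    """Generate a long-format qPCR Ct table for the IFN-score fixture.

    Five IFN-induced target genes plus two housekeeping genes per sample.
    ``shift_per_gene`` gives the patient delta-Ct shift in cycles (negative
    shift = higher expression); a scalar applies to all five targets.

    Returns a DataFrame with columns sample, gene, Ct, group.
    """
    rng = np.random.default_rng([seed, zlib.crc32(b"qpcr")])
    if np.isscalar(shift_per_gene):
        shift_map = {g: float(shift_per_gene) for g in IFN_GENES}
    else:
        shift_map = {g: float(shift_per_gene.get(g, 0.0)) for g in IFN_GENES}
    base_ct = {g: rng.uniform(24.0, 30.0) for g in IFN_GENES}
    hk_ct = {g: rng.uniform(18.0, 22.0) for g in HOUSEKEEPING_GENES}

    rows: list[tuple[str, str, float, str]] = []
    samples = [(f"HC{i:02d}", "HC") for i in range(n_hc)] + [
        (f"PT{i:02d}", "patient") for i in range(n_patient)
    ]
    for sample, group in samples:
        sample_offset = rng.normal(0.0, 0.5)  # sample-wide loading differences
        for g in HOUSEKEEPING_GENES:
            rows.append((sample, g, hk_ct[g] + sample_offset + rng.normal(0, ct_noise_sd), group))
        for g in IFN_GENES:
            ct = base_ct[g] + sample_offset + rng.normal(0, ct_noise_sd)
            if group == "patient":
                ct += shift_map[g]
            rows.append((sample, g, ct, group))
    return pd.DataFrame(rows, columns=["sample", "gene", "Ct", "group"])


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down config for fast tests (600 genes, 2 modules)."""
    defaults = dict(
        n_genes=600,
        module_sizes=(60, 40),
        group_effects={
            "HC": (0.0, 0.0),
            "nSS": (1.25, -1.25),
            "pSS": (2.5, -2.5),
        },
        dispersion=0.15,
        batch_strength=0.3,
        background_de_fraction=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
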