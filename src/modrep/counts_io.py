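"""Readers/writers and validated containers for the formats the pipeline touches.

Count matrices are tab-separated (gene id in the first column, sample ids in
the header), sample sheets are CSV, gene-set collections are GMT.  All
readers validate and raise :class:`ValidationError` on malformed input
rather than silently coercing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

GROUPS = ("HC", "nSS", "pSS")
COHORTS = ("discovery", "replication")


class ValidationError(ValueError):
    """Raised when an input file or in-memory table violates an invariant."""


@dataclass(frozen=True)
class CountMatrix:
    """Nonnegative integer gene x sample table.

    Parameters
    ----------
    values : pandas.DataFrame
        Integer matrix, index = gene ids, columns = sample ids.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("count matrix contains non-numeric values")
        if np.any(~np.isfinite(arr)):
            bad = df.index[np.any(~np.isfinite(arr), axis=1)][0]
            raise ValidationError(f"non-finite count for gene {bad!r}")
        if np.any(arr < 0):
            bad = df.index[np.any(arr < 0, axis=1)][0]
            raise ValidationError(f"negative count for gene {bad!r}")
        if not np.allclose(arr, np.round(arr)):
            bad = df.index[np.any(arr != np.round(arr), axis=1)][0]
            raise ValidationError(f"non-integer count for gene {bad!r}")
        object.__setattr__(self, "values", df.astype(np.int64))

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[:, list(samples)])

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(genes)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.values.equals(other.values)


@dataclass(frozen=True)
class SampleSheet:
    """Sample annotations: sample_id, group in {HC,nSS,pSS}, cohort."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"sample_id", "group", "cohort"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown group labels: {sorted(bad_groups)}")
        bad_cohorts = set(df["cohort"]) - set(COHORTS)
        if bad_cohorts:
            raise ValidationError(f"unknown cohort labels: {sorted(bad_cohorts)}")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["group"]

    def samples_in_group(self, group: str) -> list[str]:
        t = self.table
        return list(t.loc[t["group"] == group, "sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        ids = list(sample_ids)
        t = self.table.set_index("sample_id").loc[ids].reset_index()
        return SampleSheet(t)

    def check_matches(self, counts: CountMatrix) -> None:
        """Require a one-to-one match with the count-matrix columns."""
        sheet = set(self.sample_ids)
        cols = set(counts.samples)
        if sheet != cols:
            raise ValidationError(
                f"sample sheet / count matrix mismatch: "
                f"only-in-sheet={sorted(sheet - cols)[:5]}, "
                f"only-in-counts={sorted(cols - sheet)[:5]}"
            )


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene identifiers with optional descriptions."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def add(self, name: str, members: Iterable[str], description: str = "") -> None:
        seen: dict[str, None] = {}
        n_dup = 0
        for m in members:
            if m in seen:
                n_dup += 1
            else:
                seen[m] = None
        if n_dup:
            warnings.warn(f"gene set {name!r}: {n_dup} duplicate member(s) dropped")
        if not seen:
            raise ValidationError(f"gene set {name!r} is empty")
        self.sets[name] = list(seen)
        self.descriptions[name] = description


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column = gene id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set (name, desc, members...)."""
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ValidationError(f"{path}: line {lineno}: gene set {name!r} empty")
            coll.add(name, members, desc)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a real-valued TSV matrix (e.g. VSD output)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    arr = df.to_numpy()
    if np.any(~np.isfinite(arr)):
        raise ValidationError("matrix contains non-finite values")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)
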