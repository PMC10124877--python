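"""Readers and writers for the external file formats the pipeline touches.

Expression matrices follow the UCSC-Xena convention: a TSV whose header
row lists sample identifiers, whose first column holds gene identifiers,
and whose values are log2(x+1)-transformed read counts.  A unit tag
travels with each matrix so downstream stages can refuse inputs in the
wrong unit.  Phenotype, survival and GMT gene-set files are plain TSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

VALID_UNITS = ("log2_plus1", "raw_count", "log_ratio")

#: suffix appended to a matrix filename to carry its unit tag
_UNIT_SIDECAR = ".unit"


class MatrixValidationError(ValueError):
    """Raised when a genomic matrix violates its structural invariants."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns or values."""


class UnitError(ValueError):
    """Raised when an operation receives a matrix in the wrong unit."""


@dataclass
class GenomicMatrix:
    """Dense gene-by-sample expression grid with an explicit unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    unit
        One of ``log2_plus1``, ``raw_count``, ``log_ratio``.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise MatrixValidationError(f"duplicate gene ids: {list(dup_genes)[:5]}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise MatrixValidationError(f"duplicate sample ids: {list(dup_samples)[:5]}")
        if self.unit == "raw_count":
            arr = self.values.to_numpy()
            if arr.size and ((arr < 0).any() or not np.allclose(arr, np.round(arr))):
                raise MatrixValidationError("raw_count matrix must hold non-negative integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, unit: Optional[str] = None) -> "GenomicMatrix":
        return GenomicMatrix(values=values, unit=unit if unit is not None else self.unit)


@dataclass
class SampleMetadata:
    """Per-sample phenotype record.

    ``clinical`` is an open key-value bag for columns beyond the required
    schema (e.g. extranodal-site counts, primary diagnosis).  Missing
    clinical values are kept as ``None``, never imputed.
    """

    sample_id: str
    primary_site: str
    stage: str
    clinical: dict = field(default_factory=dict)
    os_days: Optional[float] = None
    os_event: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise SchemaError("empty sample_id")
        if not self.primary_site:
            raise SchemaError(f"sample {self.sample_id}: empty primary_site")
        if self.stage not in ("early", "advanced", "normal"):
            raise SchemaError(
                f"sample {self.sample_id}: stage {self.stage!r} not in {{early, advanced, normal}}"
            )
        if self.os_days is not None and self.os_event is None:
            raise SchemaError(f"sample {self.sample_id}: os_days present without os_event")


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions, as read from a GMT file."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise SchemaError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets


def read_genomic_matrix(path: str | Path, unit: Optional[str] = None) -> GenomicMatrix:
    """Read a Xena-style gene-by-sample TSV.

    The header row holds sample ids; the first column holds gene ids.
    Row and column order of the file are preserved.  If ``unit`` is not
    given, a ``<path>.unit`` sidecar file is consulted; without either
    the unit defaults to ``log2_plus1`` (the Xena convention).
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_fields = len(header)
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != n_fields:
                raise MatrixValidationError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_fields}"
                )
            gene_ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if unit is None:
        sidecar = path.with_name(path.name + _UNIT_SIDECAR)
        unit = sidecar.read_text().strip() if sidecar.exists() else "log2_plus1"
    values = pd.DataFrame(np.asarray(rows, dtype=float), index=gene_ids, columns=sample_ids)
    if unit == "raw_count":
        values = values.round().astype(np.int64).astype(float)
    return GenomicMatrix(values=values, unit=unit)


def write_genomic_matrix(matrix: GenomicMatrix, path: str | Path) -> None:
    """Write a matrix as a Xena-style TSV plus a unit sidecar file.

    Counts are written as plain integers; floating units use 6
    significant digits so write-read round trips are stable within
    printed precision.
    """
    path = Path(path)
    if not matrix.sample_ids:
        raise MatrixValidationError("refusing to serialize a matrix with no samples")
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        arr = matrix.values.to_numpy()
        for gid, row in zip(matrix.gene_ids, arr):
            if matrix.unit == "raw_count":
                cells = [str(int(round(v))) for v in row]
            else:
                cells = [_format_float(v) for v in row]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")
    path.with_name(path.name + _UNIT_SIDECAR).write_text(matrix.unit + "\n")


def _format_float(v: float) -> str:
    if v == 0:
        return "0"
    if math.isnan(v):
        return "nan"
    return f"{v:.6g}"


_REQUIRED_PHENOTYPE_COLUMNS = ("sample_id", "primary_site", "stage")


def read_phenotypes(path: str | Path) -> list[SampleMetadata]:
    """Read a phenotype TSV into per-sample metadata records.

    Required columns: ``sample_id``, ``primary_site``, ``stage``.
    ``os_days``/``os_event`` are recognised if present; every other
    column lands in the open ``clinical`` bag with NaN mapped to None.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in _REQUIRED_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in _REQUIRED_PHENOTYPE_COLUMNS + ("os_days", "os_event")]
    records = []
    for _, row in df.iterrows():
        clinical = {c: (None if pd.isna(row[c]) else row[c]) for c in extra}
        os_days = None
        os_event = None
        if "os_days" in df.columns and not pd.isna(row["os_days"]):
            os_days = float(row["os_days"])
        if "os_event" in df.columns and not pd.isna(row["os_event"]):
            os_event = int(float(row["os_event"]))
        records.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                primary_site=row["primary_site"],
                stage=row["stage"],
                clinical=clinical,
                os_days=os_days,
                os_event=os_event,
            )
        )
    return records


def write_phenotypes(records: Sequence[SampleMetadata], path: str | Path) -> None:
    """Write metadata records back to the canonical phenotype TSV schema."""
    clinical_cols: list[str] = []
    for rec in records:
        for key in rec.clinical:
            if key not in clinical_cols:
                clinical_cols.append(key)
    rows = []
    for rec in records:
        row: dict = {
            "sample_id": rec.sample_id,
            "primary_site": rec.primary_site,
            "stage": rec.stage,
        }
        for c in clinical_cols:
            row[c] = rec.clinical.get(c)
        row["os_days"] = rec.os_days
        row["os_event"] = rec.os_event
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read a survival TSV with columns sample_id, os_days, os_event."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "os_days", "os_event"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if (df["os_days"] < 0).any():
        raise SchemaError(f"{path}: negative os_days")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, then members.

    Member lists are deduplicated preserving first occurrence.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc = parts[0], parts[1]
            members = list(dict.fromkeys(m for m in parts[2:] if m))
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_biotypes(path: str | Path) -> dict[str, str]:
    """Read a gene_id → biotype TSV (static stand-in for an annotation query)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "biotype"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate gene_id {dup!r}")
    return dict(zip(df["gene_id"], df["biotype"]))


def write_biotypes(biotypes: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame({"gene_id": list(biotypes), "biotype": list(biotypes.values())}).to_csv(
        path, sep="\t", index=False
    )
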