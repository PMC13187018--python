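"""Typed readers/writers for the tabular formats the pipeline consumes.

Every downstream module works with the validated containers defined here
(:class:`ClinicalTable`, :class:`AlterationTable`, :class:`CountMatrix`,
:class:`GeneSetCollection`, :class:`MarkerTable`), never with raw files.
Canonical dialect is tab-separated text with a mandatory header; comma is
accepted via ``dialect="comma"``. Gene symbols are compared case-sensitively
after whitespace stripping; no alias resolution is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LoadError",
    "ClinicalTable",
    "AlterationTable",
    "CountMatrix",
    "GeneSetCollection",
    "MarkerTable",
    "read_clinical",
    "read_alterations",
    "read_counts",
    "read_markers",
    "read_gmt",
    "write_gmt",
    "write_results",
]

MSI_STATUSES = frozenset({"MSS", "MSI"})
MUTATION_STATUSES = frozenset({"mut", "wt"})
RESPONSE_CATEGORIES = frozenset({"CR", "PR", "SD", "PD", "NE"})
ALTERATION_CLASSES = frozenset({"SNV", "INDEL", "CNV", "LOH"})

#: rendering precision for floating-point values in written tables
FLOAT_FORMAT = "%.6g"

_SEPARATORS = {"tab": "\t", "comma": ","}


class LoadError(ValueError):
    """Raised when an input file violates the format contract.

    The message names the offending row/column so users can fix the file.
    """


def _sep(dialect: str) -> str:
    try:
        return _SEPARATORS[dialect]
    except KeyError:
        raise LoadError(f"unknown dialect {dialect!r}; expected 'tab' or 'comma'") from None


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required column(s) {missing}")


def _check_enum(series: pd.Series, allowed: frozenset, column: str, path: Path) -> None:
    bad = series[~series.isin(allowed)]
    if len(bad):
        row = bad.index[0]
        raise LoadError(
            f"{path}: column {column!r}, row {row}: value {bad.iloc[0]!r} "
            f"not in {sorted(allowed)}"
        )


@dataclass(frozen=True)
class ClinicalTable:
    """One row per enrolled patient: MSI/RAS/BRAF status, censored PFS, best response.

    ``data`` keeps any extra input columns as opaque annotations; the required
    columns are validated on construction.
    """

    data: pd.DataFrame

    REQUIRED = (
        "patient_id",
        "msi_status",
        "ras_status",
        "braf_status",
        "pfs_months",
        "pfs_event",
        "best_response",
    )

    def __post_init__(self) -> None:
        df = self.data
        dup = df["patient_id"][df["patient_id"].duplicated()]
        if len(dup):
            raise LoadError(f"duplicate patient_id {dup.iloc[0]!r}")
        pfs = df["pfs_months"]
        if not np.all(np.isfinite(pfs)) or (pfs < 0).any():
            bad = df.index[~np.isfinite(pfs) | (pfs < 0)][0]
            raise LoadError(f"row {bad}: pfs_months must be finite and non-negative")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data["patient_id"])

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClinicalTable):
            return NotImplemented
        a = self.data.sort_values("patient_id").reset_index(drop=True)
        b = other.data.sort_values("patient_id").reset_index(drop=True)
        return a[list(self.REQUIRED)].equals(b[list(self.REQUIRED)])

    def subset(self, patient_ids: Iterable[str]) -> "ClinicalTable":
        wanted = set(patient_ids)
        return ClinicalTable(
            self.data[self.data["patient_id"].isin(wanted)].reset_index(drop=True)
        )


@dataclass(frozen=True)
class AlterationTable:
    """Sparse patient x gene genomic-alteration records plus per-patient TMB.

    Duplicate (patient, gene, class) records are collapsed on load; TMB is
    mutations per megabase and must be present for every patient that has
    alteration rows.
    """

    records: pd.DataFrame  # columns: patient_id, gene, alteration_class
    tmb: pd.Series  # index patient_id, values mutations/Mb

    def __post_init__(self) -> None:
        rec = self.records.drop_duplicates(ignore_index=True)
        object.__setattr__(self, "records", rec)
        missing = set(rec["patient_id"]) - set(self.tmb.index)
        if missing:
            raise LoadError(f"TMB missing for patient(s) {sorted(missing)[:3]}")
        if (self.tmb < 0).any():
            raise LoadError("TMB values must be non-negative")

    def altered_genes(self, patient_ids: Iterable[str]) -> set[str]:
        """Genes with >= 1 alteration record (any class) in the given patients."""
        wanted = set(patient_ids)
        mask = self.records["patient_id"].isin(wanted)
        return set(self.records.loc[mask, "gene"])

    def patients_with_any(self, genes: Iterable[str]) -> set[str]:
        """Patients carrying >= 1 alteration in >= 1 of the given genes."""
        wanted = set(genes)
        mask = self.records["gene"].isin(wanted)
        return set(self.records.loc[mask, "patient_id"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlterationTable):
            return NotImplemented
        key = ["patient_id", "gene", "alteration_class"]
        a = self.records.sort_values(key).reset_index(drop=True)
        b = other.records.sort_values(key).reset_index(drop=True)
        return a.equals(b) and self.tmb.sort_index().equals(other.tmb.sort_index())


@dataclass(frozen=True)
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            raise LoadError("duplicate gene ids in count matrix")
        if df.columns.has_duplicates:
            raise LoadError("duplicate sample ids in count matrix")
        if (df.to_numpy() < 0).any():
            raise LoadError("negative entries in count matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.sort_index().sort_index(axis=1).equals(
            other.counts.sort_index().sort_index(axis=1)
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise LoadError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class MarkerTable:
    """Signed subtype marker genes: one row per (gene, class) with direction up/down."""

    data: pd.DataFrame  # columns: gene, class, direction

    def __post_init__(self) -> None:
        df = self.data
        dup = df.duplicated(subset=["gene", "class"])
        if dup.any():
            g = df.loc[dup, "gene"].iloc[0]
            raise LoadError(f"duplicate (gene, class) row for gene {g!r}")
        bad = ~df["direction"].isin({"up", "down"})
        if bad.any():
            raise LoadError(
                f"direction {df.loc[bad, 'direction'].iloc[0]!r} not in {{'up', 'down'}}"
            )

    @property
    def classes(self) -> list[str]:
        return sorted(self.data["class"].unique())


# ---------------------------------------------------------------------------
# readers


def read_clinical(path: str | Path, dialect: str = "tab") -> ClinicalTable:
    """Read a clinical table; see :class:`ClinicalTable` for the contract.

    Missing ``best_response`` entries are encoded as NE (no assessment).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"patient_id": str})
    _require_columns(df, ClinicalTable.REQUIRED, path)
    df = df.copy()
    df["patient_id"] = df["patient_id"].str.strip()
    df["best_response"] = df["best_response"].fillna("NE")
    for col, allowed in (
        ("msi_status", MSI_STATUSES),
        ("ras_status", MUTATION_STATUSES),
        ("braf_status", MUTATION_STATUSES),
        ("best_response", RESPONSE_CATEGORIES),
    ):
        _check_enum(df[col].astype(str).str.strip(), allowed, col, path)
        df[col] = df[col].astype(str).str.strip()
    try:
        df["pfs_months"] = pd.to_numeric(df["pfs_months"], errors="raise")
    except (ValueError, TypeError):
        bad = pd.to_numeric(df["pfs_months"], errors="coerce")
        row = df.index[bad.isna()][0]
        raise LoadError(f"{path}: column 'pfs_months', row {row}: not a number") from None
    if df["pfs_months"].isna().any():
        row = df.index[df["pfs_months"].isna()][0]
        raise LoadError(f"{path}: column 'pfs_months', row {row}: missing value")
    df["pfs_event"] = df["pfs_event"].map(
        {True: True, False: False, "True": True, "False": False, 1: True, 0: False,
         "1": True, "0": False, "true": True, "false": False}
    )
    if df["pfs_event"].isna().any():
        row = df.index[df["pfs_event"].isna()][0]
        raise LoadError(f"{path}: column 'pfs_event', row {row}: not a boolean")
    df["pfs_event"] = df["pfs_event"].astype(bool)
    return ClinicalTable(df.reset_index(drop=True))


def read_alterations(
    path: str | Path, tmb_path: str | Path, dialect: str = "tab"
) -> AlterationTable:
    """Read alteration records and the per-patient TMB side table."""
    path, tmb_path = Path(path), Path(tmb_path)
    rec = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    _require_columns(rec, ("patient_id", "gene", "alteration_class"), path)
    rec = rec[["patient_id", "gene", "alteration_class"]].copy()
    for col in rec.columns:
        rec[col] = rec[col].str.strip()
    _check_enum(rec["alteration_class"], ALTERATION_CLASSES, "alteration_class", path)
    tmb_df = pd.read_csv(tmb_path, sep=_sep(dialect), dtype={"patient_id": str})
    _require_columns(tmb_df, ("patient_id", "tmb"), tmb_path)
    tmb_df["patient_id"] = tmb_df["patient_id"].str.strip()
    if tmb_df["patient_id"].duplicated().any():
        raise LoadError(f"{tmb_path}: duplicate patient_id in TMB table")
    tmb = pd.to_numeric(tmb_df.set_index("patient_id")["tmb"], errors="raise")
    return AlterationTable(rec, tmb)


def read_counts(path: str | Path, dialect: str = "tab") -> CountMatrix:
    """Read a gene x sample raw count matrix (first column = gene id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise LoadError(f"{path}: non-numeric entries in count matrix")
    if not np.allclose(arr, np.round(arr)):
        raise LoadError(f"{path}: counts must be integers")
    df = df.astype(np.int64)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    return CountMatrix(df)


def read_markers(path: str | Path, dialect: str = "tab") -> MarkerTable:
    """Read a subtype marker table with columns gene, class, direction."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    _require_columns(df, ("gene", "class", "direction"), path)
    df = df[["gene", "class", "direction"]].copy()
    for col in df.columns:
        df[col] = df[col].str.strip()
    return MarkerTable(df.reset_index(drop=True))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT: name TAB description TAB gene1 TAB gene2 ...

    Duplicate genes within a line are collapsed; an empty file yields an
    empty collection.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            name, desc, *genes = fields
            name = name.strip()
            if name in sets:
                raise LoadError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = frozenset(g.strip() for g in genes if g.strip())
            if not genes:
                raise LoadError(f"{path}: line {lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "")
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


# ---------------------------------------------------------------------------
# writers


def _write_frame(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    _write_frame(table.data, Path(path))


def write_alterations(table: AlterationTable, path: str | Path, tmb_path: str | Path) -> None:
    key = ["patient_id", "gene", "alteration_class"]
    _write_frame(table.records.sort_values(key), Path(path))
    tmb = table.tmb.sort_index().rename("tmb").rename_axis("patient_id").reset_index()
    _write_frame(tmb, Path(tmb_path))


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    _write_frame(matrix.counts.rename_axis("gene"), Path(path), index=True)


def write_results(result: Any, outdir: str | Path, prefix: str = "result") -> dict[str, str]:
    """Write a pipeline product to ``outdir``; return a manifest of files.

    Dispatch is duck-typed: anything exposing ``to_frames()`` (a mapping of
    table name -> DataFrame) is written as one TSV per frame; plain mappings
    of scalars become a single JSON file. File names are deterministic and
    re-running with identical input produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    if hasattr(result, "to_frames"):
        frames: Mapping[str, pd.DataFrame] = result.to_frames()
        for name, frame in sorted(frames.items()):
            fname = f"{prefix}_{name}.tsv"
            _write_frame(frame, outdir / fname)
            manifest[name] = fname
    elif isinstance(result, pd.DataFrame):
        fname = f"{prefix}.tsv"
        _write_frame(result, outdir / fname)
        manifest[prefix] = fname
    elif isinstance(result, Mapping):
        fname = f"{prefix}.json"
        with open(outdir / fname, "w") as fh:
            json.dump(result, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        manifest[prefix] = fname
    else:
        raise TypeError(f"cannot serialise result of type {type(result).__name__}")
    return manifest
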