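"""Readers and writers for the tab-delimited AP-MS table dialects.

Two input dialects are supported:

* a MaxQuant ``proteinGroups.txt``-style export carrying per-channel
  label-free quantification (LFQ) intensities, unique-peptide counts and
  the three standard QC flag columns (``Reverse``, ``Potential
  contaminant``, ``Only identified by site``, flagged rows marked ``+``);
* a Proteome Discoverer-style export carrying per-condition peptide
  spectrum match (PSM) counts and a peptide count.

All column-name mapping lives in the dialect objects so other exports can
be read by supplying a different mapping (e.g. from the pipeline YAML
config).  Readers never reorder rows and reject — rather than silently
drop — rows with unparseable numeric fields.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
import typing
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, DataError

__all__ = [
    "ProteinGroup",
    "ProteinGroupTable",
    "PsmRow",
    "PsmTable",
    "ProteinGroupDialect",
    "PsmDialect",
    "read_protein_groups",
    "write_protein_groups",
    "read_psm_table",
    "write_psm_table",
    "write_results",
    "read_results",
]


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinGroup:
    """One protein group: the leading accession plus per-channel LFQ intensities.

    ``lfq`` maps channel label (e.g. ``anti_bait``, ``igg``, ``beads``) to a
    finite, non-negative intensity in arbitrary instrument units.
    """

    protein_id: str
    gene_symbol: str
    unique_peptides: int
    lfq: dict[str, float]
    flag_reverse: bool = False
    flag_contaminant: bool = False
    flag_site_only: bool = False
    description: str = ""

    def validate(self) -> None:
        if not self.protein_id:
            raise DataError("protein_id must be non-empty")
        if self.unique_peptides < 0:
            raise DataError(f"{self.protein_id}: negative unique_peptides")
        for channel, value in self.lfq.items():
            if not math.isfinite(value) or value < 0:
                raise DataError(
                    f"{self.protein_id}: intensity for channel {channel!r} "
                    f"must be finite and >= 0, got {value!r}"
                )


@dataclass(frozen=True)
class ProteinGroupTable:
    """An ordered protein-group table over a declared channel set."""

    channels: tuple[str, ...]
    rows: tuple[ProteinGroup, ...]
    provenance: str = ""

    def validate(self) -> None:
        seen: set[str] = set()
        declared = set(self.channels)
        for row in self.rows:
            row.validate()
            if row.protein_id in seen:
                raise DataError(f"duplicate protein_id {row.protein_id!r}")
            seen.add(row.protein_id)
            if set(row.lfq) != declared:
                raise DataError(
                    f"{row.protein_id}: channels {sorted(row.lfq)} do not "
                    f"match the declared set {sorted(declared)}"
                )

    def ids(self) -> list[str]:
        return [r.protein_id for r in self.rows]

    def get(self, protein_id: str) -> ProteinGroup:
        for row in self.rows:
            if row.protein_id == protein_id:
                return row
        raise KeyError(protein_id)

    def replace_rows(self, rows: Sequence[ProteinGroup]) -> "ProteinGroupTable":
        return dataclasses.replace(self, rows=tuple(rows))


@dataclass(frozen=True)
class PsmRow:
    """Per-protein spectral counts across pull-down conditions."""

    protein_id: str
    gene_symbol: str
    psm: dict[str, int]
    peptides: int

    def validate(self) -> None:
        if not self.protein_id:
            raise DataError("protein_id must be non-empty")
        for condition, count in self.psm.items():
            if count < 0:
                raise DataError(
                    f"{self.protein_id}: PSM count for {condition!r} is negative"
                )
        if self.peptides < 0:
            raise DataError(f"{self.protein_id}: negative peptide count")


@dataclass(frozen=True)
class PsmTable:
    """Spectral-count table over ordered conditions, with a designated bait row."""

    conditions: tuple[str, ...]
    rows: tuple[PsmRow, ...]
    bait_id: str

    def validate(self, require_bait: bool = True) -> None:
        seen: set[str] = set()
        declared = set(self.conditions)
        for row in self.rows:
            row.validate()
            if row.protein_id in seen:
                raise DataError(f"duplicate protein_id {row.protein_id!r}")
            seen.add(row.protein_id)
            if set(row.psm) != declared:
                raise DataError(
                    f"{row.protein_id}: conditions {sorted(row.psm)} do not "
                    f"match the declared set {sorted(declared)}"
                )
        if require_bait and self.bait_id not in seen:
            raise DataError(f"bait not found: {self.bait_id!r}")

    def get(self, protein_id: str) -> PsmRow:
        for row in self.rows:
            if row.protein_id == protein_id:
                return row
        raise KeyError(protein_id)

    def replace_rows(self, rows: Sequence[PsmRow]) -> "PsmTable":
        return dataclasses.replace(self, rows=tuple(rows))


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------

@dataclass
class ProteinGroupDialect:
    """Column mapping for a protein-group export.

    Defaults follow MaxQuant ``proteinGroups.txt`` conventions: multi-accession
    cells are semicolon-separated (the leading "majority" accession is used as
    the identity), QC flags are encoded as ``+`` / empty, intensities may use
    scientific notation.
    """

    protein_id: str = "Majority protein IDs"
    gene_symbol: str | None = "Gene names"
    description: str | None = "Protein names"
    unique_peptides: str = "Razor + unique peptides"
    #: channel label -> LFQ intensity column header
    lfq_channels: dict[str, str] = field(default_factory=lambda: {
        "anti_bait": "LFQ intensity RyR2",
        "igg": "LFQ intensity IgG",
        "beads": "LFQ intensity Beads",
    })
    flag_reverse: str | None = "Reverse"
    flag_contaminant: str | None = "Potential contaminant"
    flag_site_only: str | None = "Only identified by site"
    flag_true: str = "+"
    id_separator: str = ";"

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ProteinGroupDialect":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown protein-group dialect keys: {sorted(unknown)}"
            )
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProteinGroupDialect":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PsmDialect:
    """Column mapping for a PSM-count export (Proteome Discoverer style)."""

    protein_id: str = "Accession"
    gene_symbol: str | None = "Gene Symbol"
    peptides: str = "# Peptides"
    #: condition label -> PSM column header
    psm_conditions: dict[str, str] = field(default_factory=lambda: {
        "WT": "# PSMs WT",
        "S2814A": "# PSMs S2814A",
        "S2814D": "# PSMs S2814D",
    })
    id_separator: str = ";"

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PsmDialect":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown PSM dialect keys: {sorted(unknown)}")
        return cls(**dict(data))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _load_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    # everything as string; numeric coercion is explicit so bad cells can be
    # reported with a row identifier instead of becoming NaN
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, columns: Mapping[str, str], path: Path) -> None:
    for role, header in columns.items():
        if header not in df.columns:
            raise ConfigurationError(
                f"{path}: required column {header!r} (mapped to {role}) is missing"
            )


def _first_id(cell: str, sep: str) -> str:
    return cell.split(sep)[0].strip()


def _parse_float(cell: str, *, row_id: str, column: str) -> float:
    try:
        value = float(cell) if cell.strip() else 0.0
    except ValueError:
        raise DataError(f"row {row_id!r}: non-numeric value {cell!r} in {column!r}")
    if not math.isfinite(value) or value < 0:
        raise DataError(f"row {row_id!r}: invalid intensity {cell!r} in {column!r}")
    return value


def _parse_int(cell: str, *, row_id: str, column: str) -> int:
    text = cell.strip()
    if not text:
        return 0
    try:
        value = float(text)
    except ValueError:
        raise DataError(f"row {row_id!r}: non-numeric value {cell!r} in {column!r}")
    if not value.is_integer():
        raise DataError(f"row {row_id!r}: non-integer count {cell!r} in {column!r}")
    if value < 0:
        raise DataError(f"row {row_id!r}: negative count {cell!r} in {column!r}")
    return int(value)


def read_protein_groups(
    path: str | Path,
    dialect: ProteinGroupDialect | None = None,
) -> ProteinGroupTable:
    """Read a protein-group export into a :class:`ProteinGroupTable`.

    Raises :class:`ConfigurationError` when a mapped column is missing and
    :class:`DataError` for duplicate accessions or unparseable numbers.
    """
    dialect = dialect or ProteinGroupDialect()
    path = Path(path)
    df = _load_tsv(path)

    required = {"protein_id": dialect.protein_id,
                "unique_peptides": dialect.unique_peptides}
    for channel, header in dialect.lfq_channels.items():
        required[f"lfq[{channel}]"] = header
    _require_columns(df, required, path)

    rows: list[ProteinGroup] = []
    for _, rec in df.iterrows():
        protein_id = _first_id(str(rec[dialect.protein_id]), dialect.id_separator)
        gene = ""
        if dialect.gene_symbol and dialect.gene_symbol in df.columns:
            gene = _first_id(str(rec[dialect.gene_symbol]), dialect.id_separator)
        desc = ""
        if dialect.description and dialect.description in df.columns:
            desc = str(rec[dialect.description]).strip()

        lfq = {
            channel: _parse_float(str(rec[header]), row_id=protein_id, column=header)
            for channel, header in dialect.lfq_channels.items()
        }

        def _flag(header: str | None) -> bool:
            if header is None or header not in df.columns:
                return False
            return str(rec[header]).strip() == dialect.flag_true

        rows.append(ProteinGroup(
            protein_id=protein_id,
            gene_symbol=gene,
            unique_peptides=_parse_int(
                str(rec[dialect.unique_peptides]),
                row_id=protein_id, column=dialect.unique_peptides),
            lfq=lfq,
            flag_reverse=_flag(dialect.flag_reverse),
            flag_contaminant=_flag(dialect.flag_contaminant),
            flag_site_only=_flag(dialect.flag_site_only),
            description=desc,
        ))

    table = ProteinGroupTable(
        channels=tuple(dialect.lfq_channels),
        rows=tuple(rows),
        provenance=str(path),
    )
    table.validate()
    return table


def read_psm_table(
    path: str | Path,
    dialect: PsmDialect | None = None,
    bait_id: str = "",
) -> PsmTable:
    """Read a PSM-count export into a :class:`PsmTable`.

    ``bait_id`` must name a row in the file (it anchors the normalization
    downstream); its absence is a :class:`DataError`.
    """
    dialect = dialect or PsmDialect()
    path = Path(path)
    df = _load_tsv(path)

    required = {"protein_id": dialect.protein_id, "peptides": dialect.peptides}
    for condition, header in dialect.psm_conditions.items():
        required[f"psm[{condition}]"] = header
    _require_columns(df, required, path)

    rows: list[PsmRow] = []
    for _, rec in df.iterrows():
        protein_id = _first_id(str(rec[dialect.protein_id]), dialect.id_separator)
        gene = ""
        if dialect.gene_symbol and dialect.gene_symbol in df.columns:
            gene = _first_id(str(rec[dialect.gene_symbol]), dialect.id_separator)
        psm = {
            condition: _parse_int(str(rec[header]), row_id=protein_id, column=header)
            for condition, header in dialect.psm_conditions.items()
        }
        rows.append(PsmRow(
            protein_id=protein_id,
            gene_symbol=gene,
            psm=psm,
            peptides=_parse_int(str(rec[dialect.peptides]),
                                row_id=protein_id, column=dialect.peptides),
        ))

    table = PsmTable(
        conditions=tuple(dialect.psm_conditions),
        rows=tuple(rows),
        bait_id=bait_id,
    )
    table.validate(require_bait=True)
    return table


# ---------------------------------------------------------------------------
# writing the input dialects (round-trip support; used by the simulator)
# ---------------------------------------------------------------------------

def write_protein_groups(
    table: ProteinGroupTable,
    path: str | Path,
    dialect: ProteinGroupDialect | None = None,
) -> None:
    """Write a table back out in the protein-group dialect (inverse of read)."""
    dialect = dialect or ProteinGroupDialect()
    missing = set(table.channels) - set(dialect.lfq_channels)
    if missing:
        raise ConfigurationError(
            f"dialect lacks LFQ columns for channels: {sorted(missing)}"
        )
    data: dict[str, list[Any]] = {dialect.protein_id: [r.protein_id for r in table.rows]}
    if dialect.gene_symbol:
        data[dialect.gene_symbol] = [r.gene_symbol for r in table.rows]
    if dialect.description:
        data[dialect.description] = [r.description for r in table.rows]
    data[dialect.unique_peptides] = [r.unique_peptides for r in table.rows]
    for channel in table.channels:
        header = dialect.lfq_channels[channel]
        data[header] = [repr(r.lfq[channel]) for r in table.rows]
    for attr, header in (("flag_reverse", dialect.flag_reverse),
                         ("flag_contaminant", dialect.flag_contaminant),
                         ("flag_site_only", dialect.flag_site_only)):
        if header:
            data[header] = [dialect.flag_true if getattr(r, attr) else ""
                            for r in table.rows]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_psm_table(
    table: PsmTable,
    path: str | Path,
    dialect: PsmDialect | None = None,
) -> None:
    dialect = dialect or PsmDialect()
    missing = set(table.conditions) - set(dialect.psm_conditions)
    if missing:
        raise ConfigurationError(
            f"dialect lacks PSM columns for conditions: {sorted(missing)}"
        )
    data: dict[str, list[Any]] = {dialect.protein_id: [r.protein_id for r in table.rows]}
    if dialect.gene_symbol:
        data[dialect.gene_symbol] = [r.gene_symbol for r in table.rows]
    data[dialect.peptides] = [r.peptides for r in table.rows]
    for condition in table.conditions:
        data[dialect.psm_conditions[condition]] = [r.psm[condition] for r in table.rows]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result serialization (TSV / JSON, round-trip safe)
# ---------------------------------------------------------------------------

_COMPOSITE = (dict, list, tuple)


def _encode_value(value: Any) -> Any:
    if isinstance(value, float):
        return repr(value)  # full precision
    if isinstance(value, _COMPOSITE):
        return json.dumps(value, sort_keys=False)
    if value is None:
        return ""
    return value


def write_results(
    records: Sequence[Any],
    path: str | Path,
    format: str = "tsv",
    record_cls: type | None = None,
) -> None:
    """Serialize a homogeneous list of result dataclasses to TSV or JSON.

    Float fields keep full precision; mapping/sequence fields are stored as
    JSON cells in the TSV so that ``read_results`` is an exact inverse.  An
    empty record list produces a header-only TSV (``record_cls`` supplies
    the header when no record is available) or ``[]`` for JSON.
    """
    if records is None:
        raise DataError("records must not be None")
    path = Path(path)
    dicts = [dataclasses.asdict(r) for r in records]
    if format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dicts, fh, indent=1)
            fh.write("\n")
        return
    if format != "tsv":
        raise ConfigurationError(f"unknown result format {format!r}")
    if dicts:
        columns = list(dicts[0])
    elif record_cls is not None:
        columns = [f.name for f in dataclasses.fields(record_cls)]
    else:
        columns = []
    df = pd.DataFrame(
        [{k: _encode_value(v) for k, v in d.items()} for d in dicts],
        columns=columns,
    )
    df.to_csv(path, sep="\t", index=False)


def _coerce(value: Any, annotation: Any) -> Any:
    origin = typing.get_origin(annotation)
    if origin is typing.Union:
        args = [a for a in typing.get_args(annotation) if a is not type(None)]
        if value == "" or value is None:
            return None
        return _coerce(value, args[0])
    if annotation is float:
        return float(value)
    if annotation is int:
        return int(value)
    if annotation is bool:
        return value in (True, "True", "true", 1, "1")
    if annotation is str:
        return str(value) if value is not None else ""
    if origin in (dict, list, tuple) or annotation in (dict, list, tuple):
        if isinstance(value, str):
            value = json.loads(value) if value else (origin or annotation)()
        if origin is tuple or annotation is tuple:
            return _tuplify(value)
        if origin is dict or annotation is dict:
            args = typing.get_args(annotation)
            if args and args[1] is not Any:
                return {k: _coerce(v, args[1]) for k, v in value.items()}
            return dict(value)
        args = typing.get_args(annotation)
        if args:
            return [_coerce(v, args[0]) for v in value]
        return list(value)
    return value


def _tuplify(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def read_results(path: str | Path, record_cls: type, format: str = "tsv") -> list[Any]:
    """Read back a file written by :func:`write_results` into dataclasses."""
    path = Path(path)
    hints = typing.get_type_hints(record_cls)
    fields = [f.name for f in dataclasses.fields(record_cls)]
    if format == "json":
        with open(path, "r", encoding="utf-8") as fh:
            dicts = json.load(fh)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        dicts = df.to_dict(orient="records")
    else:
        raise ConfigurationError(f"unknown result format {format!r}")
    out = []
    for d in dicts:
        kwargs = {name: _coerce(d.get(name), hints[name]) for name in fields}
        out.append(record_cls(**kwargs))
    return out
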