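"""Readers and writers for the pipeline's external formats.

Counts arrive as TSV/CSV/XLSX with the gene identifier in the first column
and one column per sample.  Sample annotations come from a four-column
sample sheet, or are inferred from structured sample names such as
``PAH01_HSS``.  Gene sets use the GMT convention (name, description, then
tab-separated members).  All result tables round-trip through TSV or JSON
with 10 significant digits.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CONDITIONS,
    CountMatrix,
    ExternalCohortMatrix,
    GeneSetCollection,
    ParseError,
    SampleAnnotation,
    ValidationError,
)

_FLOAT_FMT = "%.10g"


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("tsv", "txt"):
        return "tsv"
    if suffix == "csv":
        return "csv"
    if suffix in ("xlsx", "xls"):
        return "xlsx"
    raise ParseError(f"cannot infer format of {path} (use format=...)")


def read_counts(
    path: str | Path,
    format: str | None = None,
    sheet: int | str = 0,
    gene_column: int = 0,
) -> CountMatrix:
    """Read a gene x sample count table.

    The gene identifier column (``gene_column``, default first) supplies row
    names; every remaining column is a sample.  Values within 1e-9 of an
    integer are rounded; anything else, and any negative value or duplicated
    gene ID, raises an error naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    try:
        if fmt == "xlsx":
            df = pd.read_excel(path, sheet_name=sheet)
        else:
            df = pd.read_csv(path, sep="\t" if fmt == "tsv" else ",")
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a gene column plus at least one sample")
    gene_ids = df.iloc[:, gene_column].astype(str).tolist()
    data = df.drop(columns=[df.columns[gene_column]])
    sample_ids = [str(c) for c in data.columns]
    try:
        values = data.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for j, col in enumerate(data.columns):
            coerced = pd.to_numeric(data[col], errors="coerce")
            bad = coerced.isna() & data[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise ParseError(
                    f"{path}: non-numeric count at row {i + 2} "
                    f"(gene {gene_ids[i]!r}), column {col!r}"
                ) from exc
        raise ParseError(f"{path}: non-numeric counts") from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(
            f"{path}: missing count at gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return CountMatrix(gene_ids, sample_ids, values)


def read_sample_sheet(path: str | Path) -> SampleAnnotation:
    """Read a TSV sample sheet with columns sample_id, donor_id, group, condition."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleAnnotation(df)


def infer_annotation(sample_ids: Sequence[str]) -> SampleAnnotation:
    """Infer donor/group/condition from sample names like ``PAH01_HSS``.

    The token before the last underscore is the donor; the trailing token
    must be a flow condition; donors whose name starts with ``PAH``
    (case-insensitive) fall in the PAH group, all others in control.
    """
    rows = []
    for sid in sample_ids:
        if "_" not in sid:
            raise ParseError(
                f"cannot infer annotation from sample name {sid!r} "
                "(expected <donor>_<condition>)"
            )
        donor, cond = sid.rsplit("_", 1)
        if cond not in CONDITIONS:
            raise ParseError(
                f"sample {sid!r}: trailing token {cond!r} is not one of {CONDITIONS}"
            )
        group = "PAH" if donor.upper().startswith("PAH") else "control"
        rows.append({"sample_id": sid, "donor_id": donor,
                     "group": group, "condition": cond})
    return SampleAnnotation(pd.DataFrame(rows))


def write_sample_sheet(ann: SampleAnnotation, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT file: one gene set per line, name TAB description TAB members."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate gene set {name!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(source or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, collection.source] + members) + "\n")


def read_external_cohort(
    matrix_path: str | Path, labels_path: str | Path
) -> ExternalCohortMatrix:
    """Read a probe-level log2 matrix (probe, gene, samples...) plus a label sheet.

    The label sheet is a TSV with columns ``sample_id`` and ``label``
    (control/case).  Probes with an empty or NA gene field stay in the
    matrix flagged as unannotated; probe collapse drops them.
    """
    df = pd.read_csv(matrix_path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ParseError(f"{matrix_path}: need probe, gene and sample columns")
    probes = df.iloc[:, 0].astype(str).tolist()
    genes = df.iloc[:, 1].fillna("").astype(str).tolist()
    samples = [str(c) for c in df.columns[2:]]
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    if not {"sample_id", "label"} <= set(lab.columns):
        raise ParseError(f"{labels_path}: need columns sample_id, label")
    lab_map = dict(zip(lab["sample_id"], lab["label"]))
    missing = [s for s in samples if s not in lab_map]
    if missing:
        raise ValidationError(f"samples without labels: {missing[:10]}")
    labels = [lab_map[s] for s in samples]
    return ExternalCohortMatrix(probes, genes, samples, values, labels)


def write_table(obj, path: str | Path, format: str = "tsv") -> None:
    """Write a result table (anything with ``to_frame`` or a DataFrame).

    Columns keep a deterministic order; floats carry 10 significant digits,
    so a read-back agrees with the original within 1e-9 relative error.
    """
    df = obj.to_frame() if hasattr(obj, "to_frame") else obj
    if not isinstance(df, pd.DataFrame):
        raise ValidationError(f"cannot serialize object of type {type(obj).__name__}")
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)
    elif format == "json":
        out = df.reset_index()
        records = []
        for rec in out.to_dict(orient="records"):
            clean = {}
            for k, v in rec.items():
                if isinstance(v, float):
                    clean[k] = None if math.isnan(v) else float(_FLOAT_FMT % v)
                elif isinstance(v, (np.integer,)):
                    clean[k] = int(v)
                else:
                    clean[k] = v
            records.append(clean)
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise ValidationError(f"unknown table format {format!r}")


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t")
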