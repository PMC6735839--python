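"""Readers and writers for the plain-text interchange formats.

TSV is the canonical format for every table; count matrices can also be
read from GCT 1.2 (the format GTEx distributes). All files are UTF-8
with "." as the decimal point.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    CountMatrix,
    DrugRecord,
    EssentialityTable,
    GeneAnnotation,
    REReportTable,
    SampleMeta,
    ValidationError,
    VariabilityTable,
)

TARGET_DELIMITER = ";"


class FormatError(ValidationError):
    """Raised when a file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# count matrices


def read_counts(path, format: str = "tsv") -> CountMatrix:
    """Read a genes x samples raw-count matrix from TSV or GCT 1.2.

    TSV: header row of sample ids, first column of gene ids. GCT 1.2:
    "#1.2" version line, "<n_genes>\\t<n_samples>" dimension line, then a
    header with Name/Description columns followed by sample ids.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    elif format == "gct":
        df = _read_gct(path)
    else:
        raise ValueError(f"unknown counts format: {format!r}")
    return _validate_count_frame(df)


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise FormatError(f"expected GCT version line '#1.2', got {version!r}")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise FormatError("malformed GCT dimension line")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError as exc:
            raise FormatError("malformed GCT dimension line") from exc
        body = pd.read_csv(fh, sep="\t")
    if body.columns[0] != "Name" or body.columns[1] != "Description":
        raise FormatError("GCT header must start with Name and Description")
    if body.shape != (n_genes, n_samples + 2):
        raise FormatError(
            f"GCT dimensions {n_genes}x{n_samples} do not match the body "
            f"({body.shape[0]} rows, {body.shape[1] - 2} samples)"
        )
    return body.drop(columns="Description").set_index("Name").rename_axis(None)


def _validate_count_frame(df: pd.DataFrame) -> CountMatrix:
    for col in df.columns:
        series = df[col]
        if series.isna().any():
            raise FormatError(f"missing value in sample column {col!r}")
        values = pd.to_numeric(series, errors="coerce")
        if values.isna().any():
            bad = series[values.isna()].iloc[0]
            raise FormatError(f"non-numeric count {bad!r} in sample {col!r}")
        if (values < 0).any():
            raise FormatError(f"negative count in sample {col!r}")
        if not np.all(values == np.floor(values)):
            raise FormatError(f"non-integer count in sample {col!r}")
    return CountMatrix(df.astype(np.int64).rename_axis(None))


def write_counts(matrix: CountMatrix, path) -> None:
    matrix.counts.rename_axis("gene_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# generic TSV tables


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing required column(s) {missing}")
    return df


def read_sample_meta(path) -> SampleMeta:
    df = _read_tsv(path, ("sample_id", "tissue", "sex", "death_cause"))
    return SampleMeta(df.set_index("sample_id"))


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_gene_annotation(path) -> GeneAnnotation:
    df = _read_tsv(path, ("gene_id", "chromosome", "is_protein_coding"))
    df["is_protein_coding"] = df["is_protein_coding"].str.lower().map(
        {"true": True, "false": False, "1": True, "0": False}
    )
    if df["is_protein_coding"].isna().any():
        raise FormatError("is_protein_coding must be true/false")
    return GeneAnnotation(df.set_index("gene_id"))


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_drugs(path) -> list[DrugRecord]:
    df = _read_tsv(path, ("drug_id", "name", "status", "targets", "atc"))
    records = []
    for row in df.itertuples(index=False):
        targets = frozenset(t for t in row.targets.split(TARGET_DELIMITER) if t)
        if not targets:
            raise FormatError(f"drug {row.drug_id}: empty target list")
        atc = frozenset(a for a in row.atc.split(TARGET_DELIMITER) if a)
        records.append(
            DrugRecord(
                drug_id=row.drug_id,
                name=row.name,
                status=row.status,
                target_gene_ids=targets,
                atc_level1=atc,
            )
        )
    return records


def write_drugs(drugs: list[DrugRecord], path) -> None:
    rows = [
        {
            "drug_id": d.drug_id,
            "name": d.name,
            "status": d.status,
            "targets": TARGET_DELIMITER.join(sorted(d.target_gene_ids)),
            "atc": TARGET_DELIMITER.join(sorted(d.atc_level1)),
        }
        for d in drugs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reports(path, min_reports: int = 10) -> REReportTable:
    df = _read_tsv(path, ("drug_id", "disease", "n_ineffective", "n_most_common_complaint"))
    for col in ("n_ineffective", "n_most_common_complaint"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any() or not np.all(values == np.floor(values)):
            raise FormatError(f"column {col} must hold integers")
        df[col] = values.astype(np.int64)
    return REReportTable(df, min_reports=min_reports)


def write_reports(reports: REReportTable, path) -> None:
    reports.table[list(REReportTable.COLUMNS)].to_csv(path, sep="\t", index=False)


def read_essentiality(path) -> EssentialityTable:
    df = _read_tsv(path, ("gene_id", "cell_line", "score"))
    score = pd.to_numeric(df["score"], errors="coerce")
    if score.isna().any():
        raise FormatError("essentiality scores must be numeric")
    df["score"] = score
    return EssentialityTable(df)


def write_essentiality(ess: EssentialityTable, path) -> None:
    ess.table.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# variability scores


def write_scores(table: VariabilityTable, path) -> None:
    """Write a variability table as TSV, sorted (gene, tissue, measure).

    Scores round-trip at 12 significant digits; an empty table is an
    error rather than an empty file.
    """
    if not len(table):
        raise ValidationError("refusing to write an empty variability table")
    out = table.table.sort_values(["gene_id", "tissue", "measure"])
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scores(path) -> VariabilityTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "tissue": str, "measure": str})
    return VariabilityTable(df)
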