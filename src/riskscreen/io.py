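"""Readers, writers and schema validation for all interchange files.

Plain-text interchange throughout: TSV for tables, BED for intervals,
MatrixMarket for the sparse cell x gene matrix. Validation reports every
violation it finds (with row numbers), not just the first.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .library import SgRNALibrary
from .screens import ScreenCountMatrix
from .singlecell import SingleCellDataset

# ---------------------------------------------------------------- writers


def write_library(library: SgRNALibrary, out_dir: str | Path) -> None:
    """Library annotation TSV (one row per sgRNA, gene fields joined in) and
    a gene annotation TSV with TSS coordinates."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_cols = library.genes.set_index("gene_id")
    lib = library.sgrnas.copy()
    lib["category"] = lib["target_id"].map(gene_cols["category"]).fillna("")
    driver_of = gene_cols["known_driver"].to_dict()
    lib["driver_flag"] = [bool(driver_of.get(t, False)) for t in lib["target_id"]]
    lib["partner_id"] = lib["target_id"].map(gene_cols["partner_id"]).fillna("")
    lib.to_csv(out / "library.tsv", sep="\t", index=False)
    library.genes.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)


def read_library(out_dir: str | Path) -> SgRNALibrary:
    out = Path(out_dir)
    lib = pd.read_csv(out / "library.tsv", sep="\t", keep_default_na=False)
    genes = pd.read_csv(out / "gene_annotation.tsv", sep="\t", keep_default_na=False)
    sgrnas = lib[["sgrna_id", "target_id", "target_type"]].copy()
    return SgRNALibrary(sgrnas=sgrnas, genes=genes)


def write_counts(counts: ScreenCountMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts.counts.to_csv(out / "counts.tsv", sep="\t")
    counts.samples.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)


def read_counts(out_dir: str | Path) -> ScreenCountMatrix:
    out = Path(out_dir)
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="sgrna_id")
    samples = pd.read_csv(out / "sample_sheet.tsv", sep="\t", keep_default_na=False)
    return ScreenCountMatrix(counts=counts, samples=samples)


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: list[str] | None = None) -> None:
    """BED3 plus optional extra columns (BED4 for CCVs, BED6-style for enhancers)."""
    cols = ["contig", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    cols = ["contig", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, names=cols, keep_default_na=False)
    return df


def write_enhancers_bed(enhancers: pd.DataFrame, path: str | Path) -> None:
    """BED6: name = enhancer id, score = contained-CCV count, strand '.'."""
    out = enhancers.copy()
    out["name"] = out["enhancer_id"]
    out["score"] = out["n_ccvs"]
    out["strand"] = "."
    write_bed(out, path, extra_cols=["name", "score", "strand"])


def write_single_cell(dataset: SingleCellDataset, out_dir: str | Path) -> None:
    """MTX triplet + index files + guide assignment and per-cell QC TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    buf = _io.BytesIO()
    spio.mmwrite(buf, sparse.coo_matrix(dataset.matrix))
    (out / "matrix.mtx").write_bytes(buf.getvalue())
    pd.Series(dataset.cell_ids, name="cell_id").to_csv(out / "cells.tsv", sep="\t", index=False)
    dataset.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    dataset.assignments.to_csv(out / "sgrna_assignments.tsv", sep="\t", index=False)
    dataset.cell_qc.to_csv(out / "cell_qc.tsv", sep="\t", index=False)
    dataset.guides.to_csv(out / "guides.tsv", sep="\t", index=False)


def read_single_cell(out_dir: str | Path) -> SingleCellDataset:
    out = Path(out_dir)
    matrix = sparse.csr_matrix(spio.mmread(out / "matrix.mtx"))
    cells = pd.read_csv(out / "cells.tsv", sep="\t")["cell_id"].tolist()
    genes = pd.read_csv(out / "genes.tsv", sep="\t", keep_default_na=False)
    assignments = pd.read_csv(out / "sgrna_assignments.tsv", sep="\t", keep_default_na=False)
    cell_qc = pd.read_csv(out / "cell_qc.tsv", sep="\t", keep_default_na=False)
    guides = pd.read_csv(out / "guides.tsv", sep="\t", keep_default_na=False)
    return SingleCellDataset(
        matrix=matrix, cell_ids=cells, genes=genes, cell_qc=cell_qc,
        assignments=assignments, guides=guides,
    )


# ------------------------------------------------------------- validation


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def _require_columns(df: pd.DataFrame, cols: list[str], violations: list[str]) -> bool:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        violations.append(f"missing required columns: {missing}")
        return False
    return True


def _validate_counts(path: Path) -> list[str]:
    v: list[str] = []
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sgrna_id":
        v.append("first column must be sgrna_id")
        return v
    mat = df.set_index("sgrna_id")
    for col in mat.columns:
        series = pd.to_numeric(mat[col], errors="coerce")
        bad = series.isna() | (series < 0) | (series % 1 != 0)
        for row in mat.index[bad]:
            v.append(f"non-negative integer required at row {row!r}, column {col!r}")
    if mat.index.duplicated().any():
        dupes = list(mat.index[mat.index.duplicated()])
        v.append(f"duplicate sgrna ids: {dupes[:5]}")
    return v


def _validate_sample_sheet(path: Path) -> list[str]:
    v: list[str] = []
    df = _read_table(path)
    _require_columns(df, ["sample_id", "cell_line", "modality", "assay", "arm", "role", "reference_id"], v)
    return v


def _validate_library(path: Path) -> list[str]:
    v: list[str] = []
    df = _read_table(path)
    if not _require_columns(df, ["sgrna_id", "target_id", "target_type"], v):
        return v
    bad = ~df["target_type"].isin(["gene", "negative_control"])
    for i in df.index[bad]:
        v.append(f"line {i + 2}: unknown target_type {df.loc[i, 'target_type']!r}")
    ctrl_with_target = (df["target_type"] == "negative_control") & (df["target_id"] != "")
    for i in df.index[ctrl_with_target]:
        v.append(f"line {i + 2}: negative control must not have a target")
    return v


def _validate_annotation(path: Path) -> list[str]:
    v: list[str] = []
    df = _read_table(path)
    _require_columns(df, ["gene_id", "category", "known_driver", "contig", "tss"], v)
    return v


def _validate_gene_result(path: Path) -> list[str]:
    v: list[str] = []
    df = _read_table(path)
    if not _require_columns(df, ["gene_id", "screen_id", "gene_lfc", "fdr"], v):
        return v
    fdr = pd.to_numeric(df["fdr"], errors="coerce")
    bad = fdr.notna() & ((fdr < 0) | (fdr > 1))
    for i in df.index[bad]:
        v.append(f"line {i + 2}: fdr outside [0, 1]")
    return v


def _validate_pair_result(path: Path) -> list[str]:
    v: list[str] = []
    df = _read_table(path)
    if not _require_columns(df, ["enhancer_id", "gene_id", "z", "p"], v):
        return v
    p = pd.to_numeric(df["p"], errors="coerce")
    bad = p.notna() & ((p <= 0) | (p > 1))
    for i in df.index[bad]:
        v.append(f"line {i + 2}: p outside (0, 1]")
    return v


def _validate_bed(path: Path, n_cols: int) -> list[str]:
    v: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < n_cols:
                v.append(f"line {lineno}: expected >= {n_cols} fields, got {len(parts)}")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                v.append(f"line {lineno}: non-integer coordinates")
                continue
            if start < 0:
                v.append(f"line {lineno}: negative start")
            if start >= end:
                v.append(f"line {lineno}: start >= end")
    return v


def _validate_mtx(path: Path) -> list[str]:
    try:
        m = spio.mmread(path)
    except Exception as exc:  # malformed header or triplets
        return [f"unreadable MatrixMarket file: {exc}"]
    if (sparse.coo_matrix(m).data < 0).any():
        return ["negative entries in count matrix"]
    return []


SCHEMAS = {
    "counts": _validate_counts,
    "sample_sheet": _validate_sample_sheet,
    "library": _validate_library,
    "annotation": _validate_annotation,
    "gene_result": _validate_gene_result,
    "pair_result": _validate_pair_result,
    "bed3": lambda p: _validate_bed(p, 3),
    "bed4": lambda p: _validate_bed(p, 4),
    "bed6": lambda p: _validate_bed(p, 6),
    "mtx": _validate_mtx,
}


def validate_tables(path: str | Path, schema: str) -> list[str]:
    """Validate one interchange file against a named schema.

    Returns the full list of violations (empty = valid). Unknown schema names
    raise, listing the registered ones.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    return SCHEMAS[schema](Path(path))
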