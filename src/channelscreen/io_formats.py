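"""Readers and writers for the delimited formats the pipeline touches.

Matrices and metadata travel as TSV/CSV (MTX triplets with ID sidecars are
also accepted for counts); gene sets use the Broad GMT dialect. Readers
validate strictly and reject rather than repair: duplicate identifiers,
negative abundances and malformed lines are errors carrying file
coordinates. Gene identifiers are opaque case-sensitive strings — no
symbol/alias resolution is attempted.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import (
    ExpressionMatrix,
    FamilyAnnotation,
    FormatError,
    GeneSetCollection,
    SampleMetadata,
    SurvivalTable,
    ValidationError,
)

logger = logging.getLogger("channelscreen")


def _sniff_sep(path: Path, sep: str | None) -> str:
    """Delimiter auto-detection limited to tab and comma."""
    if sep is not None:
        return sep
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise FormatError(
        f"{path}: cannot auto-detect delimiter (only tab and comma are "
        "recognised); pass sep= explicitly"
    )


def read_expression_table(
    path: str | Path,
    unit: str,
    orientation: str = "genes_in_rows",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited gene x sample abundance table.

    The file must have one header row and one leading ID column. With
    ``orientation="genes_in_columns"`` the table is transposed after
    reading so genes always end up as rows.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "genes_in_columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if orientation == "genes_in_columns":
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            where = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell at row {where!r}, column {col!r}"
            )
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{path}: duplicate gene ids {dup}")
    if df.columns.duplicated().any():
        dup = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValidationError(f"{path}: duplicate sample ids {dup}")
    arr = df.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
        )
    return ExpressionMatrix(df.astype(float), unit)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.values.to_csv(path, sep=sep, index_label="gene_id")


def read_expression_mtx(
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
    unit: str = "counts",
) -> ExpressionMatrix:
    """Read an MTX triplet matrix with gene/sample ID sidecar files."""
    mat = scipy.io.mmread(str(mtx_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
    samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
    if mat.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.shape}, sidecars give "
            f"{len(genes)} genes x {len(samples)} samples"
        )
    df = pd.DataFrame(np.asarray(mat, dtype=float), index=genes, columns=samples)
    return ExpressionMatrix(df, unit)


def write_expression_mtx(
    matrix: ExpressionMatrix,
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.coo_matrix(matrix.values.to_numpy()))
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(matrix.sample_ids) + "\n")


def read_sample_metadata(path: str | Path, sep: str | None = None) -> SampleMetadata:
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path: str | Path, sep: str = "\t") -> None:
    meta.table.to_csv(path, sep=sep, index_label="sample_id")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name <TAB> description <TAB> members...

    Duplicate members within a line are dropped with a warning; duplicate
    set names across lines are an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "%s:%d: gene set %r has duplicate members; deduplicated "
                    "%d -> %d", path, lineno, name, len(members), len(deduped)
                )
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = deduped
    return GeneSetCollection(sets, provenance=str(path))


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.provenance or "na", *members]) + "\n")


def read_family_table(path: str | Path, sep: str | None = None) -> FamilyAnnotation:
    """Two-column gene -> family table (header row required)."""
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene_id, family)")
    mapping = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].astype(str).values)
    return FamilyAnnotation(mapping)


def read_survival_table(path: str | Path, sep: str | None = None) -> SurvivalTable:
    """Read sample_id / time / event (+ optional expression) records.

    Rows with missing time are dropped and counted (the count is reported
    on the returned table and logged); negative times and event values
    outside {0, 1} are errors.
    """
    path = Path(path)
    sep = _sniff_sep(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    for col in ("time", "event"):
        if col not in df:
            raise FormatError(f"{path}: missing required column {col!r}")
    missing = df["time"].isna()
    dropped = int(missing.sum())
    if dropped:
        logger.warning("%s: dropped %d rows with missing time-to-death", path, dropped)
        df = df[~missing]
    return SurvivalTable(df, dropped_missing_time=dropped)


def write_survival_table(table: SurvivalTable, path: str | Path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index_label="sample_id")


def report_missing_set_genes(
    collection: GeneSetCollection, matrix: ExpressionMatrix
) -> dict[str, list[str]]:
    """Report, once per run, gene-set members absent from the matrix.

    Missing genes are treated as absent downstream (they simply never
    appear in rankings); this mirrors screening a curated list against a
    dataset that quantified only part of it.
    """
    universe = set(matrix.gene_ids)
    out: dict[str, list[str]] = {}
    for name, members in collection.sets.items():
        miss = [m for m in members if m not in universe]
        if miss:
            out[name] = miss
            logger.warning(
                "gene set %r: %d of %d members absent from dataset", name, len(miss), len(members)
            )
    return out
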