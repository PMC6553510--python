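"""Readers and writers for every external artifact the pipeline touches.

Supported formats
-----------------
counts
    matrix-market triplet (``matrix.mtx`` with ``features.tsv`` /
    ``barcodes.tsv`` sidecars, 10x-style layout; 1-based indices in the
    triplet body) or a dense TSV with gene symbols as the first column and
    barcodes as the header row.
annotation
    TSV with columns ``barcode``, ``cluster`` and optionally ``genotype``.
pairs
    two-column TSV/CSV of (ligand, receptor) gene symbols; an optional header
    row is detected when both fields spell "ligand"/"receptor" (any case).
gene sets
    standard GMT: name, description, then member symbols, tab-separated.
"""
from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    CellAnnotation,
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    LRPairTable,
    NormalizedMatrix,
    ParseError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_lr_pairs",
    "write_lr_pairs",
    "read_gene_sets",
    "write_gene_sets",
    "read_matrix_tsv",
    "write_interaction_outputs",
]

_PAIR_HEADER_VOCAB = {"ligand", "receptor", "ligand_gene", "receptor_gene"}


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | os.PathLike, dialect: str = "auto") -> CountMatrix:
    """Read a genes x cells count matrix.

    Parameters
    ----------
    path
        For ``triplet-mtx``: the ``.mtx`` file (or a directory containing
        ``matrix.mtx``); ``features.tsv`` and ``barcodes.tsv`` must sit
        alongside.  For ``dense-tsv``: a TSV whose first column holds gene
        symbols and whose header row holds barcodes.
    dialect
        ``"triplet-mtx"``, ``"dense-tsv"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if dialect == "auto":
        if path.is_dir() or path.suffix == ".mtx":
            dialect = "triplet-mtx"
        else:
            dialect = "dense-tsv"
    if dialect == "triplet-mtx":
        return _read_counts_mtx(path)
    if dialect == "dense-tsv":
        return _read_counts_dense(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_counts_mtx(path: Path) -> CountMatrix:
    if path.is_dir():
        path = path / "matrix.mtx"
    if not path.exists():
        raise ParseError("matrix file not found", path)
    feat = path.with_name("features.tsv")
    if not feat.exists():
        feat = path.with_name("genes.tsv")
    barc = path.with_name("barcodes.tsv")
    for side in (feat, barc):
        if not side.exists():
            raise ParseError(f"sidecar file missing: {side.name}", path)
    try:
        mat = scipy.io.mmread(str(path))
    except Exception as exc:  # malformed header / body
        raise ParseError(f"malformed matrix-market file: {exc}", path) from exc
    mat = sp.csr_matrix(mat)
    genes = [ln.split("\t")[0] for ln in _read_nonempty_lines(feat)]
    barcodes = [ln.split("\t")[0] for ln in _read_nonempty_lines(barc)]
    if mat.shape[0] != len(genes) or mat.shape[1] != len(barcodes):
        raise ParseError(
            f"dimension mismatch: matrix is {mat.shape[0]}x{mat.shape[1]} but "
            f"sidecars declare {len(genes)} genes and {len(barcodes)} barcodes",
            path,
        )
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ParseError("non-integer count in matrix body", path)
    return CountMatrix(genes=genes, barcodes=barcodes, counts=mat)


def _read_nonempty_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _read_counts_dense(path: Path) -> CountMatrix:
    if not path.exists():
        raise ParseError("file not found", path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ParseError("empty matrix file", path) from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError("matrix has no genes or no cells", path)
    values = df.to_numpy()
    try:
        as_float = values.astype(float)
    except (TypeError, ValueError) as exc:
        bad = _first_bad_numeric_line(df)
        raise ParseError(f"non-numeric count: {exc}", path, line=bad) from exc
    if not np.allclose(as_float, np.round(as_float)):
        bad_rows = np.where(~np.all(np.isclose(as_float, np.round(as_float)), axis=1))[0]
        raise ParseError("non-integer count", path, line=int(bad_rows[0]) + 2)
    return CountMatrix(
        genes=[str(g) for g in df.index],
        barcodes=[str(b) for b in df.columns],
        counts=sp.csr_matrix(as_float),
    )


def _first_bad_numeric_line(df: pd.DataFrame) -> int | None:
    for i, (_, row) in enumerate(df.iterrows()):
        try:
            row.astype(float)
        except (TypeError, ValueError):
            return i + 2  # 1-based, after header
    return None


def write_counts(matrix: CountMatrix, outdir: str | os.PathLike) -> Path:
    """Write counts as matrix-market triplet with features/barcodes sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), matrix.counts.tocoo(), field="integer")
    (outdir / "features.tsv").write_text("".join(g + "\n" for g in matrix.genes))
    (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in matrix.barcodes))
    return outdir / "matrix.mtx"


def write_counts_dense(matrix: CountMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        matrix.counts.toarray(), index=matrix.genes, columns=matrix.barcodes
    )
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike) -> CellAnnotation:
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError("empty annotation file", path) from exc
    cols = {c.lower(): c for c in df.columns}
    if "barcode" not in cols or "cluster" not in cols:
        raise ParseError(
            f"annotation needs 'barcode' and 'cluster' columns, got {list(df.columns)}",
            path,
        )
    rename = {cols["barcode"]: "barcode", cols["cluster"]: "cluster"}
    if "genotype" in cols:
        rename[cols["genotype"]] = "genotype"
    df = df.rename(columns=rename)
    return CellAnnotation.from_frame(df)


def write_annotation(annotation: CellAnnotation, path: str | os.PathLike) -> None:
    annotation.table.rename_axis("barcode").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# ligand-receptor pairs
# ---------------------------------------------------------------------------

def read_lr_pairs(path: str | os.PathLike) -> LRPairTable:
    """Read a two-column (ligand, receptor) list from TSV or CSV.

    Row 1 is treated as a header when both of its first two fields are in the
    known column-name vocabulary ("ligand", "receptor", any case); otherwise
    it is data.  Exact duplicate records are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path)
    lines = [
        (i + 1, ln.rstrip("\n"))
        for i, ln in enumerate(path.read_text().splitlines())
        if ln.strip()
    ]
    if not lines:
        raise ParseError("empty pair file", path)
    sep = "\t" if "\t" in lines[0][1] else ","
    rows: list[tuple[int, list[str]]] = [
        (lineno, [f.strip() for f in ln.split(sep)]) for lineno, ln in lines
    ]
    first = [f.lower() for f in rows[0][1][:2]]
    if len(first) == 2 and all(f in _PAIR_HEADER_VOCAB for f in first):
        rows = rows[1:]
        if not rows:
            raise ParseError("pair file has a header but no records", path)
    bad = [lineno for lineno, fields in rows if len(fields) < 2 or "" in fields[:2]]
    if bad:
        raise ParseError(f"rows with missing fields at lines {bad[:10]}", path)
    df = pd.DataFrame(
        [(fields[0], fields[1]) for _, fields in rows], columns=["ligand", "receptor"]
    )
    n_dup = int(df.duplicated().sum())
    if n_dup:
        logger.info("dropped %d duplicate ligand-receptor records from %s", n_dup, path)
    df = df.drop_duplicates().reset_index(drop=True)
    return LRPairTable(df, provenance=str(path))


def write_lr_pairs(pairs: LRPairTable, path: str | os.PathLike) -> None:
    pairs.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets(path: str | os.PathLike) -> GeneSetCollection:
    """Read a GMT file: per line, set name, description, then member symbols."""
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line has {len(fields)} fields, need at least 3", path, lineno
                )
            name, description, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if name in names:
                raise ParseError(f"duplicate gene set name {name!r}", path, lineno)
            names.add(name)
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "set %r lists %d duplicate members; collapsed",
                    name,
                    len(members) - len(deduped),
                )
            sets.append(GeneSet(name=name, description=description, genes=deduped))
    if not sets:
        raise ParseError("empty GMT file", path)
    return GeneSetCollection.from_sets(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# analysis outputs
# ---------------------------------------------------------------------------

def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a labeled numeric matrix written by :func:`write_interaction_outputs`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_interaction_outputs(matrix, pair_table, chord, outdir: str | os.PathLike) -> dict[str, Path]:
    """Write the cross-talk outputs: matrix TSV, pair-score TSV, chord JSON.

    Values are written at full ``repr`` precision so a read-back reproduces
    them exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if matrix is not None:
        paths["interaction_matrix"] = outdir / "interaction_matrix.tsv"
        matrix.matrix.to_csv(paths["interaction_matrix"], sep="\t", float_format="%.17g")
    if pair_table is not None:
        paths["pair_scores"] = outdir / "pair_scores.tsv"
        pair_table.records.to_csv(
            paths["pair_scores"], sep="\t", index=False, float_format="%.17g"
        )
    if chord is not None:
        paths["chord"] = outdir / "chord.json"
        with open(paths["chord"], "w") as fh:
            json.dump(
                {"links": chord.links, "totals": chord.totals.to_dict(orient="index")},
                fh,
                indent=2,
            )
    return paths


def validate_file(path: str | os.PathLike, kind: str = "auto") -> str:
    """Validate any supported input file, returning a one-line report.

    ``kind`` is one of ``counts``, ``annotation``, ``pairs``, ``gene-sets`` or
    ``auto`` (guessed from the file name).
    """
    path = Path(path)
    if kind == "auto":
        name = path.name.lower()
        if name.endswith(".mtx") or path.is_dir():
            kind = "counts"
        elif name.endswith(".gmt"):
            kind = "gene-sets"
        elif "annot" in name:
            kind = "annotation"
        elif "pair" in name:
            kind = "pairs"
        else:
            kind = "counts"
    if kind == "counts":
        m = read_counts(path)
        return f"OK counts: {m.n_genes} genes x {m.n_cells} cells, total {int(m.counts.sum())}"
    if kind == "annotation":
        a = read_annotation(path)
        return (
            f"OK annotation: {len(a.barcodes)} cells, "
            f"{len(a.clusters)} clusters, genotypes {a.genotypes}"
        )
    if kind == "pairs":
        p = read_lr_pairs(path)
        return f"OK pairs: {len(p)} unique ligand-receptor records"
    if kind == "gene-sets":
        g = read_gene_sets(path)
        return f"OK gene sets: {len(g)} sets"
    raise ValueError(f"unknown kind {kind!r}")
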