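"""Core in-memory containers for the cross-talk pipeline.

All expression containers are gene-major (genes x cells): rows are gene
symbols, columns are cell barcodes.  Counts are exact non-negative integers;
normalized values are non-negative floats that share the zero pattern of the
counts they came from.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ValidationError",
    "ParseError",
    "CountMatrix",
    "NormalizedMatrix",
    "CellAnnotation",
    "LRPairTable",
    "GeneSet",
    "GeneSetCollection",
]


class ValidationError(ValueError):
    """An in-memory object violates one of its type invariants."""


class ParseError(ValueError):
    """A file cannot be parsed into a valid object.

    Carries ``path`` and (when known) a 1-based ``line`` number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


def _check_unique(labels: Sequence[str], what: str) -> None:
    if len(set(labels)) != len(labels):
        seen, dups = set(), []
        for lab in labels:
            if lab in seen:
                dups.append(lab)
            seen.add(lab)
        raise ValidationError(f"duplicate {what}: {sorted(set(dups))[:5]}")


@dataclasses.dataclass
class CountMatrix:
    """Raw integer counts, genes x cells.

    Parameters
    ----------
    genes
        Ordered gene symbols (unique).
    barcodes
        Ordered cell identifiers (unique).
    counts
        ``scipy.sparse`` matrix of shape ``(len(genes), len(barcodes))``
        holding non-negative integral values.
    """

    genes: list[str]
    barcodes: list[str]
    counts: sp.spmatrix

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        _check_unique(self.genes, "gene symbols")
        _check_unique(self.barcodes, "barcodes")
        for g in self.genes:
            if not g:
                raise ValidationError("empty gene symbol")
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative count found")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("non-integral count found")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)
        self.counts.eliminate_zeros()

    # -- per-cell summaries -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def total_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def mito_fraction(self, prefix: str = "mt-") -> np.ndarray:
        """Per-cell fraction of counts on genes whose symbol starts with *prefix*."""
        mask = np.array([g.startswith(prefix) for g in self.genes])
        totals = self.total_per_cell().astype(float)
        if not mask.any():
            return np.zeros(self.n_cells)
        mito = np.asarray(self.counts[mask].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.where(totals > 0, totals, 1), 0.0)
        return frac

    def subset_cells(self, keep: np.ndarray | Sequence[str]) -> "CountMatrix":
        """Subset to the given barcodes (list) or boolean mask, preserving order."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {b: i for i, b in enumerate(self.barcodes)}
            missing = [b for b in keep if b not in pos]
            if missing:
                raise ValidationError(f"unknown barcodes: {missing[:5]}")
            idx = np.array([pos[b] for b in keep], dtype=int)
        return CountMatrix(
            genes=self.genes,
            barcodes=[self.barcodes[i] for i in idx],
            counts=self.counts[:, idx],
        )


@dataclasses.dataclass
class NormalizedMatrix:
    """Log-normalized expression, genes x cells, zero exactly where counts were zero."""

    genes: list[str]
    barcodes: list[str]
    values: sp.spmatrix
    scale_factor: float

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        self.values = self.values.tocsr().astype(float)
        if self.values.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError("values shape does not match labels")
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        if self.values.data.size and np.any(self.values.data < 0):
            raise ValidationError("negative normalized value")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)


@dataclasses.dataclass
class CellAnnotation:
    """Per-cell cluster and genotype labels.

    ``table`` is indexed by barcode with columns ``cluster`` and ``genotype``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        tab = self.table
        if "cluster" not in tab.columns:
            raise ValidationError("annotation needs a 'cluster' column")
        if "genotype" not in tab.columns:
            tab = tab.copy()
            tab["genotype"] = "pooled"
        if tab.index.has_duplicates:
            dup = tab.index[tab.index.duplicated()].tolist()
            raise ValidationError(f"duplicate barcodes in annotation: {dup[:5]}")
        for col in ("cluster", "genotype"):
            vals = tab[col].astype(str)
            if (vals == "").any() or tab[col].isna().any():
                raise ValidationError(f"empty {col} label in annotation")
            tab[col] = vals
        self.table = tab

    @classmethod
    def from_frame(cls, df: pd.DataFrame, barcode_col: str = "barcode") -> "CellAnnotation":
        if barcode_col in df.columns:
            df = df.set_index(barcode_col)
        return cls(df)

    @property
    def barcodes(self) -> list[str]:
        return list(self.table.index)

    @property
    def clusters(self) -> list[str]:
        return sorted(self.table["cluster"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.table["genotype"].unique())

    def subset(self, barcodes: Iterable[str]) -> "CellAnnotation":
        return CellAnnotation(self.table.loc[list(barcodes)].copy())

    def by_genotype(self, genotype: str) -> "CellAnnotation":
        mask = self.table["genotype"] == genotype
        if not mask.any():
            raise ValidationError(f"no cells with genotype {genotype!r}")
        return CellAnnotation(self.table[mask].copy())


@dataclasses.dataclass
class LRPairTable:
    """Ordered (ligand, receptor) gene pairs defining the interaction universe."""

    records: pd.DataFrame  # columns: ligand, receptor
    provenance: str = ""

    def __post_init__(self) -> None:
        rec = self.records
        if list(rec.columns[:2]) != ["ligand", "receptor"]:
            rec = rec.rename(
                columns={rec.columns[0]: "ligand", rec.columns[1]: "receptor"}
            )
        rec = rec[["ligand", "receptor"]].astype(str).reset_index(drop=True)
        if (rec == "").any().any() or rec.isna().any().any():
            raise ValidationError("empty gene symbol in pair table")
        if rec.duplicated().any():
            raise ValidationError("exact duplicate (ligand, receptor) records")
        self.records = rec

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], provenance: str = "") -> "LRPairTable":
        df = pd.DataFrame(list(pairs), columns=["ligand", "receptor"])
        df = df.drop_duplicates().reset_index(drop=True)
        return cls(df, provenance)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def genes(self) -> list[str]:
        """All distinct gene symbols in the universe, ligand-first order."""
        seen: dict[str, None] = {}
        for col in ("ligand", "receptor"):
            for g in self.records[col]:
                seen.setdefault(g, None)
        return list(seen)

    def intersect(self, detected: Iterable[str]) -> tuple["LRPairTable", int]:
        """Drop pairs whose ligand or receptor is not among *detected* genes.

        Returns the reduced table and the number of pairs dropped.
        """
        have = set(detected)
        keep = self.records["ligand"].isin(have) & self.records["receptor"].isin(have)
        dropped = int((~keep).sum())
        reduced = self.records[keep].reset_index(drop=True)
        if reduced.empty:
            raise ValidationError("no ligand-receptor pair survives gene intersection")
        return LRPairTable(reduced, self.provenance), dropped


@dataclasses.dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("gene set with empty name")
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} has no members")


@dataclasses.dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in out:
                raise ValidationError(f"duplicate gene set name {s.name!r}")
            out[s.name] = s
        return cls(out)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())
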