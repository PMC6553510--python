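"""Cell-level quality control, log-normalization and cell-cycle scoring.

QC removes cells expressing fewer than ``min_genes`` or more than
``max_genes`` genes (noncell debris and cell aggregates respectively) and
cells whose mitochondrial count fraction exceeds ``max_mito_fraction``.
Bounds are read literally: a cell at exactly 200 or 2,500 expressed genes, or
at mitochondrial fraction exactly 0.05, is retained.

Normalization is the standard counts-per-scale-factor log transform:
``value = ln(1 + scale_factor * count / cell_total)``, which preserves the
zero pattern and the within-cell rank order of genes.

Cell-cycle scores follow the matched-control recipe: the score of a cell for
an n-gene phase set is the mean normalized expression of the set genes minus
the mean over 10n control genes chosen, once per set, as the nearest
neighbors of the set members in the standardized (mean log-expression,
detection frequency) plane.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import (
    CountMatrix,
    GeneSet,
    NormalizedMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "filter_cells",
    "log_normalize",
    "gene_set_score",
    "cycle_scores",
]


@dataclasses.dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC thresholds.

    ``min_genes``/``max_genes`` bound the number of genes with count > 0
    (inclusive); ``max_mito_fraction`` bounds the mitochondrial share of
    counts (cells strictly above are removed).  Mitochondrial genes are
    recognized by the ``mito_prefix`` on the gene symbol (mouse convention
    ``"mt-"``).
    """

    min_genes: int = 200
    max_genes: int = 2500
    max_mito_fraction: float = 0.05
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be in [0,1]")


@dataclasses.dataclass
class QCReport:
    """Per-cell QC metrics and the rule(s) that removed each discarded cell."""

    table: pd.DataFrame  # index barcode; n_genes, mito_fraction, removed_by

    @property
    def removed_barcodes(self) -> list[str]:
        return list(self.table.index[self.table["removed_by"] != ""])

    def removed_by_rule(self, rule: str) -> list[str]:
        has = self.table["removed_by"].str.split(",").apply(lambda r: rule in r)
        return list(self.table.index[has & (self.table["removed_by"] != "")])


def filter_cells(
    counts: CountMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[CountMatrix, QCReport]:
    """Remove QC-failing cells; the three rules are applied jointly in one pass.

    Raises if no cell survives (an empty result is never returned silently).
    """
    n_genes = counts.genes_per_cell()
    mito = counts.mito_fraction(thresholds.mito_prefix)
    low = n_genes < thresholds.min_genes
    high = n_genes > thresholds.max_genes
    mhigh = mito > thresholds.max_mito_fraction

    removed_by = []
    for i in range(counts.n_cells):
        rules = []
        if low[i]:
            rules.append("low_gene")
        if high[i]:
            rules.append("high_gene")
        if mhigh[i]:
            rules.append("high_mito")
        removed_by.append(",".join(rules))
    report = QCReport(
        pd.DataFrame(
            {
                "n_genes": n_genes,
                "mito_fraction": mito,
                "removed_by": removed_by,
            },
            index=pd.Index(counts.barcodes, name="barcode"),
        )
    )
    keep = ~(low | high | mhigh)
    if not keep.any():
        raise ValidationError("QC removed every cell; check thresholds and input")
    return counts.subset_cells(keep), report


def log_normalize(counts: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """``ln(1 + scale_factor * count / cell_total)`` per entry.

    Every cell must have total count > 0 (run QC first).
    """
    if scale_factor <= 0:
        raise ValidationError("scale_factor must be positive")
    totals = counts.total_per_cell().astype(float)
    if np.any(totals == 0):
        zero = [b for b, t in zip(counts.barcodes, totals) if t == 0]
        raise ValidationError(
            f"cells with zero total count (run QC first): {zero[:5]}"
        )
    mat = counts.counts.tocsc(copy=True).astype(float)
    # scale each column by scale_factor / total, then log1p on stored entries
    mat = mat @ sp.diags(scale_factor / totals)
    mat = mat.tocsr()
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        genes=counts.genes,
        barcodes=counts.barcodes,
        values=mat,
        scale_factor=float(scale_factor),
    )


# ---------------------------------------------------------------------------
# matched-control gene-set scoring
# ---------------------------------------------------------------------------

def _select_control_genes(
    norm: NormalizedMatrix, set_idx: np.ndarray, controls_per_gene: int
) -> np.ndarray:
    """Pick ``controls_per_gene`` nearest non-set neighbors per set gene.

    Coordinates are each gene's mean log-expression and detection frequency,
    z-scored across genes; distance is Euclidean; ties break by gene order;
    a control gene is used at most once, so the pooled controls number exactly
    ``controls_per_gene * len(set_idx)``.
    """
    values = norm.values.tocsr()
    n_cells = values.shape[1]
    mean_expr = np.asarray(values.mean(axis=1)).ravel()
    detect = np.asarray((values > 0).sum(axis=1)).ravel() / n_cells

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    coords = np.column_stack([zscore(mean_expr), zscore(detect)])
    in_set = np.zeros(len(norm.genes), dtype=bool)
    in_set[set_idx] = True
    candidates = np.flatnonzero(~in_set)
    if len(candidates) < controls_per_gene * len(set_idx):
        raise ValidationError(
            f"need {controls_per_gene * len(set_idx)} control genes but only "
            f"{len(candidates)} non-set genes exist"
        )
    chosen: list[int] = []
    taken = np.zeros(len(norm.genes), dtype=bool)
    for gi in set_idx:
        free = candidates[~taken[candidates]]
        d = np.linalg.norm(coords[free] - coords[gi], axis=1)
        order = np.argsort(d, kind="stable")  # ties resolve by gene order
        picked = free[order[:controls_per_gene]]
        taken[picked] = True
        chosen.extend(picked.tolist())
    return np.array(sorted(chosen), dtype=int)


def gene_set_score(
    norm: NormalizedMatrix, gene_set: GeneSet, controls_per_gene: int = 10
) -> pd.Series:
    """Per-cell matched-control score for one gene set.

    score(cell) = mean over set genes of normalized expression
                - mean over the pooled control genes.
    """
    index = {g: i for i, g in enumerate(norm.genes)}
    present = [g for g in gene_set.genes if g in index]
    missing = [g for g in gene_set.genes if g not in index]
    if missing:
        logger.warning(
            "set %r: %d gene(s) absent from matrix, dropped: %s",
            gene_set.name,
            len(missing),
            missing[:5],
        )
    if not present:
        raise ValidationError(f"no gene of set {gene_set.name!r} is in the matrix")
    set_idx = np.array([index[g] for g in present], dtype=int)
    ctrl_idx = _select_control_genes(norm, set_idx, controls_per_gene)
    values = norm.values.tocsr()
    set_mean = np.asarray(values[set_idx].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(values[ctrl_idx].mean(axis=0)).ravel()
    return pd.Series(set_mean - ctrl_mean, index=norm.barcodes, name=gene_set.name)


def cycle_scores(
    norm: NormalizedMatrix,
    g1s_set: GeneSet,
    g2m_set: GeneSet,
    controls_per_gene: int = 10,
) -> pd.DataFrame:
    """G1/S and G2/M phase scores for every cell.

    Returns a DataFrame indexed by barcode with columns ``g1s_score`` and
    ``g2m_score``; all values are finite.
    """
    g1s = gene_set_score(norm, g1s_set, controls_per_gene)
    g2m = gene_set_score(norm, g2m_set, controls_per_gene)
    out = pd.DataFrame({"g1s_score": g1s, "g2m_score": g2m})
    if not np.isfinite(out.to_numpy()).all():
        raise ValidationError("non-finite cycle score")
    return out
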