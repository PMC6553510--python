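"""Ligand-receptor communication scoring between annotated cell types.

The counting rule: a ligand-receptor pair is counted for an ordered pair of
cells (ligand cell in type A, receptor cell in type B) when the ligand gene
is expressed (> 0) in the ligand cell and the receptor gene is expressed
(> 0) in the receptor cell.  The mean interaction number between types A and
B divides the total count of such triples by |A|*|B|.  Writing f_C(g) for the
fraction of type-C cells expressing gene g, the triple count for one pair
factorizes as f_A(ligand)*|A| * f_B(receptor)*|B|, so

    M(A, B) = sum over pairs of f_A(ligand) * f_B(receptor)

exactly.  All scores depend on expression only through positivity, so raw
counts and any zero-preserving monotone normalization give identical results.

Directionality convention, fixed repo-wide: the FIRST index (matrix row,
first type argument) is the ligand cell type.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    CellAnnotation,
    CountMatrix,
    GeneSet,
    LRPairTable,
    NormalizedMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressingFractionTable",
    "InteractionMatrix",
    "PairInteractionTable",
    "ChordData",
    "GenotypeComparison",
    "expressing_fractions",
    "mean_interaction_matrix",
    "pair_interaction_scores",
    "rank_top_pairs",
    "chord_data",
    "compare_genotypes",
    "downsample_robustness",
]


@dataclasses.dataclass
class ExpressingFractionTable:
    """f_C(g): fraction of type-C cells with expression > 0, plus |C|.

    ``fractions`` is genes x cell types; ``n_cells`` maps type -> cell count.
    Every fraction is a count divided by the type's cell count.
    """

    fractions: pd.DataFrame
    n_cells: pd.Series

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if f.size and (f.min() < 0 or f.max() > 1):
            raise ValidationError("expressing fraction outside [0,1]")
        for ct in self.fractions.columns:
            if ct not in self.n_cells.index:
                raise ValidationError(f"missing cell count for type {ct!r}")
        # f * |C| must be integral (it is a cell count)
        prod = f * self.n_cells[self.fractions.columns].to_numpy()[None, :]
        if prod.size and not np.allclose(prod, np.round(prod), atol=1e-6):
            raise ValidationError("fraction times cell count is not integral")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def total_cells(self) -> int:
        return int(self.n_cells.sum())


@dataclasses.dataclass
class InteractionMatrix:
    """Directed mean interaction numbers; rows = ligand cell type."""

    matrix: pd.DataFrame
    n_pairs: int
    genotype: str | None = None
    restriction: str | None = None
    total_cells: int | None = None

    def __post_init__(self) -> None:
        m = self.matrix.to_numpy()
        if m.size and (m.min() < -1e-12 or m.max() > self.n_pairs + 1e-9):
            raise ValidationError("interaction number outside [0, n_pairs]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.matrix.index)


@dataclasses.dataclass
class PairInteractionTable:
    """Per-(pair, ligand type, receptor type) interaction scores.

    ``records`` columns: ligand, receptor, ligand_type, receptor_type,
    ligand_fraction, receptor_fraction, score, with
    score = ligand_fraction * receptor_fraction in [0, 1].
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.records["score"].to_numpy()
        if s.size and (s.min() < 0 or s.max() > 1):
            raise ValidationError("pair score outside [0,1]")

    def __len__(self) -> int:
        return len(self.records)


@dataclasses.dataclass
class ChordData:
    """Chord-diagram payload: links plus per-type contribution totals.

    Each link carries the pair, both endpoint types, the score and both
    expressing fractions; ``totals`` (index: cell type) holds each type's
    summed contribution as ligand and as receptor.  Self-links contribute to
    both columns of the same type.
    """

    links: list[dict]
    totals: pd.DataFrame

    def __post_init__(self) -> None:
        lig = {}
        rec = {}
        for link in self.links:
            lig[link["ligand_type"]] = lig.get(link["ligand_type"], 0.0) + link["score"]
            rec[link["receptor_type"]] = (
                rec.get(link["receptor_type"], 0.0) + link["score"]
            )
        for ct in self.totals.index:
            if not np.isclose(self.totals.loc[ct, "ligand_total"], lig.get(ct, 0.0)):
                raise ValidationError(f"ligand total mismatch for {ct!r}")
            if not np.isclose(self.totals.loc[ct, "receptor_total"], rec.get(ct, 0.0)):
                raise ValidationError(f"receptor total mismatch for {ct!r}")


# ---------------------------------------------------------------------------
# fractions
# ---------------------------------------------------------------------------

def expressing_fractions(
    matrix: CountMatrix | NormalizedMatrix,
    annotation: CellAnnotation,
    genes: Sequence[str],
) -> ExpressingFractionTable:
    """Per-cell-type expressing fractions for the requested genes.

    Positivity is evaluated on whatever values the matrix holds; raw counts
    and log-normalized values give identical fractions because the transform
    preserves zeros.  Genes absent from the matrix are excluded with a logged
    count.  An annotated cell type with zero cells in the matrix is an error.
    """
    data = matrix.counts if isinstance(matrix, CountMatrix) else matrix.values
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    requested = list(dict.fromkeys(genes))
    present = [g for g in requested if g in gene_pos]
    absent = [g for g in requested if g not in gene_pos]
    if absent:
        logger.info("%d requested gene(s) absent from matrix, excluded", len(absent))
    if not present:
        raise ValidationError("none of the requested genes is in the matrix")

    bar_pos = {b: i for i, b in enumerate(matrix.barcodes)}
    missing_bc = [b for b in annotation.barcodes if b not in bar_pos]
    if missing_bc:
        raise ValidationError(
            f"annotated barcodes missing from matrix: {missing_bc[:5]}"
        )
    rows = np.array([gene_pos[g] for g in present], dtype=int)
    sub = data[rows]
    positive = sub > 0

    cols: dict[str, np.ndarray] = {}
    n_cells: dict[str, int] = {}
    clusters = annotation.table["cluster"]
    for ct in sorted(clusters.unique()):
        members = [bar_pos[b] for b in clusters.index[clusters == ct]]
        if not members:
            raise ValidationError(f"cell type {ct!r} has no cells")
        idx = np.array(members, dtype=int)
        cols[ct] = np.asarray(positive[:, idx].sum(axis=1)).ravel() / len(idx)
        n_cells[ct] = len(idx)
    fractions = pd.DataFrame(cols, index=present)
    return ExpressingFractionTable(fractions=fractions, n_cells=pd.Series(n_cells))


# ---------------------------------------------------------------------------
# interaction scores
# ---------------------------------------------------------------------------

def _restrict_pairs(
    pairs: LRPairTable, restrict_to: GeneSet | None, mode: str
) -> LRPairTable:
    if restrict_to is None:
        return pairs
    members = set(restrict_to.genes)
    lig_in = pairs.records["ligand"].isin(members)
    rec_in = pairs.records["receptor"].isin(members)
    keep = (lig_in & rec_in) if mode == "both" else (lig_in | rec_in)
    reduced = pairs.records[keep].reset_index(drop=True)
    if reduced.empty:
        raise ValidationError(
            f"no pair survives restriction to set {restrict_to.name!r} (mode={mode})"
        )
    return LRPairTable(reduced, pairs.provenance)


def _covered_pairs(fractions: ExpressingFractionTable, pairs: LRPairTable) -> LRPairTable:
    covered, dropped = pairs.intersect(fractions.genes)
    if dropped:
        logger.info("%d pair(s) dropped at gene intersection", dropped)
    return covered


def mean_interaction_matrix(
    fractions: ExpressingFractionTable,
    pairs: LRPairTable,
    restrict_to: GeneSet | None = None,
    restrict_mode: str = "both",
    genotype: str | None = None,
) -> InteractionMatrix:
    """M(A, B) = sum over pairs of f_A(ligand) * f_B(receptor).

    ``restrict_to`` keeps only pairs whose genes are set members — both genes
    by default (``restrict_mode="both"``), or at least one
    (``restrict_mode="either"``).
    """
    if restrict_mode not in ("both", "either"):
        raise ValueError("restrict_mode must be 'both' or 'either'")
    pairs = _restrict_pairs(pairs, restrict_to, restrict_mode)
    pairs = _covered_pairs(fractions, pairs)
    fl = fractions.fractions.loc[pairs.records["ligand"]].to_numpy()
    fr = fractions.fractions.loc[pairs.records["receptor"]].to_numpy()
    m = fl.T @ fr
    types = fractions.cell_types
    return InteractionMatrix(
        matrix=pd.DataFrame(m, index=types, columns=types),
        n_pairs=len(pairs),
        genotype=genotype,
        restriction=None if restrict_to is None else restrict_to.name,
        total_cells=fractions.total_cells,
    )


def pair_interaction_scores(
    fractions: ExpressingFractionTable,
    pairs: LRPairTable,
    types: Sequence[str] | None = None,
) -> PairInteractionTable:
    """One record per (pair, ligand type, receptor type): s = f_A(l) * f_B(r)."""
    pairs = _covered_pairs(fractions, pairs)
    all_types = fractions.cell_types
    if types is None:
        types = all_types
    else:
        unknown = [t for t in types if t not in all_types]
        if unknown:
            raise ValidationError(f"unknown cell type(s): {unknown}")
    ligands = pairs.records["ligand"].to_numpy()
    receptors = pairs.records["receptor"].to_numpy()
    rows = []
    for lt in types:
        fa = fractions.fractions.loc[ligands, lt].to_numpy()
        for rt in types:
            fb = fractions.fractions.loc[receptors, rt].to_numpy()
            rows.append(
                pd.DataFrame(
                    {
                        "ligand": ligands,
                        "receptor": receptors,
                        "ligand_type": lt,
                        "receptor_type": rt,
                        "ligand_fraction": fa,
                        "receptor_fraction": fb,
                        "score": fa * fb,
                    }
                )
            )
    return PairInteractionTable(pd.concat(rows, ignore_index=True))


def rank_top_pairs(table: PairInteractionTable, k: int) -> pd.DataFrame:
    """Top-k records by score, descending.

    Deterministic tie-break: score desc, then ligand symbol, receptor symbol,
    ligand type, receptor type, all ascending lexicographic.  Returns
    min(k, len(table)) records.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = table.records.sort_values(
        by=["score", "ligand", "receptor", "ligand_type", "receptor_type"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ordered.head(k)


def chord_data(
    table: PairInteractionTable,
    pair_subset: Iterable[tuple[str, str]] | None = None,
) -> ChordData:
    """Chord-diagram links with both expressing fractions and per-type totals."""
    rec = table.records
    if pair_subset is not None:
        wanted = set(pair_subset)
        keep = [
            (lig, r) in wanted for lig, r in zip(rec["ligand"], rec["receptor"])
        ]
        rec = rec[keep]
    if rec.empty:
        raise ValidationError("no interaction records after pair subsetting")
    links = [
        {
            "ligand_type": row.ligand_type,
            "receptor_type": row.receptor_type,
            "ligand": row.ligand,
            "receptor": row.receptor,
            "score": float(row.score),
            "ligand_fraction": float(row.ligand_fraction),
            "receptor_fraction": float(row.receptor_fraction),
        }
        for row in rec.itertuples()
    ]
    types = sorted(set(rec["ligand_type"]) | set(rec["receptor_type"]))
    totals = pd.DataFrame(0.0, index=types, columns=["ligand_total", "receptor_total"])
    for link in links:
        totals.loc[link["ligand_type"], "ligand_total"] += link["score"]
        totals.loc[link["receptor_type"], "receptor_total"] += link["score"]
    return ChordData(links=links, totals=totals)


# ---------------------------------------------------------------------------
# genotype comparison
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GenotypeComparison:
    """Signed genotype comparison: log2((M_ko + eps) / (M_wt + eps))."""

    log2_ratio: pd.DataFrame
    wt: pd.DataFrame
    ko: pd.DataFrame
    epsilon: float


def compare_genotypes(
    m_wt: InteractionMatrix,
    m_ko: InteractionMatrix,
    epsilon: float | None = None,
) -> GenotypeComparison:
    """Element-wise log2 ratio of the two genotype matrices.

    ``epsilon`` defaults to 1 / (N_wt * N_ko) with N the total cell counts —
    the smallest score either matrix can resolve — and regularizes zeros.
    Both matrices must share type labels and pair universe.
    """
    a, b = m_wt.matrix, m_ko.matrix
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        only_wt = [t for t in a.index if t not in b.index]
        only_ko = [t for t in b.index if t not in a.index]
        raise ValidationError(
            f"cell-type label mismatch (wt-only: {only_wt}, ko-only: {only_ko})"
        )
    if m_wt.n_pairs != m_ko.n_pairs:
        raise ValidationError(
            f"pair universes differ: {m_wt.n_pairs} vs {m_ko.n_pairs}"
        )
    if epsilon is None:
        if not m_wt.total_cells or not m_ko.total_cells:
            raise ValidationError("cell totals unknown; pass epsilon explicitly")
        epsilon = 1.0 / (m_wt.total_cells * m_ko.total_cells)
    if epsilon <= 0:
        raise ValidationError("epsilon must be positive")
    ratio = np.log2((b.to_numpy() + epsilon) / (a.to_numpy() + epsilon))
    return GenotypeComparison(
        log2_ratio=pd.DataFrame(ratio, index=a.index, columns=a.columns),
        wt=a.copy(),
        ko=b.copy(),
        epsilon=float(epsilon),
    )


# ---------------------------------------------------------------------------
# cell-number robustness
# ---------------------------------------------------------------------------

def downsample_robustness(
    matrix: CountMatrix | NormalizedMatrix,
    annotation: CellAnnotation,
    pairs: LRPairTable,
    repeats: int = 100,
    seed: int = 0,
) -> tuple[InteractionMatrix, pd.DataFrame]:
    """Adjust for cell-number effects by repeated equal-size downsampling.

    Every repeat samples each cell type without replacement down to the
    smallest type's size, recomputes the mean interaction matrix, and the
    across-repeat mean and standard deviation (population SD) are returned.
    With equal type sizes every repeat uses all cells and the SD is exactly 0.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    clusters = annotation.table["cluster"]
    sizes = clusters.value_counts()
    if (sizes < 2).any():
        tiny = list(sizes.index[sizes < 2])
        raise ValidationError(f"cell type(s) with < 2 cells: {tiny}")
    target = int(sizes.min())
    genes = pairs.genes
    rng = np.random.default_rng(seed)
    mats = []
    meta = None
    for _ in range(repeats):
        kept: list[str] = []
        for ct in sorted(sizes.index):
            members = list(clusters.index[clusters == ct])
            if len(members) == target:
                kept.extend(members)
            else:
                pick = rng.choice(len(members), size=target, replace=False)
                kept.extend(members[i] for i in sorted(pick))
        sub_ann = annotation.subset(kept)
        # fractions only look at annotated barcodes, so the full matrix serves
        frac = expressing_fractions(matrix, sub_ann, genes)
        m = mean_interaction_matrix(frac, pairs)
        mats.append(m.matrix.to_numpy())
        meta = m
    stack = np.stack(mats)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    # entries identical across repeats have exactly zero dispersion; mask out
    # the roundoff that mean subtraction introduces
    constant = np.ptp(stack, axis=0) == 0
    sd[constant] = 0.0
    mean[constant] = stack[0][constant]
    types = meta.cell_types
    mean_matrix = InteractionMatrix(
        matrix=pd.DataFrame(mean, index=types, columns=types),
        n_pairs=meta.n_pairs,
        total_cells=target * len(types),
    )
    dispersion = pd.DataFrame(sd, index=types, columns=types)
    return mean_matrix, dispersion
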