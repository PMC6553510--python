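"""Shared fixtures: tiny hand-built datasets and brute-force oracles."""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import advcomm as a


@pytest.fixture
def tiny_counts() -> a.CountMatrix:
    """3 genes x 4 cells with a hand-checkable positivity pattern."""
    counts = np.array(
        [
            [0, 1, 2, 0],  # L1 expressed in cells 1,2
            [3, 0, 0, 4],  # R1 expressed in cells 0,3
            [5, 5, 5, 5],  # housekeeping, everywhere
        ]
    )
    return a.CountMatrix(
        genes=["L1", "R1", "HK"],
        barcodes=["c0", "c1", "c2", "c3"],
        counts=sp.csr_matrix(counts),
    )


@pytest.fixture
def tiny_annotation() -> a.CellAnnotation:
    return a.CellAnnotation.from_frame(
        pd.DataFrame(
            {
                "barcode": ["c0", "c1", "c2", "c3"],
                "cluster": ["A", "A", "B", "B"],
                "genotype": ["wt", "wt", "wt", "wt"],
            }
        )
    )


def brute_force_mean_interaction(
    matrix: a.CountMatrix,
    annotation: a.CellAnnotation,
    pairs: a.LRPairTable,
) -> dict[tuple[str, str], Fraction]:
    """Literal triple loop over (pair, ligand cell, receptor cell).

    Counts the triples where both genes are positive, divides by |A|*|B| in
    exact rational arithmetic.  Pairs with a gene absent from the matrix are
    skipped (gene intersection), matching the pipeline's contract.
    """
    dense = matrix.counts.toarray()
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    bar_pos = {b: i for i, b in enumerate(matrix.barcodes)}
    clusters = annotation.table["cluster"]
    members = {
        ct: [bar_pos[b] for b in clusters.index[clusters == ct]]
        for ct in sorted(clusters.unique())
    }
    out: dict[tuple[str, str], Fraction] = {}
    for ct_a, cells_a in members.items():
        for ct_b, cells_b in members.items():
            total = 0
            for _, row in pairs.records.iterrows():
                lig, rec = row["ligand"], row["receptor"]
                if lig not in gene_pos or rec not in gene_pos:
                    continue
                for i in cells_a:
                    if dense[gene_pos[lig], i] <= 0:
                        continue
                    for j in cells_b:
                        if dense[gene_pos[rec], j] > 0:
                            total += 1
            out[(ct_a, ct_b)] = Fraction(total, len(cells_a) * len(cells_b))
    return out


def random_instance(rng: np.random.Generator):
    """A random small (counts, annotation, pairs) instance for fuzzing."""
    n_genes = int(rng.integers(2, 21))
    n_cells = int(rng.integers(4, 51))
    n_types = int(rng.integers(2, 5))
    genes = [f"g{i}" for i in range(n_genes)]
    barcodes = [f"c{i}" for i in range(n_cells)]
    density = rng.uniform(0.1, 0.9)
    counts = rng.poisson(1.0, size=(n_genes, n_cells)) * (
        rng.random((n_genes, n_cells)) < density
    )
    labels = [f"T{rng.integers(n_types)}" for _ in range(n_cells)]
    # guarantee every named type has at least one cell
    for t in range(n_types):
        labels[t % n_cells] = f"T{t}"
    annotation = a.CellAnnotation.from_frame(
        pd.DataFrame({"barcode": barcodes, "cluster": labels})
    )
    n_pairs = min(int(rng.integers(1, 11)), n_genes * n_genes)
    pair_set = set()
    while len(pair_set) < n_pairs:
        pair_set.add(
            (genes[rng.integers(n_genes)], genes[rng.integers(n_genes)])
        )
    pairs = a.LRPairTable.from_pairs(sorted(pair_set))
    matrix = a.CountMatrix(genes=genes, barcodes=barcodes, counts=counts)
    return matrix, annotation, pairs
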