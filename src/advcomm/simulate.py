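"""Synthetic clustered two-genotype scRNA-seq counts with planted ground truth.

The generator emulates the structure of an adventitia-style experiment: two
genotypes (wild type and ApoE-deficient), a handful of clusters including
mesenchyme and monocyte-macrophage types, mitochondrial genes carrying the
conventional mouse ``mt-`` prefix, cells engineered to violate exactly one QC
rule each, and per-(genotype, cluster) expressing fractions planted for chosen
ligand and receptor genes.

Counts follow a negative binomial with per-(cluster, gene) mean multipliers.
For a planted record the gene is Bernoulli-gated: with probability equal to
the target fraction the cell draws a zero-truncated negative binomial
(guaranteed positive), otherwise it gets zero — so the expected expressing
fraction equals the target exactly, independent of count magnitudes.  The
realized (post-gating) fraction for every planted record is recorded in the
returned :class:`SyntheticTruth` and serves as the analytic oracle for the
downstream interaction score.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import CellAnnotation, CountMatrix, LRPairTable, ValidationError

__all__ = [
    "PlantedFraction",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "planted_expected_score",
    "default_spec",
]

_DEFAULT_CLUSTERS = (
    "Mesen_I",
    "Mesen_II",
    "Mesen_III",
    "Mesen_IV",
    "Mac_resident",
    "Mac_inflammatory",
)
_DEFAULT_GENOTYPES = ("wt", "apoe_ko")


@dataclasses.dataclass(frozen=True)
class PlantedFraction:
    """Target expressing fraction for one gene in one (genotype, cluster) group."""

    genotype: str
    cluster: str
    gene: str
    fraction: float


def _default_planted() -> tuple[PlantedFraction, ...]:
    # Mesen II chemokines talking to inflammatory macrophages, stronger in the
    # hyperlipidemic genotype — the motif the pipeline is meant to detect.
    plan = [
        ("wt", "Mesen_II", "Ccl2", 0.30),
        ("apoe_ko", "Mesen_II", "Ccl2", 0.60),
        ("wt", "Mesen_II", "Ccl7", 0.20),
        ("apoe_ko", "Mesen_II", "Ccl7", 0.45),
        ("wt", "Mac_inflammatory", "Ccr2", 0.35),
        ("apoe_ko", "Mac_inflammatory", "Ccr2", 0.50),
        ("wt", "Mac_inflammatory", "Il1r2", 0.25),
        ("apoe_ko", "Mac_inflammatory", "Il1r2", 0.40),
    ]
    return tuple(PlantedFraction(*row) for row in plan)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic dataset.

    Defaults are a desk-scale mirror of a two-genotype adventitia experiment:
    2 genotypes x 6 clusters x 300 cells, 2,000 genes of which 13 are
    mitochondrial, with low-gene and high-mito QC offenders planted.  The
    high-gene offender class needs ``min(n_genes, 3000) > 2500`` expressed
    genes to violate the upper QC bound, so it requires ``n_genes >= 2501``
    and is off by default at this gene count.
    """

    n_clusters: int = 6
    cells_per_cluster_per_genotype: int = 300
    n_genes: int = 2000
    n_mito_genes: int = 13
    baseline_mean: float = 0.5
    nb_dispersion: float = 2.0
    genotypes: tuple[str, ...] = _DEFAULT_GENOTYPES
    cluster_names: tuple[str, ...] | None = None
    planted_fractions: tuple[PlantedFraction, ...] = dataclasses.field(
        default_factory=_default_planted
    )
    qc_low_fraction: float = 0.01
    qc_high_fraction: float = 0.0
    qc_mito_fraction: float = 0.01
    seed: int = 0

    def clusters(self) -> tuple[str, ...]:
        if self.cluster_names is not None:
            if len(self.cluster_names) != self.n_clusters:
                raise ValidationError("cluster_names length != n_clusters")
            return tuple(self.cluster_names)
        if self.n_clusters <= len(_DEFAULT_CLUSTERS):
            return _DEFAULT_CLUSTERS[: self.n_clusters]
        extra = tuple(
            f"Cluster_{i}" for i in range(len(_DEFAULT_CLUSTERS) + 1, self.n_clusters + 1)
        )
        return _DEFAULT_CLUSTERS + extra

    def gene_names(self) -> list[str]:
        """Planted genes first, then generic fillers, then mt- genes last."""
        named = list(dict.fromkeys(p.gene for p in self.planted_fractions))
        for g in named:
            if g.startswith("mt-"):
                raise ValidationError("planted genes may not be mitochondrial")
        n_filler = self.n_genes - self.n_mito_genes - len(named)
        if n_filler < 0:
            raise ValidationError("n_genes too small for planted + mito genes")
        fillers = [f"Gene{i:05d}" for i in range(1, n_filler + 1)]
        mito = [f"mt-Gene{i}" for i in range(1, self.n_mito_genes + 1)]
        return named + fillers + mito

    def validate(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster_per_genotype < 1:
            raise ValidationError("need at least one cluster and one cell")
        if self.n_genes < 1 or self.n_mito_genes < 0:
            raise ValidationError("bad gene counts")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("baseline_mean and nb_dispersion must be positive")
        for p in self.planted_fractions:
            if not 0.0 <= p.fraction <= 1.0:
                raise ValidationError(f"planted fraction out of [0,1]: {p}")
            if p.genotype not in self.genotypes:
                raise ValidationError(f"planted genotype {p.genotype!r} unknown")
            if p.cluster not in self.clusters():
                raise ValidationError(f"planted cluster {p.cluster!r} unknown")
        offender = (self.qc_low_fraction, self.qc_high_fraction, self.qc_mito_fraction)
        if any(f < 0 or f >= 1 for f in offender) or sum(offender) >= 1:
            raise ValidationError("offender proportions must be in [0,1) and sum < 1")
        if self.qc_high_fraction > 0 and min(self.n_genes, 3000) <= 2500:
            raise ValidationError(
                "high-gene offenders need n_genes >= 2501 to exceed the 2500-gene bound"
            )
        self.gene_names()  # raises if inconsistent

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = json.load(fh)
        if "planted_fractions" in raw:
            raw["planted_fractions"] = tuple(
                PlantedFraction(**p) for p in raw["planted_fractions"]
            )
        for key in ("genotypes", "cluster_names"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclasses.dataclass
class SyntheticTruth:
    """What was actually planted: realized fractions and offender barcodes."""

    expressing_fraction: dict[tuple[str, str, str], float]  # (genotype, cluster, gene)
    offender_barcodes: dict[str, list[str]]  # low_gene / high_gene / high_mito

    def __post_init__(self) -> None:
        for key, frac in self.expressing_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValidationError(f"realized fraction out of [0,1] for {key}")
        all_off = [b for lst in self.offender_barcodes.values() for b in lst]
        if len(set(all_off)) != len(all_off):
            raise ValidationError("offender barcode lists are not disjoint")

    @property
    def all_offenders(self) -> list[str]:
        return [b for lst in self.offender_barcodes.values() for b in lst]

    def to_json(self, path) -> None:
        payload = {
            "expressing_fraction": [
                {"genotype": g, "cluster": c, "gene": gene, "fraction": f}
                for (g, c, gene), f in self.expressing_fraction.items()
            ],
            "offender_barcodes": self.offender_barcodes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def default_spec(**overrides) -> SyntheticSpec:
    """The default desk-scale spec, optionally with fields overridden."""
    return dataclasses.replace(SyntheticSpec(), **overrides)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _ztnb_draws(rng: np.random.Generator, r: float, p: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial via inverse-CDF above the zero mass."""
    p0 = stats.nbinom.cdf(0, r, p)
    u = rng.uniform(p0, 1.0, size=size)
    return stats.nbinom.ppf(u, r, p).astype(np.int64)


def generate(spec: SyntheticSpec) -> tuple[CountMatrix, CellAnnotation, SyntheticTruth]:
    """Generate (counts, annotation, truth) from a validated spec.

    Deterministic: identical spec (including seed) gives byte-identical output.
    """
    spec.validate()
    genes = spec.gene_names()
    gene_index = {g: i for i, g in enumerate(genes)}
    clusters = spec.clusters()
    r = spec.nb_dispersion
    n_per = spec.cells_per_cluster_per_genotype

    root = np.random.SeedSequence(spec.seed)
    ss_mult, ss_cells, ss_offenders = root.spawn(3)

    # Cluster structure: per-(cluster, gene) lognormal mean multipliers, shared
    # across genotypes so genotype differences come only from planted records.
    # Mitochondrial and planted genes stay at multiplier 1 so QC separability
    # and fraction control hold by construction.
    rng_mult = np.random.default_rng(ss_mult)
    mult = rng_mult.lognormal(mean=0.0, sigma=0.5, size=(len(clusters), len(genes)))
    planted_rows = sorted({gene_index[p.gene] for p in spec.planted_fractions})
    mito_rows = [i for i, g in enumerate(genes) if g.startswith("mt-")]
    mult[:, planted_rows] = 1.0
    mult[:, mito_rows] = 1.0

    planted_by_group: dict[tuple[str, str], list[PlantedFraction]] = {}
    for p in spec.planted_fractions:
        planted_by_group.setdefault((p.genotype, p.cluster), []).append(p)

    blocks: list[np.ndarray] = []
    barcodes: list[str] = []
    ann_rows: list[tuple[str, str, str]] = []
    truth_fraction: dict[tuple[str, str, str], float] = {}

    group_seeds = ss_cells.spawn(len(spec.genotypes) * len(clusters))
    gi = 0
    for genotype in spec.genotypes:
        for ci, cluster in enumerate(clusters):
            rng = np.random.default_rng(group_seeds[gi])
            gi += 1
            means = spec.baseline_mean * mult[ci]  # per gene
            pnb = r / (r + means)
            block = rng.negative_binomial(r, pnb[:, None], size=(len(genes), n_per))
            for rec in planted_by_group.get((genotype, cluster), []):
                row = gene_index[rec.gene]
                gate = rng.random(n_per) < rec.fraction
                vals = np.zeros(n_per, dtype=np.int64)
                if gate.any():
                    p_base = r / (r + spec.baseline_mean)
                    vals[gate] = _ztnb_draws(rng, r, p_base, int(gate.sum()))
                block[row] = vals
                truth_fraction[(genotype, cluster, rec.gene)] = float(
                    gate.sum() / n_per
                )
            blocks.append(block)
            for j in range(n_per):
                bc = f"{genotype}:{cluster}:c{j:04d}"
                barcodes.append(bc)
                ann_rows.append((bc, cluster, genotype))

    n_normal = len(barcodes)
    counts = np.concatenate(blocks, axis=1)

    # QC offenders: appended extra cells, each violating exactly one rule.
    rng_off = np.random.default_rng(ss_offenders)
    offender_barcodes: dict[str, list[str]] = {
        "low_gene": [],
        "high_gene": [],
        "high_mito": [],
    }
    non_mito_rows = np.array(
        [i for i, g in enumerate(genes) if not g.startswith("mt-")]
    )
    groups = [(g, c) for g in spec.genotypes for c in clusters]
    extra_cols: list[np.ndarray] = []

    def _append(kind: str, col: np.ndarray, k: int) -> None:
        genotype, cluster = groups[k % len(groups)]
        bc = f"{genotype}:{cluster}:{kind}{k:03d}"
        offender_barcodes[kind].append(bc)
        barcodes.append(bc)
        ann_rows.append((bc, cluster, genotype))
        extra_cols.append(col)

    n_low = int(round(spec.qc_low_fraction * n_normal))
    for k in range(n_low):
        col = np.zeros(len(genes), dtype=np.int64)
        rows = rng_off.choice(non_mito_rows, size=50, replace=False)
        col[rows] = 1
        _append("low_gene", col, k)

    n_high = int(round(spec.qc_high_fraction * n_normal))
    k_expr = min(spec.n_genes, 3000)
    for k in range(n_high):
        col = np.zeros(len(genes), dtype=np.int64)
        rows = rng_off.choice(len(genes), size=k_expr, replace=False)
        col[rows] = 1
        _append("high_gene", col, k)

    n_mito_off = int(round(spec.qc_mito_fraction * n_normal))
    p_base = r / (r + spec.baseline_mean)
    for k in range(n_mito_off):
        col = rng_off.negative_binomial(r, p_base, size=len(genes)).astype(np.int64)
        col[mito_rows] = 0
        non_mito_total = int(col.sum())
        if non_mito_total == 0:
            col[non_mito_rows[:250]] = 1
            non_mito_total = 250
        share = rng_off.uniform(0.10, 0.30)
        need = int(np.ceil(share / (1.0 - share) * non_mito_total))
        if mito_rows:
            per = int(np.ceil(need / len(mito_rows)))
            col[mito_rows] = per
        _append("high_mito", col, k)

    if extra_cols:
        counts = np.concatenate([counts, np.stack(extra_cols, axis=1)], axis=1)

    matrix = CountMatrix(genes=genes, barcodes=barcodes, counts=sp.csr_matrix(counts))
    annotation = CellAnnotation.from_frame(
        pd.DataFrame(ann_rows, columns=["barcode", "cluster", "genotype"])
    )
    truth = SyntheticTruth(
        expressing_fraction=truth_fraction, offender_barcodes=offender_barcodes
    )
    return matrix, annotation, truth


# ---------------------------------------------------------------------------
# analytic oracle
# ---------------------------------------------------------------------------

def planted_expected_score(
    truth: SyntheticTruth,
    pairs: LRPairTable,
    ligand_cluster: str,
    receptor_cluster: str,
    genotype: str,
) -> float:
    """Analytic expectation of the mean interaction number between two clusters.

    Sums, over the pair universe, the product of the planted expressing
    fraction of the ligand in the ligand cluster and of the receptor in the
    receptor cluster.  Every pair gene must carry a planted fraction for the
    requested (genotype, cluster); anything else is an error, because the
    oracle is only defined where ground truth exists.
    """
    total = 0.0
    for _, row in pairs.records.iterrows():
        key_l = (genotype, ligand_cluster, row["ligand"])
        key_r = (genotype, receptor_cluster, row["receptor"])
        for key in (key_l, key_r):
            if key not in truth.expressing_fraction:
                raise ValidationError(f"no planted fraction for {key}")
        total += (
            truth.expressing_fraction[key_l] * truth.expressing_fraction[key_r]
        )
    return total
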