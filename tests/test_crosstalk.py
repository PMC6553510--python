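"""Interaction scoring: oracle equivalence, factorization, invariances."""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import advcomm as a
from conftest import brute_force_mean_interaction, random_instance


class TestExpressingFractions:
    def test_direct_count(self, tiny_counts, tiny_annotation):
        frac = a.expressing_fractions(tiny_counts, tiny_annotation,
                                      ["L1", "R1", "HK"])
        # L1 positive in c1 (A) and c2 (B); R1 in c0 (A) and c3 (B)
        assert frac.fractions.loc["L1", "A"] == 0.5
        assert frac.fractions.loc["L1", "B"] == 0.5
        assert frac.fractions.loc["HK", "A"] == 1.0
        assert frac.n_cells["A"] == 2

    def test_all_zero_gene(self, tiny_annotation):
        counts = np.zeros((2, 4))
        counts[1] = 1
        m = a.CountMatrix(genes=["dead", "alive"],
                          barcodes=["c0", "c1", "c2", "c3"], counts=counts)
        frac = a.expressing_fractions(m, tiny_annotation, ["dead", "alive"])
        assert (frac.fractions.loc["dead"] == 0).all()

    def test_raw_and_normalized_fractions_identical(self, tiny_counts, tiny_annotation):
        raw = a.expressing_fractions(tiny_counts, tiny_annotation, tiny_counts.genes)
        norm = a.log_normalize(tiny_counts)
        via_norm = a.expressing_fractions(norm, tiny_annotation, tiny_counts.genes)
        pd.testing.assert_frame_equal(raw.fractions, via_norm.fractions)

    def test_absent_genes_excluded_and_empty_is_error(self, tiny_counts, tiny_annotation):
        frac = a.expressing_fractions(tiny_counts, tiny_annotation, ["L1", "ghost"])
        assert frac.genes == ["L1"]
        with pytest.raises(a.ValidationError):
            a.expressing_fractions(tiny_counts, tiny_annotation, ["ghost"])


class TestMeanInteractionMatrix:
    def test_worked_example_two_by_three(self):
        """A=4 cells (ligand in 2), B=5 cells (receptor in 3) -> 6/20 = 0.3."""
        counts = np.zeros((2, 9))
        counts[0, [0, 1]] = 1  # ligand in 2 of 4 A-cells
        counts[1, [4, 5, 6]] = 2  # receptor in 3 of 5 B-cells
        m = a.CountMatrix(genes=["L", "R"], barcodes=[f"c{i}" for i in range(9)],
                          counts=counts)
        ann = a.CellAnnotation.from_frame(pd.DataFrame({
            "barcode": [f"c{i}" for i in range(9)],
            "cluster": ["A"] * 4 + ["B"] * 5,
        }))
        pairs = a.LRPairTable.from_pairs([("L", "R")])
        frac = a.expressing_fractions(m, ann, pairs.genes)
        mat = a.mean_interaction_matrix(frac, pairs)
        assert mat.matrix.loc["A", "B"] == pytest.approx(0.3)
        oracle = brute_force_mean_interaction(m, ann, pairs)
        assert Fraction(mat.matrix.loc["A", "B"]).limit_denominator(10**6) \
            == oracle[("A", "B")]

    def test_oracle_equivalence_fuzzed(self):
        """Fast fuzz against the exact triple-loop counting rule."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            m, ann, pairs = random_instance(rng)
            try:
                frac = a.expressing_fractions(m, ann, pairs.genes)
                mat = a.mean_interaction_matrix(frac, pairs)
            except a.ValidationError:
                continue  # no pair survives intersection: oracle undefined too
            oracle = brute_force_mean_interaction(m, ann, pairs)
            for ct_a in mat.cell_types:
                for ct_b in mat.cell_types:
                    assert mat.matrix.loc[ct_a, ct_b] == pytest.approx(
                        float(oracle[(ct_a, ct_b)]), abs=1e-12
                    )

    def test_saturated_upper_bound(self, tiny_annotation):
        counts = np.ones((6, 4))
        genes = ["L1", "R1", "L2", "R2", "L3", "R3"]
        m = a.CountMatrix(genes=genes, barcodes=["c0", "c1", "c2", "c3"],
                          counts=counts)
        pairs = a.LRPairTable.from_pairs([("L1", "R1"), ("L2", "R2"), ("L3", "R3")])
        frac = a.expressing_fractions(m, tiny_annotation, pairs.genes)
        mat = a.mean_interaction_matrix(frac, pairs)
        assert (mat.matrix.to_numpy() == 3.0).all()

    def test_gene_set_restriction_modes(self, tiny_counts, tiny_annotation):
        pairs = a.LRPairTable.from_pairs([("L1", "R1"), ("L1", "HK")])
        frac = a.expressing_fractions(tiny_counts, tiny_annotation, tiny_counts.genes)
        both = a.mean_interaction_matrix(
            frac, pairs, restrict_to=a.GeneSet("s", "", ["L1", "R1"]))
        assert both.n_pairs == 1
        either = a.mean_interaction_matrix(
            frac, pairs, restrict_to=a.GeneSet("s", "", ["R1"]),
            restrict_mode="either")
        assert either.n_pairs == 1
        with pytest.raises(a.ValidationError, match="restriction"):
            a.mean_interaction_matrix(
                frac, pairs, restrict_to=a.GeneSet("s", "", ["ghost"]))


class TestPairScoresAndRanking:
    def test_score_is_product_of_fractions(self):
        frac = a.ExpressingFractionTable(
            fractions=pd.DataFrame({"A": [0.5, 0.0], "B": [0.0, 0.25]},
                                   index=["Ccl2", "Ccr2"]),
            n_cells=pd.Series({"A": 4, "B": 4}),
        )
        table = a.pair_interaction_scores(frac, a.LRPairTable.from_pairs([("Ccl2", "Ccr2")]))
        rec = table.records.set_index(["ligand_type", "receptor_type"])
        assert rec.loc[("A", "B"), "score"] == pytest.approx(0.125)
        # direction matters: B has no Ccl2 expression
        assert rec.loc[("B", "A"), "score"] == 0.0

    def test_sum_of_pair_scores_reproduces_matrix(self, tiny_counts, tiny_annotation):
        pairs = a.LRPairTable.from_pairs([("L1", "R1"), ("HK", "L1"), ("R1", "HK")])
        frac = a.expressing_fractions(tiny_counts, tiny_annotation, tiny_counts.genes)
        mat = a.mean_interaction_matrix(frac, pairs)
        table = a.pair_interaction_scores(frac, pairs)
        summed = table.records.groupby(["ligand_type", "receptor_type"])["score"].sum()
        for ct_a in mat.cell_types:
            for ct_b in mat.cell_types:
                assert summed.loc[(ct_a, ct_b)] == pytest.approx(
                    mat.matrix.loc[ct_a, ct_b], abs=1e-12)

    def test_unknown_type_requested_is_error(self, tiny_counts, tiny_annotation):
        frac = a.expressing_fractions(tiny_counts, tiny_annotation, tiny_counts.genes)
        with pytest.raises(a.ValidationError, match="unknown cell type"):
            a.pair_interaction_scores(
                frac, a.LRPairTable.from_pairs([("L1", "R1")]), types=["A", "Z"])

    def test_rank_tie_break_lexicographic(self):
        records = pd.DataFrame({
            "ligand": ["Zz", "Aa", "Mm"],
            "receptor": ["R", "R", "R"],
            "ligand_type": ["A"] * 3,
            "receptor_type": ["B"] * 3,
            "ligand_fraction": [0.3, 0.3, 0.1],
            "receptor_fraction": [1.0, 1.0, 1.0],
            "score": [0.3, 0.3, 0.1],
        })
        top = a.rank_top_pairs(a.PairInteractionTable(records), k=2)
        assert list(top["ligand"]) == ["Aa", "Zz"]
        # k beyond table size returns everything, no padding
        full = a.rank_top_pairs(a.PairInteractionTable(records), k=10)
        assert len(full) == 3
        assert list(full["ligand"]) == ["Aa", "Zz", "Mm"]


class TestChordData:
    def test_single_link_bookkeeping(self):
        records = pd.DataFrame({
            "ligand": ["Cxcl12"], "receptor": ["Cxcr4"],
            "ligand_type": ["M14"], "receptor_type": ["M7"],
            "ligand_fraction": [0.5], "receptor_fraction": [0.4],
            "score": [0.2],
        })
        chord = a.chord_data(a.PairInteractionTable(records))
        assert len(chord.links) == 1
        assert chord.totals.loc["M14", "ligand_total"] == pytest.approx(0.2)
        assert chord.totals.loc["M7", "receptor_total"] == pytest.approx(0.2)
        assert chord.totals.loc["M14", "receptor_total"] == 0.0

    def test_self_link_contributes_to_both_columns(self):
        records = pd.DataFrame({
            "ligand": ["L"], "receptor": ["R"],
            "ligand_type": ["A"], "receptor_type": ["A"],
            "ligand_fraction": [1.0], "receptor_fraction": [0.5],
            "score": [0.5],
        })
        chord = a.chord_data(a.PairInteractionTable(records))
        assert chord.totals.loc["A", "ligand_total"] == pytest.approx(0.5)
        assert chord.totals.loc["A", "receptor_total"] == pytest.approx(0.5)

    def test_totals_conserve_scores(self, tiny_counts, tiny_annotation):
        pairs = a.LRPairTable.from_pairs([("L1", "R1"), ("HK", "R1")])
        frac = a.expressing_fractions(tiny_counts, tiny_annotation, tiny_counts.genes)
        table = a.pair_interaction_scores(frac, pairs)
        chord = a.chord_data(table)
        total_score = table.records["score"].sum()
        assert chord.totals["ligand_total"].sum() == pytest.approx(total_score)
        assert chord.totals["receptor_total"].sum() == pytest.approx(total_score)

    def test_pair_subset_and_empty_error(self, tiny_counts, tiny_annotation):
        pairs = a.LRPairTable.from_pairs([("L1", "R1"), ("HK", "R1")])
        frac = a.expressing_fractions(tiny_counts, tiny_annotation, tiny_counts.genes)
        table = a.pair_interaction_scores(frac, pairs)
        chord = a.chord_data(table, pair_subset=[("L1", "R1")])
        assert all(l["ligand"] == "L1" for l in chord.links)
        with pytest.raises(a.ValidationError):
            a.chord_data(table, pair_subset=[("nope", "nada")])


class TestCompareGenotypes:
    @staticmethod
    def interaction(values, n_pairs=1, total_cells=100):
        return a.InteractionMatrix(
            matrix=pd.DataFrame(values, index=["A", "B"], columns=["A", "B"]),
            n_pairs=n_pairs, total_cells=total_cells)

    def test_identity_gives_zero(self):
        m = self.interaction([[0.1, 0.2], [0.3, 0.4]])
        cmp = a.compare_genotypes(m, m)
        np.testing.assert_allclose(cmp.log2_ratio.to_numpy(), 0.0)

    def test_closed_form_doubling(self):
        wt = self.interaction([[0.1, 0.1], [0.1, 0.1]])
        ko = self.interaction([[0.2, 0.2], [0.2, 0.2]])
        cmp = a.compare_genotypes(wt, ko, epsilon=1e-12)
        np.testing.assert_allclose(cmp.log2_ratio.to_numpy(), 1.0, atol=1e-9)

    def test_both_zero_regularized_to_zero(self):
        wt = self.interaction([[0.0, 0.0], [0.0, 0.0]])
        ko = self.interaction([[0.0, 0.0], [0.0, 0.0]])
        cmp = a.compare_genotypes(wt, ko)
        np.testing.assert_allclose(cmp.log2_ratio.to_numpy(), 0.0)
        assert cmp.epsilon == pytest.approx(1.0 / (100 * 100))

    def test_label_mismatch_listed(self):
        wt = self.interaction([[0.1, 0.2], [0.3, 0.4]])
        ko = a.InteractionMatrix(
            matrix=pd.DataFrame([[0.1, 0.2], [0.3, 0.4]],
                                index=["A", "C"], columns=["A", "C"]),
            n_pairs=1, total_cells=100)
        with pytest.raises(a.ValidationError, match="label mismatch"):
            a.compare_genotypes(wt, ko)


class TestNormalizationInvariance:
    def test_outputs_identical_on_counts_and_normalized(self):
        m, ann, _ = a.generate(a.default_spec(cells_per_cluster_per_genotype=40,
                                              seed=21))
        filtered, _ = a.filter_cells(m)
        ann_f = ann.subset(filtered.barcodes)
        pairs = a.LRPairTable.from_pairs([("Ccl2", "Ccr2"), ("Ccl7", "Il1r2")])
        norm = a.log_normalize(filtered)
        f_raw = a.expressing_fractions(filtered, ann_f, pairs.genes)
        f_norm = a.expressing_fractions(norm, ann_f, pairs.genes)
        m_raw = a.mean_interaction_matrix(f_raw, pairs)
        m_norm = a.mean_interaction_matrix(f_norm, pairs)
        pd.testing.assert_frame_equal(m_raw.matrix, m_norm.matrix)
        t_raw = a.pair_interaction_scores(f_raw, pairs)
        t_norm = a.pair_interaction_scores(f_norm, pairs)
        pd.testing.assert_frame_equal(t_raw.records, t_norm.records)


class TestDownsampleRobustness:
    def test_equal_sizes_zero_dispersion(self, tiny_counts, tiny_annotation):
        pairs = a.LRPairTable.from_pairs([("L1", "R1")])
        mean_m, disp = a.downsample_robustness(
            tiny_counts, tiny_annotation, pairs, repeats=5, seed=0)
        assert (disp.to_numpy() == 0).all()
        full = a.mean_interaction_matrix(
            a.expressing_fractions(tiny_counts, tiny_annotation, pairs.genes), pairs)
        pd.testing.assert_frame_equal(mean_m.matrix, full.matrix)

    def test_deterministic_given_seed(self):
        m, ann, _ = a.generate(a.default_spec(cells_per_cluster_per_genotype=30,
                                              seed=4, qc_low_fraction=0.0,
                                              qc_mito_fraction=0.0))
        # unequal sizes: drop a few cells from one cluster
        keep = [b for b in m.barcodes if not b.startswith("wt:Mesen_I:c000")]
        m2 = m.subset_cells(keep)
        ann2 = ann.subset(keep)
        pairs = a.LRPairTable.from_pairs([("Ccl2", "Ccr2")])
        out1 = a.downsample_robustness(m2, ann2, pairs, repeats=3, seed=7)
        out2 = a.downsample_robustness(m2, ann2, pairs, repeats=3, seed=7)
        pd.testing.assert_frame_equal(out1[0].matrix, out2[0].matrix)
        pd.testing.assert_frame_equal(out1[1], out2[1])

    def test_downsampled_mean_tracks_full_matrix(self):
        m, ann, _ = a.generate(a.default_spec(cells_per_cluster_per_genotype=150,
                                              seed=8, qc_low_fraction=0.0,
                                              qc_mito_fraction=0.0))
        ko = ann.by_genotype("apoe_ko")
        # make sizes unequal: halve one cluster
        drop = [b for b in ko.barcodes
                if b.startswith("apoe_ko:Mesen_I:c00") and int(b[-2:]) < 75][:75]
        kept = [b for b in ko.barcodes if b not in set(drop)]
        ann_u = ko.subset(kept)
        pairs = a.LRPairTable.from_pairs([("Ccl2", "Ccr2")])
        full = a.mean_interaction_matrix(
            a.expressing_fractions(m, ann_u, pairs.genes), pairs)
        mean_m, disp = a.downsample_robustness(m, ann_u, pairs, repeats=100, seed=3)
        se = disp.to_numpy() / np.sqrt(100)
        delta = np.abs(mean_m.matrix.to_numpy() - full.matrix.to_numpy())
        assert (delta <= 3 * se + 1e-12).all()

    def test_singleton_type_is_error(self, tiny_counts):
        ann = a.CellAnnotation.from_frame(pd.DataFrame({
            "barcode": ["c0", "c1", "c2", "c3"],
            "cluster": ["A", "A", "A", "B"],
        }))
        with pytest.raises(a.ValidationError, match="< 2 cells"):
            a.downsample_robustness(tiny_counts, ann,
                                    a.LRPairTable.from_pairs([("L1", "R1")]),
                                    repeats=2, seed=0)


class TestPermutationInvariance:
    def test_cell_and_pair_order_do_not_matter(self):
        rng = np.random.default_rng(55)
        m, ann, pairs = random_instance(rng)
        frac = a.expressing_fractions(m, ann, pairs.genes)
        base = a.mean_interaction_matrix(frac, pairs)
        # permute cells
        perm = rng.permutation(m.n_cells)
        m_p = a.CountMatrix(genes=m.genes,
                            barcodes=[m.barcodes[i] for i in perm],
                            counts=m.counts[:, perm])
        ann_p = a.CellAnnotation(ann.table.iloc[perm].copy())
        frac_p = a.expressing_fractions(m_p, ann_p, pairs.genes)
        again = a.mean_interaction_matrix(frac_p, pairs)
        pd.testing.assert_frame_equal(base.matrix, again.matrix)
        # permute pairs
        shuffled = pairs.records.sample(frac=1.0, random_state=1)
        pairs_p = a.LRPairTable(shuffled.reset_index(drop=True))
        mat_p = a.mean_interaction_matrix(frac, pairs_p)
        pd.testing.assert_frame_equal(base.matrix, mat_p.matrix)
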