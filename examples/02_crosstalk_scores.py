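"""Score ligand-receptor cross-talk between cell types.

The interaction score between an ordered pair of cell types is, per
ligand-receptor pair, the product of the ligand's expressing fraction in the
sender type and the receptor's expressing fraction in the receiver type; the
mean interaction number sums this over the pair universe.  Here the generator
planted Ccl2/Ccl7 in Mesen_II and Ccr2/Il1r2 in inflammatory macrophages, so
the Mesen_II -> Mac_inflammatory direction should stand out.
"""
import advcomm as a

matrix, annotation, truth = a.generate(a.default_spec(seed=7))
filtered, _ = a.filter_cells(matrix)
ann = annotation.subset(filtered.barcodes).by_genotype("apoe_ko")

pairs = a.LRPairTable.from_pairs(
    [("Ccl2", "Ccr2"), ("Ccl7", "Il1r2")], provenance="example"
)
frac = a.expressing_fractions(filtered, ann, pairs.genes)
mat = a.mean_interaction_matrix(frac, pairs, genotype="apoe_ko")
print("mean interaction numbers (rows = ligand cell type):")
print(mat.matrix.round(3).to_string())

table = a.pair_interaction_scores(frac, pairs)
top = a.rank_top_pairs(table, k=3)
print("\ntop 3 (pair, sender, receiver) scores:")
print(top[["ligand", "receptor", "ligand_type", "receptor_type", "score"]]
      .round(3).to_string(index=False))

# the analytic expectation from the planted fractions matches the estimate
expected = a.planted_expected_score(
    truth, pairs, "Mesen_II", "Mac_inflammatory", "apoe_ko")
observed = mat.matrix.loc["Mesen_II", "Mac_inflammatory"]
print(f"\nMesen_II -> Mac_inflammatory: observed {observed:.4f}, "
      f"planted expectation {expected:.4f}")

chord = a.chord_data(table)
print(f"chord data: {len(chord.links)} links; Mesen_II total as ligand "
      f"{chord.totals.loc['Mesen_II', 'ligand_total']:.3f}")
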