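"""Compare cross-talk strength between genotypes, with a robustness check.

The generator plants stronger chemokine expression in the knockout genotype,
mimicking enhanced mesenchyme-to-macrophage signalling under hyperlipidemia.
The log2 ratio matrix makes the direction and size of the change explicit,
and repeated equal-size downsampling shows the pattern is not a cell-number
artifact.
"""
import advcomm as a

matrix, annotation, _ = a.generate(a.default_spec(seed=7))
filtered, _ = a.filter_cells(matrix)
ann = annotation.subset(filtered.barcodes)
pairs = a.LRPairTable.from_pairs([("Ccl2", "Ccr2"), ("Ccl7", "Il1r2")])

mats = {}
for genotype in ("wt", "apoe_ko"):
    sub = ann.by_genotype(genotype)
    frac = a.expressing_fractions(filtered, sub, pairs.genes)
    mats[genotype] = a.mean_interaction_matrix(frac, pairs, genotype=genotype)

cmp = a.compare_genotypes(mats["wt"], mats["apoe_ko"])
print("log2(knockout / wild-type) mean interaction numbers:")
print(cmp.log2_ratio.round(2).to_string())
cell = cmp.log2_ratio.loc["Mesen_II", "Mac_inflammatory"]
print(f"\nMesen_II -> Mac_inflammatory log2 ratio: {cell:.2f} "
      f"(positive = stronger cross-talk in the knockout)")

# make cluster sizes unequal (halve one cluster) so downsampling has work to do
ko = ann.by_genotype("apoe_ko")
uneven = ko.subset([b for b in ko.barcodes
                    if not b.startswith("apoe_ko:Mesen_III:c00")])
full = a.mean_interaction_matrix(
    a.expressing_fractions(filtered, uneven, pairs.genes), pairs)
mean_m, sd = a.downsample_robustness(filtered, uneven, pairs, repeats=50, seed=1)
dev = (mean_m.matrix - full.matrix).abs().to_numpy().max()
print(f"\ndownsample robustness (50 repeats at the smallest cluster's size): "
      f"max |downsampled mean - full-data M| = {dev:.4f}, max across-repeat SD "
      f"= {sd.to_numpy().max():.4f} — the interaction pattern is stable when "
      f"the cell-number effect is adjusted away")
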