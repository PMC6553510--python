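"""Test a ligand list for over-representation in gene sets.

Given the ligands of the top-ranked interactions, ask whether they overlap a
gene set (for example an inflammatory-response set) more than chance, using
the hypergeometric tail against the detected-gene universe, with
Benjamini-Hochberg adjustment across sets.
"""
import advcomm as a

universe = [f"Gene{i:05d}" for i in range(1, 201)] + [
    "Ccl2", "Ccl7", "Ccl24", "Il1b", "Cxcl12", "Timp1",
]
query = ["Ccl2", "Ccl7", "Cxcl12", "Timp1"]  # e.g. top-pair ligands
sets = a.GeneSetCollection.from_sets([
    a.GeneSet("inflammatory_response", "chemokines and interleukins",
              ["Ccl2", "Ccl7", "Ccl24", "Il1b", "Cxcl12"]),
    a.GeneSet("random_block", "first 20 filler genes",
              [f"Gene{i:05d}" for i in range(1, 21)]),
])

table = a.overrepresentation(query, sets, universe)
print(table.round(6).to_string(index=False))
best = table.iloc[0]
print(f"\n{best['set']}: {best['overlap']}/{best['query_size']} query genes in a "
      f"{best['set_size']}-gene set (universe {best['universe_size']}); "
      f"fold {best['fold_enrichment']:.1f}, p = {best['p_value']:.2e} — far more "
      f"overlap than a random draw of this size would give.")
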