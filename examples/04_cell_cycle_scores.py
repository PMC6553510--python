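"""Score cells for cell-cycle phase with matched control genes.

A phase score is the mean normalized expression of the phase gene set minus
the mean over control genes matched on expression level and detection
frequency (10 controls per set gene).  On data with no planted cycling
signal the scores should hover around zero for both phases.
"""
import advcomm as a

matrix, annotation, _ = a.generate(a.default_spec(seed=7))
filtered, _ = a.filter_cells(matrix)
norm = a.log_normalize(filtered)

# stand-in phase sets drawn from the synthetic gene list (no cycling planted)
g1s = a.GeneSet("g1s", "synthetic stand-in", [f"Gene{i:05d}" for i in range(1, 11)])
g2m = a.GeneSet("g2m", "synthetic stand-in", [f"Gene{i:05d}" for i in range(11, 21)])

scores = a.cycle_scores(norm, g1s, g2m, controls_per_gene=10)
print(scores.describe().loc[["mean", "std", "min", "max"]].round(3).to_string())
print("\nmeans near zero: neither phase set is coherently elevated, i.e. the "
      "synthetic population shows no cycling subpopulation (as planted).")
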