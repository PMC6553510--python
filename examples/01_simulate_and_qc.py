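"""Generate a synthetic two-genotype dataset and run cell-level QC.

The generator plants cells that violate exactly one QC rule each (too few
expressed genes, or too high a mitochondrial count fraction), so we can check
that filtering removes precisely the planted offenders and nothing else.
"""
import advcomm as a

spec = a.default_spec(seed=7)
matrix, annotation, truth = a.generate(spec)
print(f"generated {matrix.n_genes} genes x {matrix.n_cells} cells "
      f"({len(annotation.clusters)} clusters x {len(annotation.genotypes)} genotypes)")
print(f"planted QC offenders: "
      f"{ {k: len(v) for k, v in truth.offender_barcodes.items()} }")

filtered, report = a.filter_cells(matrix, a.QCThresholds())
removed = set(report.removed_barcodes)
print(f"QC removed {len(removed)} cells; kept {filtered.n_cells}")
print(f"removed set equals planted offenders: {removed == set(truth.all_offenders)}")
# The boolean should be True: real cells are built to sit safely inside the
# 200-2500 expressed-gene window with mito fraction well under 0.05.

norm = a.log_normalize(filtered, scale_factor=10_000)
print(f"log-normalized at scale factor {norm.scale_factor:g}; "
      f"max value {norm.values.max():.3f}")
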