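# Methods

## The interaction model

`advcomm` quantifies potential cell-cell communication in clustered
single-cell RNA-seq data from co-expression of ligand and receptor genes.
The unit of evidence is a *counted triple*: a ligand-receptor pair (l, r), a
cell i of sender type A with count(l, i) > 0, and a cell j of receiver type B
with count(r, j) > 0.  The **mean interaction number** between the ordered
types (A, B) is the number of counted triples divided by |A|·|B|.

Writing f_C(g) for the expressing fraction — the share of type-C cells with
nonzero expression of g — the triple count for one pair is
(f_A(l)·|A|) · (f_B(r)·|B|), so

    M(A, B) = Σ_p f_A(l_p) · f_B(r_p)

exactly, and the per-pair score s_p(A, B) = f_A(l_p)·f_B(r_p) lies in [0, 1].
The implementation computes the factorized form (a genes×types fraction table
and one matrix product); the test suite verifies exact agreement with the
literal triple loop in integer-ratio arithmetic on fuzzed instances, so the
factorization is a proven rewrite, not an approximation.

Properties that follow and are enforced as invariants:

- 0 ≤ M(A, B) ≤ number of pairs in the universe; M is generally asymmetric
  (rows are always the ligand/sender type).
- Scores depend on expression only through positivity, so they are identical
  on raw counts and on any zero-preserving monotone transform (e.g. the log
  normalization below).  Both matrix types are accepted; positivity is simply
  evaluated on whatever values are supplied.
- Self-pairs (l = r) and within-type links (A = A) are ordinary cases.

The model is deliberately simple: it predicts *potential* communication from
transcript co-occurrence.  It knows nothing about protein abundance,
secretion, spatial proximity, or statistical significance of a link against a
label-permutation null; none of those are modelled here.

### Pair universe, restriction, ranking

The pair list is user-supplied (two-column TSV/CSV).  Pairs whose ligand or
receptor is not among the detected genes are dropped at intersection time
with a logged count.  An optional gene-set restriction keeps pairs whose
genes are set members — by default both genes must be members; an
"either-gene" mode is available because figure-legend conventions in the
literature are ambiguous on this point.  Top-k ranking sorts by score
descending with a deterministic tie-break (ligand, receptor, sender,
receiver, lexicographic).

### Genotype comparison

Two interaction matrices over the same types and pair universe are compared
element-wise as log2((M_ko + ε)/(M_wt + ε)).  ε defaults to 1/(N_wt·N_ko)
(N = total cells per genotype): one counted triple out of the maximum
possible is the smallest resolvable score, so the regularizer is scale-aware
rather than an arbitrary pseudocount.  Entries that are zero in both
genotypes map to a log-ratio of exactly 0.

### Cell-number robustness

Expressing fractions, and hence M, are estimated more noisily in small
clusters, and comparing clusters of very different sizes can look like
biology.  `downsample_robustness` repeatedly samples every type without
replacement down to the smallest type's size, recomputes M, and reports the
across-repeat mean and population SD.  Under simple random sampling each
expressing fraction is exactly unbiased for its full-data value, so for
distinct sender and receiver types (independent samples) the mean downsampled
M converges on the full-data M; same-type (diagonal) entries additionally
carry an O(1/m) covariance term between the two fraction estimates, which is
negligible at the default sizes but is the reason the accompanying checks are
stated in standard-error terms rather than as exact equalities.  Entries
identical across all repeats are reported with SD exactly 0 (a roundoff guard
masks the ~1e-17 residue of float mean subtraction).

## Quality control and normalization

Cells are removed when they express fewer than 200 or more than 2,500 genes
(debris and aggregates/doublets respectively) or when mitochondrial genes —
recognized by the mouse-convention symbol prefix `mt-`, configurable — exceed
0.05 of their counts.  The inequalities are read literally: 200, 2,500 and
0.05 exactly are retained.  The three rules are conjunctive and applied in
one pass; order cannot change the result.  Removing every cell raises an
error rather than returning an empty matrix.  All thresholds are parameters
of `QCThresholds`; the numbers above are the defaults.

Normalization is counts-per-scale-factor log transform:
value(g, i) = ln(1 + s·count(g, i)/total(i)) with s = 10,000 by default (the
convention of the major single-cell toolkits).  The transform preserves the
zero pattern and within-cell rank order — which is exactly what the
interaction model needs — and doubling every count in a cell leaves its
values unchanged.

## Cell-cycle (gene-set) scoring

The score of a cell for an n-gene phase set is the mean normalized expression
of the set genes minus the mean over 10n control genes.  Controls are chosen
once per set (not per cell): each gene is placed in the plane of
(mean log-expression, detection frequency), both coordinates z-scored across
genes; for each set gene its 10 nearest non-set, not-yet-chosen neighbors by
Euclidean distance are taken, ties broken by gene order, giving exactly 10n
pooled controls.  "Nearest by expression level and detection frequency" does
not pin down a metric; standardized Euclidean distance with per-set-gene
matching is the simplest faithful reading and is fixed here as the package's
convention.  When set and control genes are exchangeable draws from one
distribution the expected score is 0; a planted additive shift in the set
genes is recovered unbiasedly — both are verified by simulation at 3-SE
tolerance.

## Over-representation

For a query of q genes in a universe of N, and a set with m members in the
universe sharing k genes with the query, the p-value is the one-sided
hypergeometric tail P(X ≥ k) and fold enrichment is (k/q)/(m/N).
Benjamini-Hochberg adjustment is applied across sets.  The recommended
universe is the set of genes detected in the count matrix — the analysis is
conditioned on detection, so the null should be too — not the union of the
gene sets.  Depletion is out of scope.

## The synthetic-data generator

The generator exists so that every downstream stage has planted ground truth;
it is first-class, tested code.  Defaults mirror a two-genotype adventitia
experiment at desk scale: genotypes `wt` and `apoe_ko`; 6 clusters
(Mesen_I–IV, resident and inflammatory macrophages) × 300 cells each per
genotype; 2,000 genes of which 13 carry the `mt-` prefix; negative-binomial
counts (baseline mean 0.5, dispersion 2.0) with per-(cluster, gene) lognormal
mean multipliers (σ = 0.5) shared across genotypes, so genotype differences
come only from what is planted.  At these parameters a typical cell expresses
≈ 720 genes with mitochondrial share ≈ 0.0065 — comfortably inside every QC
bound, so ordinary cells never trip the filters.  Choosing a much smaller
gene panel pushes ordinary cells toward the 200-gene floor; the defaults are
sized to keep the two regimes separated.

**Planted fractions.** For each (genotype, cluster, gene, f) record, the
gene's counts in those cells are Bernoulli(f)-gated: gated-on cells draw a
zero-truncated NB (always positive), gated-off cells get 0.  The expected
expressing fraction therefore equals f exactly, independent of NB
parameters, and the *realized* gate fraction is recorded in the returned
truth object.  Downstream estimates recount the same cells, so after QC the
estimated fraction equals the realized fraction exactly; the analytic oracle
`planted_expected_score` (sum of products of realized fractions) is
correspondingly exact, while agreement with the *target* fractions is a
binomial-sampling statement checked at 3 SE.  By default the generator
plants Ccl2/Ccl7 in Mesen_II and Ccr2/Il1r2 in inflammatory macrophages with
higher fractions in the knockout — the directed, genotype-dependent motif
the pipeline is meant to detect.

**QC offenders.** Offender cells are appended as extra cells (so they never
perturb the planted fractions of the clean population) and violate exactly
one rule each, by construction: low-gene cells express exactly 50 non-mito
genes; high-gene cells express min(n_genes, 3000) genes, which requires
n_genes ≥ 2501 and errors otherwise; high-mito cells get a mitochondrial
share drawn uniformly in (0.10, 0.30) on top of an otherwise ordinary
profile.  Because the default gene count is 2,000, the high-gene class is off
by default (the other two default to 1% each); tests exercise it with an
explicit 3,000-gene spec.

All randomness descends from one seed through spawned `numpy` SeedSequence
children, so identical specs give byte-identical outputs and individual
stages can be varied independently.

**What the generator does not emulate** — and therefore what passing tests do
not establish about real data: library-size variation beyond NB dispersion,
batch and chemistry effects, ambient RNA, doublets other than the high-gene
caricature, correlated gene programs, or any real ligand-receptor biology.
The tests establish that the *method* is computed correctly and recovers
known truth under its own assumptions, not that the assumptions hold in any
particular tissue.

## Numerical and design choices

- Gene symbols match case-sensitively (mouse symbols are mixed-case;
  silent case-folding can merge distinct genes).  Matrix-market triplet
  input uses 1-based indices on disk, 0-based internally.
- A pair list's first row is a header only when both fields spell
  "ligand"/"receptor" (any case); otherwise it is data.  Exact duplicate
  pairs are dropped with a logged count; self-pairs are legal.
- Counts are validated as non-negative integers at read time; analysis
  outputs are written at full repr precision so read-back is exact.
- Problem sizes in tests and the acceptance script (hundreds of cells per
  cluster, hundreds to a few thousand genes, ≤ 100 fuzzed instances) are
  chosen so the full suite runs in well under a minute while keeping every
  statistical check at ≥ 3-SE resolution.
- The curated pair list used in the original adventitia study (2,174 pairs)
  is not redistributable here; the reader accepts any two-column list, and
  the corresponding check runs only when the user supplies the file.
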