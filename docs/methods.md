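# Methods

## Model and procedure

The analysis treats a differential gene list as a sample drawn without
replacement from the background of genes annotated in a category, and asks
for each term whether the list contains implausibly many of the term's
genes. With category background size `N`, term size `K`, annotated list
size `n` and list∩term hits `k`, the test statistic is the exact
hypergeometric upper tail `P(X ≥ k)` — the one-sided Fisher exact p-value
for over-representation. No normal or chi-square approximation is used at
any count; the tail is computed by `scipy.stats.hypergeom.sf`, which the
test suite verifies against an exhaustive factorial-summation oracle over
every valid quadruple with `N ≤ 60` (agreement within 1e-12; measured
worst deviation ≈ 4e-16).

The nested level conditions on each over-represented parent term. Under
the null that, *given* membership in the parent, list membership is
exchangeable, the parent's gene set becomes the population (`N' = K_parent`),
the within-parent list is the list's intersection with the parent
(`n' = k_parent`), and every other term is re-tested with its gene set
intersected with the parent's. This conditional two-level structure is the
package's core contribution; both levels share one code path
(`build_contingency` → `fisher_upper_tail`), so every nested row satisfies
`List Size = parent List Hits` and `Pop. Size = parent Pop. Hits` by
construction.

### Assumptions

* Gene-level exchangeability under the null within each background;
  correlation between genes (co-expression, linked probesets) is not
  modelled, as in all Fisher-exact ORA.
* Enrichment is tested at the gene level. Probesets are collapsed to genes
  at read time, before any counting, because annotation sources are
  gene-keyed and multiple probesets per gene would otherwise double-count
  evidence.
* Each category keeps its own background (genes with ≥1 annotation in that
  category); a gene unannotated in a category is invisible to it. This is
  why List Size and Pop. Size differ between categories in the outputs.
* Candidate nested terms are all terms overlapping the parent, from any
  category. Ontology parent–child structure is deliberately not assumed:
  empirically useful drivers (e.g. an adhesion term under a proliferation
  term) need not be DAG descendants. A `--descendants-only` mode restricts
  candidates to descendants for users who want DAG-consistent nesting; it
  needs an OBO file.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_hits` | 2 | minimum list hits for a term to be tested; singleton hits carry no over-representation evidence and inflate the testing family |
| `alpha` | 0.05 | BH-corrected threshold declaring a term over-represented, and the gate for parents entering the nested pass |
| `family` | per-category (upper), global (nested) | BH family construction; `global` pools categories at the upper level, `per-parent` corrects each parent's nested family separately |
| `use_ease_score` | off | correct the jackknifed `P(X ≥ k−1)` instead of the plain tail; the plain tail is canonical because the analytically checkable published rows reproduce it exactly and exclude the jackknife |
| signature filter | `max_q = 0`, `min_abs_fold_change = 2`, inclusive | keeps features called at 0% FDR with \|fold change\| ≥ 2; the inclusive/exclusive fold-change comparison is selectable (`strict_inequality`) because both conventions circulate |
| `fold_case` | off | uppercase identifiers before comparison; off by default since identifier case is meaningful in some sources |
| true-path propagation | off | whether annotations should be propagated to ontology ancestors before counting is unknowable from published count tables; the flag exists, the default leaves annotations as given |

p-values are never reported as 0: underflow clamps to the smallest positive
representable value with a logged note. Display rounding is two significant
figures (scientific notation) for p-values and two decimals for enrichment
statistics, matching the conventions of published enrichment tables; the
glyph dialect `a.b×10^−c` is opt-in (`--table-glyphs`), ASCII e-notation is
the default.

### Derived statistics

* `gene_enrich = k − nK/N` (observed minus expected hits).
* `pct_gene_enrich = 100 · gene_enrich / K` (never exceeds 100 since `k ≤ K`).
* `pvalue_log_diff = |log10(p_full) − log10(p_nested)|`, where `p_full` is
  the same nested term's Fisher tail against its full category background.
  This is a **candidate interpretation**: the published legend ("p-value
  log difference between the same nested and upper-level terms") does not
  determine the formula, and the printed values cannot be reconstructed
  from other printed quantities to adjudicate. Output headers flag it.
* `nease_gene_enrich = gene_enrich · (parent_gene_enrich /
  parent_expected_hits)` — likewise a flagged candidate interpretation
  (the legend's "enriched gene value based on the same upper-level Gene
  Enrich value" is not a formula); it is excluded from any numerical
  verification for the same reason.

## Synthetic data generator

`nease.synthetic` emulates the study conditions at the summary level the
pipeline consumes: a universe of `n_terms` overlapping term sets drawn
independently and uniformly within a size range over `n_genes` genes
(independent draws mirror real GO's overlapping, non-partition structure);
a differential list sampled without replacement with per-gene weights equal
to the product of planted odds ratios (so odds ratio 1 is exactly the null);
nested plants that force child∩parent overlap of at least
min(|child|, |parent|/2) and up-weight those overlap genes specifically; and
a SAM-style table in which planted rows get q = 0 and |fold change| at or
above a boundary ≥ 2, nulls get |fold change| < 2 and q > 0. Defaults
(1000 genes, 50 terms of 20–60 genes, list 150) are sized like a
single-category slice of a microarray ORA. Size ranges need slack
(`hi > lo`) when coverage of all genes is required, because unannotated
genes are folded into terms with spare capacity; plant-involved terms are
never altered by this fold-in.

What the generator does **not** emulate: expression matrices, probeset
noise, inter-gene correlation, and the ontology DAG. Passing recovery tests
therefore demonstrate statistical correctness of the two-level procedure
under exchangeable sampling, not robustness to correlated real
transcriptomes.

## Numerical and design choices

* BH adjustment delegates to `statsmodels` (`fdr_bh`) and is cross-checked
  in tests against an independent hand-rolled step-up oracle; adjusted
  values are permutation-equivariant and never below the raw p.
* Ties and ordering: results sort by corrected p, then raw p, then category
  and accession, making output order deterministic under ties.
* Degenerate inputs error early and specifically: empty gene lists, lists
  disjoint from a background, unknown terms, malformed annotation lines
  (with line number), signature filters that eliminate every row.
* A single integer seed drives all generator randomness through
  per-stage `numpy` SeedSequence streams; the seed and a spec digest are
  embedded in every fixture file's metadata line.
* Null calibration: exact discrete tests are conservative, so raw p-values
  under the null are stochastically ≥ uniform rather than exactly uniform.
  The calibration tests assert that one-sided property (rejection fraction
  at 0.05 bounded above, empirical CDF below the diagonal up to a one-sided
  KS allowance); simulation sizes in those tests use large terms so the
  discrete support is fine enough for the bound to be informative.

## Known limitations

* Exactly two levels; no nested-within-nested iteration.
* Over-representation only; no depletion or two-sided testing.
* The two candidate-interpretation columns above are reported for
  completeness but should not be compared across tools.
* Upper-level corrected p-values depend on the full tested family, so they
  are checked property-wise (bounds, monotonicity, oracle equality of the
  procedure) rather than against any published corrected column, whose
  family is not fully printed.
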