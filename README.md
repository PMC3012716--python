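# nease — nested gene-ontology over-representation analysis

`nease` asks two questions about a differential gene list. First, the
classical over-representation question: which annotation terms (GO
biological process, molecular function, cellular component, or any gene-set
collection) contain more of the list's genes than chance predicts? Second,
the nested question that standard ORA cannot answer: *which sub-terms drive
each of those enrichments?* A broad term such as *cell proliferation* may be
significant only because its *cell adhesion* genes are perturbed; `nease`
finds this by re-running the analysis inside each enriched term.

It is aimed at transcriptomics analysts (bulk or single-cell) who have a
gene list or a differential-expression result table and a gene→term
annotation source (GAF 2.x, GMT, or a two-column TSV).

## The statistics

For a term with `K` annotated genes in a background of `N` annotated genes,
and a list of `n` annotated genes containing `k` term members, the
upper-level p-value is the one-sided Fisher exact (hypergeometric upper
tail) probability

    p = P(X ≥ k),   X ~ Hypergeometric(N, K, n),

computed exactly. Families of term tests are corrected by Benjamini–Hochberg
FDR. The jackknifed "EASE score" variant, `P(X ≥ k−1)`, is available behind
`--ease-score` for users who want its conservatism, but the reported
statistic is the plain tail.

The nested pass conditions on each over-represented parent term: the
parent's `K` genes become the new population, the list shrinks to its `k`
genes inside the parent, and every other term — from any category, not only
ontology descendants — is re-tested against that restricted background
(`--descendants-only` restricts candidates to DAG descendants if you supply
`--obo`). So for every nested row, List Size equals the parent's List Hits
and Pop. Size equals the parent's Pop. Hits.

Derived per-row statistics:

* **Gene Enrich** `= k − nK/N`, the observed hits above expectation;
* **% Gene Enrich** `= 100 · GeneEnrich / K`;
* **nEASE pvalue Diff** and **nEASE Gene Enrich** — candidate
  interpretations (|log10 ratio| of the within-parent vs full-background
  p-value, and the nested enrichment scaled by the parent's relative
  enrichment); they are flagged as such in every output header.

## Worked example

Generate a synthetic study with a planted enrichment (*proliferation*, odds
ratio 6) and a planted within-parent driver (*adhesion* enriched with odds
ratio 10 specifically inside *proliferation*), then run the two-level
analysis:

```sh
nease synth --n-genes 1000 --n-terms 40 --term-size 30 80 \
  --plant proliferation:6 --nest proliferation:adhesion:10 \
  --list-size 150 --seed 42 --out fixtures

nease nease --annotations fixtures/universe.gmt --format gmt \
  --genes fixtures/genes.txt --out results
```

`results/ease.tsv` (top rows):

```
Accession Type  Accession Number  Accession Term  List Hits  List Size  Pop. Hits  Pop. Size  Fisher's Exact  Corrected P Value
gene sets       proliferation     proliferation   26         150        34         1000       3.3e-16         1.3e-14
gene sets       adhesion          adhesion        21         150        69         1000       5.5e-04         1.1e-02
```

Of the 150 list genes, 26 fall in the 34-gene *proliferation* term where
150·34/1000 ≈ 5.1 were expected — hence the vanishing p-value. Both planted
terms are the only ones surviving BH correction at α = 0.05.

`results/nease.tsv` (top rows):

```
nEASE Term  List Hits  List Size  Pop. Hits  Pop. Size  Fisher's Exact  Gene Enrich  nEASE pvalue Diff  nEASE Gene Enrich  % Gene Enrich  EASE Term
adhesion    17         26         17         34         1.3e-03         4.00         0.39               16.39              23.53          proliferation
```

Read: within the *proliferation* parent (population = its 34 genes, list =
its 26 differential genes), 17 of the 17 *adhesion*-overlap genes are in
the list — 4.00 genes more than expected within the parent (p = 1.3e-3).
The planted driver is recovered. Note how the nested row's List Size (26)
and Pop. Size (34) are the parent's List Hits and Pop. Hits.

The same analyses are available as library calls (`run_ease`, `run_nease`,
`derive_signature`, …); `nease ease --de-table de.tsv --max-q 0 --min-fc 2`
first reduces a differential table to the signature of features with
q-value 0 and |fold change| ≥ 2.

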