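# gw2drug

Offline pipeline for genomics-driven drug repurposing in multiple myeloma
(MM), a plasma-cell malignancy whose GWAS-catalog risk loci are rarely
translated into treatment leads. Starting from flat-file snapshots of the
databases a desk analysis would query (GWAS catalog, a HaploReg-style LD
table, cis-eQTL, GO, the IUIS primary-immunodeficiency list, STRING,
DrugBank, ClinicalTrials.gov), the package turns lead association signals
into triaged drug candidates:

1. **select** — keep variants at genome-wide significance (p < 10⁻⁸,
   strict), one record per rsID (minimum p);
2. **expand-ld** — widen each lead SNP to its linkage-disequilibrium
   proxies (r² > 0.80, one reference-panel population, default the 1000
   Genomes Phase 1 Asian panel) and collect the genes the proxies fall in;
3. **score** — award each candidate gene one point per criterion met, out
   of six: a missense proxy, a significant whole-blood cis-eQTL, membership
   in an enriched GO biological-process / cellular-component /
   molecular-function term (upper-tail hypergeometric p < 0.05 against a
   20,000-gene background), and presence on the PID gene list. Genes with a
   total of ≥ 2 are called biological risk genes;
4. **expand-ppi** — widen the risk set by one hop across STRING-style
   protein–protein interaction edges with combined score ≥ 400;
5. **map-drugs** — intersect the expanded genes with a drug–target table
   and triage every hit against the disease:
   `approved_for_disease` > `in_trial` (evidenced by NCT registry ids) >
   `novel`.

The enrichment statistic is the hypergeometric upper tail
P(X ≥ k) = Σᵢ₌ₖ C(K,i)·C(N−K,n−i)/C(N,n) for k of n sampled genes landing
in a term of size K within a background of N, summed in log space.

Everything runs from local files; there are no network calls. A synthetic
fixture generator (`gw2drug make-fixtures`) produces complete input
bundles with a planted-truth manifest, so the whole pipeline is testable
end to end, and the published 14-gene scoring matrix and drug-evidence
tables ship as fixtures.

## Worked example

Generate a synthetic bundle at study scale (72 significant lead SNPs over
63 genes) and run the full pipeline:

```bash
$ gw2drug make-fixtures --seed 7 --out demo/bundle
$ gw2drug run --bundle-dir demo/bundle --out-dir demo/out
associations_in: 123
significant_snps: 72
ld_proxies: 456
candidate_genes: 63
risk_genes: 8
expanded_genes: 14
ppi_pairs: 16
drug_candidates: 10
bipartite_edges: 17
approved_for_disease: 1
in_trial: 4
novel: 5
```

Of 123 association rows, 72 unique lead SNPs pass genome-wide
significance; their LD blocks cover 63 genes, of which 8 score ≥ 2 on the
six annotation criteria. One PPI hop brings the druggable pool to 14
genes, targeted by 10 drugs — one already approved for the disease, four
in registered clinical trials, five novel. `demo/out/` then contains the
scores table (`gene_scores.tsv`, in the published column layout), the
candidate table with evidence ids, the bipartite drug–gene network
(`drug_gene_network.tsv`), and a JSON+text run report:

```
$ head -3 demo/out/drug_candidates.tsv
drug_id  drug_name  status                pharm_action_any  target_genes     evidence
DB90001  cmpd001    approved_for_disease  1                 MMG001,MMG018    APPR001
DB90002  cmpd002    in_trial              0                 NBR005           NCT90000001
```

Because the bundle carries a planted-truth manifest, this run is also a
check: the recovered risk genes, flag matrix and drug statuses equal the
manifest exactly.

The same steps are available as library calls (`gw2drug.run_pipeline`,
or the per-stage functions in `variant_selection`, `ld_expansion`,
`annotation_scoring`, `network_expansion`, `drug_mapping`) and as
per-stage subcommands (`gw2drug select|expand-ld|score|expand-ppi|map-drugs`).

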