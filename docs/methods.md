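# Methods

## Scope and model of the analysis

gw2drug implements a deterministic filter–score–join analysis, not a
fitted statistical model: every stage is a set operation or a count, and a
run is fully determined by its inputs and configuration. The underlying
assumption chain is the standard genomics-driven repurposing argument:
variants robustly associated with the disease tag genes (directly or
through linkage disequilibrium); genes supported by several independent
functional annotations are more plausible effectors; and drugs already
targeting those effectors (or their direct interaction partners) are
candidates for repurposing. The pipeline makes that argument auditable by
fixing each step's rule and threshold explicitly.

All joins are identifier-based (rsID or gene id). Coordinates are carried
1-based as in dbSNP/GWAS-catalog exports but never used arithmetically, so
strand and interval conventions cannot introduce errors. Gene identity is
canonicalized to the GENCODE/Ensembl stable id; symbol-keyed tables (PID
list, PPI edges, drug targets) are matched case-insensitively through a
symbol-to-id map supplied with the inputs.

## Stage rules and the parameters that matter

| parameter | default | meaning |
|---|---|---|
| `p_threshold` | 1e-8 | genome-wide significance; **strict** `<` at the boundary |
| `r2_threshold` | 0.80 | LD proxy inclusion; **strict** `>` at the boundary |
| `population` | `ASN` | reference-panel label the LD table is filtered to |
| `alpha` | 0.05 | raw enrichment significance for GO flags |
| `background_n` | 20,000 | protein-coding background for the hypergeometric test |
| `risk_threshold` | 2 | minimum annotation total for a risk-gene call |
| `ppi_min_score` | 400 | STRING combined-score cutoff ("medium confidence") |
| `condition` | `multiple myeloma` | substring matched in approval/registry rows |

Both boundary inequalities are strict because the selection criteria are
stated as strict inequalities; a non-strict mode exists for sensitivity
runs (`strict=False` keeps `<=`). Duplicate rsIDs across studies keep the
minimum p-value — the strongest evidence per locus — and dedupe order is
fixed (ascending p, then rsID) so reruns are reproducible. Every seed SNP
is retained as its own proxy (r² = 1), synthesized when the LD table lacks
it, so a lead SNP can never silently vanish between stages.

### Annotation flags

A gene's six flags are binary by design — the published scoring awards one
point per criterion regardless of effect size:

* **missense** — some r²-passing proxy in the gene is annotated
  `missense`;
* **cis-eQTL** — some proxy has a *significant* whole-blood cis-eQTL
  record for the gene. Significance is taken from a yes/no column
  pre-thresholded upstream, since the input snapshot is assumed already
  filtered; swapping in a numeric FDR column is a one-line reader change;
* **GO BP/CC/MF** — the gene belongs to ≥ 1 term of the category enriched
  at raw p < alpha in the candidate set. Enrichment is computed once over
  the whole candidate set, per term, with the query size n equal to the
  candidate-set size. No multiple-testing correction is applied by
  default, matching chart-report practice for annotation screens; no GO
  is-a propagation is performed — membership tables are taken as given;
* **PID** — symbol or id membership in the immunodeficiency list,
  case-insensitive.

Ranking is by descending total, ties broken by ascending GENCODE id.
That tie-break reproduces the published scoring table's row order exactly
(the score-2 block of that table is in ascending id order, which a
flag-priority tie-break would not reproduce).

### Hypergeometric tail

`hypergeometric_tail(k, K, n, N)` returns P(X ≥ k) for X hypergeometric:
k successes among n draws from N objects of which K are successes. It is
authored here rather than delegated so its contract is explicit: log-gamma
binomial coefficients, max-shifted log-sum-exp, exact empty/whole-support
short-circuits. The acceptance suite verifies ≤ 1e-12 relative error
against exact rational enumeration for every parameter combination with
N ≤ 60, and a randomized cross-check agrees with `scipy.stats.hypergeom.sf`
at N ≤ 1000. scipy is used only as the independent oracle, never as the
implementation.

### Network expansion and drug triage

PPI expansion is a single hop: edges with combined score ≥ `ppi_min_score`
incident to ≥ 1 risk gene are retained and their far endpoints join the
pool. No clustering, centrality or transitive closure — the repurposing
argument only licenses direct interactors. Edge endpoints that cannot be
bridged to a gene id are dropped and counted.

Drug status is a total, mutually exclusive partition with precedence
approved > in-trial > novel. Name matching lower-cases, trims, and strips
trailing salt/ester tokens (`sodium`, `hydrochloride`, ...), because
registry spellings vary; condition matching is a case-insensitive
substring test. Pharmacological-action annotations are carried through as
a flag rather than used as a filter by default (a strict mode restricts to
action-confirmed links), since target lists mix mechanistic and binding
evidence. Literature-based preclinical triage is out of scope: the
registry table is the sole in-trial oracle.

## Synthetic bundles and what they do (not) show

The generator emulates the *structure* of the real inputs with planted
truth: each significant lead SNP anchors an abstract LD block mapping to
one gene; per-gene flags are drawn Bernoulli at the published per-criterion
prevalences (11 missense, 19 cis-eQTL, 4 BP, 11 CC, 5 MF, 2 PID out of
63); decoys are planted on the wrong side of every rule (boundary-adjacent
r², wrong-population proxies, wrong-tissue and non-significant eQTL rows,
sub-threshold PPI edges, unmappable endpoints, wrong-condition trials,
salt-suffixed registry names). Default sizes mirror the published
analysis: 72 significant lead SNPs among 120 catalog rows and 63 candidate
genes.

Two constructions need care:

* *Enriched GO terms* consist entirely of candidate genes (K = k ≤ 3),
  which is always significant for candidate sets far smaller than the
  background (p ≤ n/N per member).
* *Decoy terms* hold exactly one candidate gene diluted with background
  members. P(X ≥ 1) ≈ 1 − (1 − K/N)ⁿ **falls** as the candidate set
  shrinks, so a fixed decoy size would become spuriously enriched for
  small n; the decoy size is therefore solved at generation time so the
  single-overlap tail probability sits near 4·alpha (floored at 2·alpha).

After construction the generator replays the full pipeline in memory and
requires the realized truth to equal the manifest, reseeding (bounded, and
deterministically derived from the config seed) on the rare inconsistent
draw. Significant p-values are drawn log-uniform on (10⁻³⁰, 10⁻⁹) and
non-significant ones uniform on (10⁻⁷, 1), keeping a clean margin around
the 10⁻⁸ boundary; boundary-exact behaviour is exercised by dedicated
tests instead.

Passing on these bundles demonstrates that every rule, join and threshold
is implemented correctly and deterministically. It does **not**
demonstrate robustness to the pathologies of real snapshots — realistic
LD correlation structure, multi-gene proxy annotations, symbol aliasing
and retired rsIDs, or GO term overlap — and headline counts from real
database snapshots (how many SNPs, genes, pairs or drugs survive each
stage) depend on database versions and are not reproducible from
fixtures. The published 14 × 6 scoring matrix and the drug-evidence
tables are the two points where the pipeline is checked against printed
values; the drug fixture's target assignments for the four never-trialed
drugs are synthetic (the source figure is not machine-readable), which
has no effect on status triage.

## Numerical and degenerate-input choices

* Empty association input (or zero significant SNPs) is a valid run: every
  stage returns empty output, the report carries zero counts, and the exit
  is success with a warning.
* Symmetric duplicate PPI edges collapse keeping the maximum score;
  self-loops are removed with a logged count.
* An unclassified drug candidate reaching the partition is a fatal error,
  not a silent fourth category.
* Thresholds validate their documented domains at construction
  (`p_threshold` ∈ (0,1], `r2_threshold` ∈ [0,1], scores ∈ [0,1000], risk
  threshold ≥ 0 with values above 6 returning the empty set).
* All randomness flows from one seeded `numpy` generator per bundle; there
  is no global random state, and identical (inputs, config) produce
  byte-identical outputs and reports.

## Problem sizes used by the shipped checks

The test suite and acceptance script run at deliberately small scales
chosen to exercise every rule: the study-scale default bundle (120
catalog rows / 63 genes), a 30-SNP/12-gene bundle for pipeline-level
tests, 20 random generator configs (5–25 genes) for planted-truth
recovery, and the exhaustive hypergeometric sweep at N ≤ 60 with a
randomized N ≤ 1000 cross-check.

## Known limitations

* One gene per LD-proxy row; multi-gene annotations must be pre-split by
  the reader.
* No LD computation from genotypes, no proxy windowing around the lead
  SNP, no locus clumping or conditional analysis.
* GO flags use raw per-term p-values (Benjamini–Hochberg is available as
  an option upstream of the flag rule but off by default) and ignore the
  GO graph.
* DrugBank is consumed as a CSV projection; XML parsing is out of scope.
* The approved/in-trial evidence is only as complete as the supplied
  approval and registry snapshots.
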