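"""Synthetic fixture bundles with planted ground truth, plus in-paper fixtures.

:func:`generate_bundle` emits a complete, internally consistent set of
input tables — GWAS associations, LD proxies, cis-eQTL, GO membership, PID
list, symbol map, PPI edges, drug targets, approvals, trial registry —
together with a manifest of the planted truth (significant SNPs, flag
matrix, risk genes, expanded genes, drug statuses).  Replaying the full
pipeline on the bundle at the generator's thresholds reproduces the
manifest exactly; the generator verifies this by replay and reseeds on the
rare infeasible draw rather than failing silently.

Default sizes mirror the published analysis: 72 genome-wide-significant
lead SNPs among 120 catalog rows, 63 candidate genes, and per-criterion
flag prevalences matching the published annotation counts (11 missense, 19
cis-eQTL, 4 BP, 11 CC, 5 MF, 2 PID out of 63).

LD blocks are abstract — no attempt is made to simulate population-genetic
LD structure; each significant lead SNP anchors one block of proxies
mapping to one gene.

:func:`table1_fixture` and :func:`paper_drug_fixture` encode the published
worked examples (the 14 x 6 risk-gene flag matrix and the drug-evidence
tables) for reproduction tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_scoring as scoring
from . import drug_mapping, ld_expansion, network_expansion, variant_selection
from .io_formats import (
    DrugTargetLink,
    LinkedVariant,
    PPIEdge,
    TrialRecord,
    VariantAssociation,
    write_associations,
    write_linked_variants,
    write_ppi_edges,
)
from .ld_expansion import GeneRecord

logger = logging.getLogger(__name__)

_BENIGN_CONSEQUENCES = ("intronic", "intergenic", "synonymous", "utr3")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic bundle generator.

    The defaults are the study conditions: 120 catalog rows of which 60%
    are genome-wide significant (72 lead SNPs), 63 candidate genes, and
    flag prevalences equal to the published per-criterion counts.
    """

    n_snps: int = 120
    fraction_significant: float = 0.6
    n_genes: int = 63
    mean_block_size: float = 5.0  # above-threshold proxies per lead SNP
    n_below_threshold_proxies: int = 2  # per lead SNP, r² under the cutoff
    r2_threshold: float = 0.80
    population: str = "ASN"
    p_threshold: float = 1e-8
    flag_prevalence: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 11 / 63,
            "cis_eqtl": 19 / 63,
            "go_bp": 4 / 63,
            "go_cc": 11 / 63,
            "go_mf": 5 / 63,
            "pid": 2 / 63,
        }
    )
    n_decoy_terms_per_category: int = 2
    decoy_term_size: int = 40
    background_n: int = 20_000
    alpha: float = 0.05
    risk_threshold: int = 2
    n_neighbor_genes: int = 8
    mean_neighbor_degree: float = 1.5  # high-confidence partners per risk gene
    ppi_min_score: int = 400
    n_hit_drugs: int = 10
    n_drugs_approved: int = 1
    n_drugs_in_trial: int = 4
    target_pool_size: int = 3  # expanded genes shared by the hit drugs
    n_decoy_drugs: int = 2
    condition: str = "multiple myeloma"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_significant", "alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name, v in self.flag_prevalence.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"flag_prevalence[{name!r}] must be in [0,1], got {v}")
        n_sig = round(self.n_snps * self.fraction_significant)
        if 0 < n_sig < self.n_genes:
            raise ValueError(
                f"infeasible config: {self.n_genes} genes need >= {self.n_genes} "
                f"significant lead SNPs, got {n_sig}"
            )
        if self.n_drugs_approved + self.n_drugs_in_trial > self.n_hit_drugs:
            raise ValueError("infeasible config: planted statuses exceed n_hit_drugs")


@dataclass
class FixtureBundle:
    """All synthetic input tables plus the planted-truth manifest."""

    config: GeneratorConfig
    associations: list[VariantAssociation]
    ld_table: list[LinkedVariant]
    eqtl_table: pd.DataFrame
    go_membership: pd.DataFrame
    pid_list: set[str]
    symbol_map: dict[str, str]  # UPPER symbol -> gencode id
    ppi_edges: list[PPIEdge]
    drug_targets: list[DrugTargetLink]
    approvals: pd.DataFrame
    trials: list[TrialRecord]
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every table in its io_formats dialect; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "associations": out / "associations.tsv",
            "ld_proxies": out / "ld_proxies.tsv",
            "eqtl": out / "eqtl.tsv",
            "go_membership": out / "go_membership.tsv",
            "pid_list": out / "pid_genes.txt",
            "symbol_map": out / "symbol_map.tsv",
            "ppi_edges": out / "ppi_edges.txt",
            "drug_targets": out / "drug_targets.csv",
            "approvals": out / "approvals.tsv",
            "trials": out / "trials.tsv",
            "manifest": out / "manifest.json",
        }
        write_associations(self.associations, paths["associations"])
        write_linked_variants(self.ld_table, paths["ld_proxies"])
        self.eqtl_table.to_csv(paths["eqtl"], sep="\t", index=False)
        self.go_membership.to_csv(paths["go_membership"], sep="\t", index=False)
        with open(paths["pid_list"], "w") as fh:
            for s in sorted(self.pid_list):
                fh.write(s + "\n")
        sym_df = pd.DataFrame(
            sorted(self.symbol_map.items()), columns=["gene_symbol", "gencode_id"]
        )
        sym_df.to_csv(paths["symbol_map"], sep="\t", index=False)
        write_ppi_edges(self.ppi_edges, paths["ppi_edges"])
        pd.DataFrame(
            [
                {
                    "drug_id": t.drug_id,
                    "drug_name": t.drug_name,
                    "target_gene": t.target_gene,
                    "pharmacological_action": t.pharmacological_action,
                    "groups": "|".join(sorted(t.groups)),
                }
                for t in self.drug_targets
            ],
            columns=["drug_id", "drug_name", "target_gene",
                     "pharmacological_action", "groups"],
        ).to_csv(paths["drug_targets"], index=False)
        self.approvals.to_csv(paths["approvals"], sep="\t", index=False)
        pd.DataFrame(
            [
                {"nct_id": t.nct_id, "drug_name": t.drug_name,
                 "condition": t.condition, "status": t.status}
                for t in self.trials
            ],
            columns=["nct_id", "drug_name", "condition", "status"],
        ).to_csv(paths["trials"], sep="\t", index=False)
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_flags(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    """n_genes x 6 binary matrix, one Bernoulli column per criterion."""
    cols = []
    for name in scoring.FLAG_ORDER:
        p = config.flag_prevalence.get(name, 0.0)
        cols.append((rng.random(config.n_genes) < p).astype(int))
    return np.column_stack(cols)


def _generate_once(config: GeneratorConfig, seed: int) -> FixtureBundle:
    rng = np.random.default_rng(seed)
    n_sig = round(config.n_snps * config.fraction_significant)
    n_genes = config.n_genes if n_sig > 0 else 0

    # --- genes: candidates, PPI neighbors, decoy drug targets -------------
    n_extra = config.n_neighbor_genes + 5
    id_nums = rng.choice(10**9, size=config.n_genes + n_extra, replace=False)
    all_ids = [f"ENSG{num:011d}" for num in id_nums]
    genes = [
        GeneRecord(gencode_id=all_ids[i], gene_symbol=f"MMG{i + 1:03d}")
        for i in range(config.n_genes)
    ]
    neighbor_genes = [
        GeneRecord(
            gencode_id=all_ids[config.n_genes + i], gene_symbol=f"NBR{i + 1:03d}"
        )
        for i in range(config.n_neighbor_genes)
    ]
    decoy_genes = [
        GeneRecord(
            gencode_id=all_ids[config.n_genes + config.n_neighbor_genes + i],
            gene_symbol=f"DCY{i + 1:03d}",
        )
        for i in range(5)
    ]
    symbol_map = {
        g.gene_symbol.upper(): g.gencode_id
        for g in genes + neighbor_genes + decoy_genes
    }
    candidate_genes = genes[:n_genes]

    # --- flags and risk calls --------------------------------------------
    flag_matrix = _draw_flags(rng, config)[: len(candidate_genes)]
    flags = {
        g.gencode_id: scoring.AnnotationFlags(**dict(zip(scoring.FLAG_ORDER, row)))
        for g, row in zip(candidate_genes, flag_matrix.tolist())
    }
    risk_genes = [
        g for g in candidate_genes
        if flags[g.gencode_id].total >= config.risk_threshold
    ]
    risk_ids = {g.gencode_id for g in risk_genes}

    # --- lead SNPs and association table ---------------------------------
    rs_nums = rng.choice(10**8, size=config.n_snps, replace=False)
    rsids = [f"rs{num}" for num in rs_nums]
    sig_rsids, nonsig_rsids = rsids[:n_sig], rsids[n_sig:]
    sig_p = 10.0 ** rng.uniform(-30, -9, size=n_sig)
    nonsig_p = rng.uniform(1e-7, 1.0, size=config.n_snps - n_sig)
    # every candidate gene is anchored by >= 1 significant lead SNP
    seed_gene: dict[str, GeneRecord] = {}
    for i, rs in enumerate(sig_rsids):
        if i < len(candidate_genes):
            seed_gene[rs] = candidate_genes[i]
        else:
            seed_gene[rs] = candidate_genes[rng.integers(len(candidate_genes))]
    associations = []
    for rs, p in zip(sig_rsids, sig_p):
        associations.append(
            VariantAssociation(
                rsid=rs,
                chromosome=str(rng.integers(1, 23)),
                position=int(rng.integers(1, 2 * 10**8)),
                p_value=float(p),
                mapped_genes=(seed_gene[rs].gene_symbol,),
                study_id=f"GCST{rng.integers(10**6):06d}",
            )
        )
    for rs, p in zip(nonsig_rsids, nonsig_p):
        associations.append(
            VariantAssociation(
                rsid=rs,
                chromosome=str(rng.integers(1, 23)),
                position=int(rng.integers(1, 2 * 10**8)),
                p_value=float(p),
                mapped_genes=(),
                study_id=f"GCST{rng.integers(10**6):06d}",
            )
        )
    # duplicate reports of a few loci at weaker p — collapsed by dedup
    for rs in sig_rsids[: min(3, n_sig)]:
        orig = next(a for a in associations if a.rsid == rs)
        associations.append(
            dataclasses.replace(
                orig, p_value=min(1.0, orig.p_value * 10), study_id="GCSTDUP01"
            )
        )
    order = rng.permutation(len(associations))
    associations = [associations[i] for i in order]

    # --- LD proxy table ---------------------------------------------------
    proxy_counter = 0

    def fresh_rs() -> str:
        nonlocal proxy_counter
        proxy_counter += 1
        return f"rs9{proxy_counter:07d}"

    missense_planted: set[str] = set()
    gene_proxy_rsids: dict[str, list[str]] = {g.gencode_id: [] for g in candidate_genes}
    ld_rows: list[LinkedVariant] = []
    for rs in sig_rsids:
        g = seed_gene[rs]
        ld_rows.append(
            LinkedVariant(
                query_rsid=rs, proxy_rsid=rs, r_squared=1.0,
                population=config.population, gencode_id=g.gencode_id,
                gene_symbol=g.gene_symbol,
                consequence=str(rng.choice(_BENIGN_CONSEQUENCES)),
            )
        )
        gene_proxy_rsids[g.gencode_id].append(rs)
        n_above = 1 + rng.poisson(max(config.mean_block_size - 1.0, 0.0))
        for _ in range(n_above):
            prs = fresh_rs()
            wants_missense = (
                flags[g.gencode_id].missense == 1
                and g.gencode_id not in missense_planted
            )
            empty_gene = (not wants_missense) and rng.random() < 0.1
            if wants_missense:
                missense_planted.add(g.gencode_id)
            ld_rows.append(
                LinkedVariant(
                    query_rsid=rs,
                    proxy_rsid=prs,
                    r_squared=float(rng.uniform(0.81, 0.999)),
                    population=config.population,
                    gencode_id="" if empty_gene else g.gencode_id,
                    gene_symbol="" if empty_gene else g.gene_symbol,
                    consequence="missense" if wants_missense
                    else str(rng.choice(_BENIGN_CONSEQUENCES)),
                )
            )
            if not empty_gene:
                gene_proxy_rsids[g.gencode_id].append(prs)
        for _ in range(config.n_below_threshold_proxies):
            # sub-threshold decoys, occasionally missense: must never flag
            ld_rows.append(
                LinkedVariant(
                    query_rsid=rs,
                    proxy_rsid=fresh_rs(),
                    r_squared=float(rng.uniform(0.2, 0.79)),
                    population=config.population,
                    gencode_id=g.gencode_id,
                    gene_symbol=g.gene_symbol,
                    consequence="missense" if rng.random() < 0.3
                    else str(rng.choice(_BENIGN_CONSEQUENCES)),
                )
            )
        # strong proxy in another panel: excluded by the population filter
        ld_rows.append(
            LinkedVariant(
                query_rsid=rs, proxy_rsid=fresh_rs(), r_squared=0.95,
                population="EUR", gencode_id=g.gencode_id,
                gene_symbol=g.gene_symbol, consequence="missense",
            )
        )
    # a missense-flagged gene whose block drew zero above-threshold proxies
    # still needs its planted missense variant: force one onto the seed block
    for g in candidate_genes:
        if flags[g.gencode_id].missense == 1 and g.gencode_id not in missense_planted:
            anchor = next(rs for rs in sig_rsids if seed_gene[rs] is g)
            prs = fresh_rs()
            ld_rows.append(
                LinkedVariant(
                    query_rsid=anchor, proxy_rsid=prs, r_squared=0.9,
                    population=config.population, gencode_id=g.gencode_id,
                    gene_symbol=g.gene_symbol, consequence="missense",
                )
            )
            gene_proxy_rsids[g.gencode_id].append(prs)
            missense_planted.add(g.gencode_id)

    # --- cis-eQTL table ---------------------------------------------------
    eqtl_rows = []
    for g in candidate_genes:
        if flags[g.gencode_id].cis_eqtl == 1:
            rs = gene_proxy_rsids[g.gencode_id][
                rng.integers(len(gene_proxy_rsids[g.gencode_id]))
            ]
            eqtl_rows.append(
                {"rsid": rs, "gencode_id": g.gencode_id,
                 "tissue": "Whole_Blood", "significant": "yes"}
            )
        else:
            r = rng.random()
            if r < 0.2:  # significant, but wrong tissue
                rs = gene_proxy_rsids[g.gencode_id][0]
                eqtl_rows.append(
                    {"rsid": rs, "gencode_id": g.gencode_id,
                     "tissue": "Liver", "significant": "yes"}
                )
            elif r < 0.4:  # right tissue, not significant
                rs = gene_proxy_rsids[g.gencode_id][0]
                eqtl_rows.append(
                    {"rsid": rs, "gencode_id": g.gencode_id,
                     "tissue": "Whole_Blood", "significant": "no"}
                )
            elif r < 0.5:  # right tissue and significant, but not via a proxy
                eqtl_rows.append(
                    {"rsid": fresh_rs(), "gencode_id": g.gencode_id,
                     "tissue": "Whole_Blood", "significant": "yes"}
                )
    eqtl_table = pd.DataFrame(
        eqtl_rows, columns=["rsid", "gencode_id", "tissue", "significant"]
    )

    # --- GO membership ----------------------------------------------------
    go_rows = []
    filler_counter = 0

    def filler_gene() -> str:
        nonlocal filler_counter
        filler_counter += 1
        return f"ENSG{80000000000 + filler_counter}"

    # Decoy terms contain exactly one candidate gene diluted by background
    # members.  P(X >= 1) falls with the query size n, so the decoy size must
    # grow as the candidate set shrinks to keep the term non-enriched:
    # pick K with P(X >= 1 | K, n, N) around 4*alpha, floored at 2*alpha.
    n_query = len(candidate_genes)
    if n_query:
        target_p = min(1.0, 4 * config.alpha)
        decoy_k = max(
            config.decoy_term_size,
            int(np.ceil(config.background_n
                        * (1.0 - (1.0 - target_p) ** (1.0 / n_query)))),
        )
        while (
            scoring.hypergeometric_tail(1, decoy_k, n_query, config.background_n)
            < 2 * config.alpha
        ):
            decoy_k = int(decoy_k * 1.5) + 1
    else:
        decoy_k = config.decoy_term_size
    for cat, flag_name in zip(scoring.GO_CATEGORIES, ("go_bp", "go_cc", "go_mf")):
        flagged = [
            g for g in candidate_genes
            if getattr(flags[g.gencode_id], flag_name) == 1
        ]
        unflagged = [
            g for g in candidate_genes
            if getattr(flags[g.gencode_id], flag_name) == 0
        ]
        term_i = 0
        # enriched terms: small, all members inside the candidate set
        for start in range(0, len(flagged), 3):
            term_i += 1
            for g in flagged[start:start + 3]:
                go_rows.append(
                    {"term_id": f"GO:{cat}{term_i:05d}", "category": cat,
                     "gencode_id": g.gencode_id}
                )
        for d in range(config.n_decoy_terms_per_category):
            if d >= len(unflagged):
                break
            term_i += 1
            tid = f"GO:{cat}{term_i:05d}"
            go_rows.append(
                {"term_id": tid, "category": cat,
                 "gencode_id": unflagged[d].gencode_id}
            )
            for _ in range(decoy_k - 1):
                go_rows.append(
                    {"term_id": tid, "category": cat, "gencode_id": filler_gene()}
                )
    go_membership = pd.DataFrame(
        go_rows, columns=["term_id", "category", "gencode_id"]
    )

    # --- PID list ---------------------------------------------------------
    pid_list = {
        g.gene_symbol for g in candidate_genes if flags[g.gencode_id].pid == 1
    }
    pid_list |= {f"PIDF{i + 1:02d}" for i in range(15)}

    # --- PPI edges --------------------------------------------------------
    ppi_edges: list[PPIEdge] = []
    expanded_ids = set(risk_ids)
    expanded_symbols = {g.gene_symbol for g in risk_genes}
    neighbor_attached: set[str] = set()
    for g in risk_genes:
        k = 1 + rng.poisson(max(config.mean_neighbor_degree - 1.0, 0.0))
        partners = rng.choice(
            len(neighbor_genes), size=min(k, len(neighbor_genes)), replace=False
        )
        for j in partners:
            nb = neighbor_genes[j]
            ppi_edges.append(
                PPIEdge(
                    g.gene_symbol, nb.gene_symbol,
                    int(rng.integers(config.ppi_min_score, 1000)),
                )
            )
            expanded_ids.add(nb.gencode_id)
            expanded_symbols.add(nb.gene_symbol)
            neighbor_attached.add(nb.gene_symbol)
        # sub-threshold decoy: must not expand
        if len(neighbor_genes) > 0:
            nb = neighbor_genes[rng.integers(len(neighbor_genes))]
            ppi_edges.append(
                PPIEdge(
                    g.gene_symbol, nb.gene_symbol,
                    int(rng.integers(100, config.ppi_min_score)),
                )
            )
    # risk-risk edges (neighbors already in the set)
    if len(risk_genes) >= 2:
        for _ in range(min(3, len(risk_genes) - 1)):
            i, j = rng.choice(len(risk_genes), size=2, replace=False)
            ppi_edges.append(
                PPIEdge(
                    risk_genes[i].gene_symbol, risk_genes[j].gene_symbol,
                    int(rng.integers(config.ppi_min_score, 1000)),
                )
            )
    # high-confidence edges not touching any risk gene: never retained
    non_risk = [g for g in candidate_genes if g.gencode_id not in risk_ids]
    for _ in range(3):
        if len(non_risk) >= 2:
            i, j = rng.choice(len(non_risk), size=2, replace=False)
            ppi_edges.append(
                PPIEdge(
                    non_risk[i].gene_symbol, non_risk[j].gene_symbol,
                    int(rng.integers(config.ppi_min_score, 1000)),
                )
            )
    if risk_genes:
        # endpoint missing from the symbol map: dropped with a logged count
        ppi_edges.append(PPIEdge(risk_genes[0].gene_symbol, "UNKNOWNPROT", 950))
    order = rng.permutation(len(ppi_edges))
    ppi_edges = [ppi_edges[i] for i in order]

    # --- drugs ------------------------------------------------------------
    drug_targets: list[DrugTargetLink] = []
    trials: list[TrialRecord] = []
    approval_rows = []
    drug_status: dict[str, str] = {}
    expanded_symbol_list = sorted(expanded_symbols)
    n_hits = config.n_hit_drugs if expanded_symbol_list else 0
    pool = [
        expanded_symbol_list[i]
        for i in rng.choice(
            len(expanded_symbol_list),
            size=min(config.target_pool_size, len(expanded_symbol_list)),
            replace=False,
        )
    ] if expanded_symbol_list else []
    statuses = (
        [drug_mapping.STATUS_APPROVED] * config.n_drugs_approved
        + [drug_mapping.STATUS_IN_TRIAL] * config.n_drugs_in_trial
    )
    statuses += [drug_mapping.STATUS_NOVEL] * max(0, n_hits - len(statuses))
    statuses = statuses[:n_hits]
    nct_counter = 0
    for i in range(n_hits):
        name = f"cmpd{i + 1:03d}"
        drug_id = f"DB9{i + 1:04d}"
        n_targets = int(rng.integers(1, min(2, len(pool)) + 1))
        targets = [
            pool[t] for t in rng.choice(len(pool), size=n_targets, replace=False)
        ]
        for t in targets:
            drug_targets.append(
                DrugTargetLink(
                    drug_id=drug_id, drug_name=name, target_gene=t,
                    pharmacological_action=str(rng.choice(["yes", "no", "unknown"])),
                    groups=frozenset({"approved"}),
                )
            )
        status = statuses[i]
        drug_status[name] = status
        if status == drug_mapping.STATUS_APPROVED:
            approval_rows.append(
                {"drug_name": name, "condition": config.condition.title(),
                 "approval_id": f"APPR{i + 1:03d}"}
            )
        elif status == drug_mapping.STATUS_IN_TRIAL:
            nct_counter += 1
            # registry spelling varies: sometimes a salt suffix
            reg_name = name + (" hydrochloride" if nct_counter == 1 else "")
            trials.append(
                TrialRecord(
                    nct_id=f"NCT{90000000 + nct_counter:08d}",
                    drug_name=reg_name,
                    condition=f"{config.condition.title()} (MM)",
                    status="recruiting",
                )
            )
            # decoy: same drug, unrelated condition — must not double-count
            nct_counter += 1
            trials.append(
                TrialRecord(
                    nct_id=f"NCT{90000000 + nct_counter:08d}",
                    drug_name=name, condition="Psoriasis", status="completed",
                )
            )
        else:  # novel: decoy trial for an unrelated condition only
            nct_counter += 1
            trials.append(
                TrialRecord(
                    nct_id=f"NCT{90000000 + nct_counter:08d}",
                    drug_name=name, condition="Breast Cancer", status="completed",
                )
            )
    # decoy drugs targeting genes outside the expanded set: never candidates
    for i in range(config.n_decoy_drugs):
        name = f"offtg{i + 1:03d}"
        drug_targets.append(
            DrugTargetLink(
                drug_id=f"DB8{i + 1:04d}", drug_name=name,
                target_gene=decoy_genes[i % len(decoy_genes)].gene_symbol,
                pharmacological_action="yes", groups=frozenset({"approved"}),
            )
        )
        approval_rows.append(
            {"drug_name": name, "condition": "Hypertension",
             "approval_id": f"APPRX{i + 1:02d}"}
        )
    approvals = pd.DataFrame(
        approval_rows, columns=["drug_name", "condition", "approval_id"]
    )

    # --- manifest ---------------------------------------------------------
    manifest = {
        "n_significant_snps": n_sig,
        "candidate_gene_ids": sorted(g.gencode_id for g in candidate_genes),
        "flag_matrix": {
            g.gencode_id: list(flags[g.gencode_id].as_tuple())
            for g in candidate_genes
        },
        "risk_gene_ids": sorted(risk_ids),
        "expanded_gene_ids": sorted(expanded_ids) if risk_ids else [],
        "drug_status": dict(sorted(drug_status.items())),
    }
    return FixtureBundle(
        config=config,
        associations=associations,
        ld_table=ld_rows,
        eqtl_table=eqtl_table,
        go_membership=go_membership,
        pid_list=pid_list,
        symbol_map=symbol_map,
        ppi_edges=ppi_edges,
        drug_targets=drug_targets,
        approvals=approvals,
        trials=trials,
        manifest=manifest,
    )


def replay_bundle(bundle: FixtureBundle) -> dict:
    """Run the full pipeline in memory on a bundle; return realized truth.

    Same keys as the manifest, so equality with ``bundle.manifest`` is the
    planted-truth recovery check.
    """
    cfg = bundle.config
    selected = variant_selection.deduplicate_snps(
        variant_selection.filter_associations(bundle.associations, cfg.p_threshold)
    )
    proxies = ld_expansion.expand_ld(
        [r.rsid for r in selected], bundle.ld_table,
        cfg.r2_threshold, cfg.population,
    )
    gene_proxies = ld_expansion.collect_genes(proxies)
    flags = scoring.compute_flags(
        gene_proxies, bundle.eqtl_table, bundle.go_membership, bundle.pid_list,
        alpha=cfg.alpha, background_n=cfg.background_n,
    )
    genes = [gp.gene for gp in gene_proxies]
    scores = scoring.score_genes(genes, flags, cfg.risk_threshold)
    risk = scoring.call_risk_genes(scores, cfg.risk_threshold)
    expansion = network_expansion.expand_ppi(
        [s.gene for s in risk], bundle.ppi_edges,
        cfg.ppi_min_score, bundle.symbol_map,
    )
    candidates = drug_mapping.map_drugs(
        {g.gene_symbol for g in expansion.expanded_genes}, bundle.drug_targets
    )
    classified = drug_mapping.classify_all(
        candidates, bundle.approvals, bundle.trials, cfg.condition
    )
    return {
        "n_significant_snps": len(selected),
        "candidate_gene_ids": sorted(g.gencode_id for g in genes),
        "flag_matrix": {
            g.gencode_id: list(flags[g.gencode_id].as_tuple()) for g in genes
        },
        "risk_gene_ids": sorted(s.gene.gencode_id for s in risk),
        "expanded_gene_ids": sorted(
            g.gencode_id for g in expansion.expanded_genes
        ),
        "drug_status": {c.drug_name: c.status for c in classified},
    }


def generate_bundle(config: GeneratorConfig, max_attempts: int = 10) -> FixtureBundle:
    """Generate a bundle whose pipeline replay reproduces its manifest.

    Deterministic given ``config.seed``.  A draw whose realized truth
    deviates from the planted truth (possible, e.g., when a decoy GO term
    lands under alpha for an unusual candidate-set size) is discarded and
    regenerated from a derived seed; exhausting ``max_attempts`` raises.
    """
    seed = config.seed % 2**31
    for attempt in range(max_attempts):
        bundle = _generate_once(config, seed)
        if replay_bundle(bundle) == bundle.manifest:
            return bundle
        logger.warning(
            "bundle draw at seed %d failed replay verification; reseeding", seed
        )
        seed = (seed * 69069 + 1) % 2**31
    raise RuntimeError(
        f"could not generate a self-consistent bundle in {max_attempts} attempts "
        f"from seed {config.seed}"
    )


# ---------------------------------------------------------------------------
# in-paper fixtures
# ---------------------------------------------------------------------------

_TABLE1_TSV = """\
GENCODE_id\tGENCODE_name\tMissense\tCis-eQTL\tBiological process\tCellular component\tMolecular function\tPID\tTotal score
ENSG00000168411\tRFWD3\t1\t1\t1\t1\t1\t0\t5
ENSG00000100281\tHMGXB4\t1\t0\t0\t1\t1\t0\t3
ENSG00000164649\tCDCA7L\t0\t1\t1\t1\t0\t0\t3
ENSG00000204536\tCCHCR1\t0\t1\t1\t1\t0\t0\t3
ENSG00000025770\tNCAPH2\t0\t0\t1\t1\t0\t0\t2
ENSG00000080603\tSRCAP\t0\t0\t0\t1\t1\t0\t2
ENSG00000100307\tCBX7\t0\t1\t0\t1\t0\t0\t2
ENSG00000138101\tDTNB\t0\t0\t0\t1\t1\t0\t2
ENSG00000156858\tPRR14\t1\t1\t0\t0\t0\t0\t2
ENSG00000168038\tULK4\t1\t1\t0\t0\t0\t0\t2
ENSG00000182606\tTRAK1\t0\t1\t0\t1\t0\t0\t2
ENSG00000204525\tHLA-C\t1\t1\t0\t0\t0\t0\t2
ENSG00000204531\tPOU5F1\t0\t0\t0\t1\t1\t0\t2
ENSG00000240505\tTNFRSF13B\t1\t0\t0\t0\t0\t1\t2
"""


def table1_fixture() -> pd.DataFrame:
    """The published 14-gene x 6-flag annotation matrix, printed row order.

    Columns: GENCODE_id, GENCODE_name, the six criterion flags, Total score.
    """
    return pd.read_csv(StringIO(_TABLE1_TSV), sep="\t")


def table1_gene_flags() -> tuple[list[GeneRecord], dict[str, scoring.AnnotationFlags]]:
    """The matrix as scoring inputs: gene records plus per-gene flags."""
    df = table1_fixture()
    genes = [
        GeneRecord(gencode_id=r["GENCODE_id"], gene_symbol=r["GENCODE_name"])
        for _, r in df.iterrows()
    ]
    flags = {
        r["GENCODE_id"]: scoring.AnnotationFlags(
            missense=int(r["Missense"]),
            cis_eqtl=int(r["Cis-eQTL"]),
            go_bp=int(r["Biological process"]),
            go_cc=int(r["Cellular component"]),
            go_mf=int(r["Molecular function"]),
            pid=int(r["PID"]),
        )
        for _, r in df.iterrows()
    }
    return genes, flags


def paper_drug_fixture() -> tuple[list[DrugTargetLink], pd.DataFrame, list[TrialRecord]]:
    """Drug-evidence tables for the nine drugs named in the published text.

    Panobinostat carries the sole approved indication for multiple myeloma;
    cyclosporine, belinostat, vorinostat and romidepsin carry their printed
    NCT trial identifiers; theophylline, aminophylline, oxtriphylline and
    tixocortol carry neither.  Published text names CAMLG and HDAC2 as the
    promising targets; the target assignments of the four never-trialed
    drugs among these two genes are synthetic (the figure they appear in is
    not machine-readable), which does not affect status triage.
    """
    links = [
        DrugTargetLink("DB06603", "panobinostat", "HDAC2", "yes",
                       frozenset({"approved"})),
        DrugTargetLink("DB00091", "cyclosporine", "CAMLG", "yes",
                       frozenset({"approved"})),
        DrugTargetLink("DB05015", "belinostat", "HDAC2", "yes",
                       frozenset({"approved"})),
        DrugTargetLink("DB02546", "vorinostat", "HDAC2", "yes",
                       frozenset({"approved"})),
        DrugTargetLink("DB06176", "romidepsin", "HDAC2", "yes",
                       frozenset({"approved"})),
        DrugTargetLink("DB00277", "theophylline", "HDAC2", "no",
                       frozenset({"approved"})),
        DrugTargetLink("DB01223", "aminophylline", "HDAC2", "no",
                       frozenset({"approved"})),
        DrugTargetLink("DB01303", "oxtriphylline", "HDAC2", "no",
                       frozenset({"approved"})),
        DrugTargetLink("DB09091", "tixocortol", "CAMLG", "no",
                       frozenset({"approved"})),
    ]
    approvals = pd.DataFrame(
        [{"drug_name": "panobinostat", "condition": "Multiple Myeloma",
          "approval_id": "FDA-2015-panobinostat"}],
        columns=["drug_name", "condition", "approval_id"],
    )
    trials = [
        TrialRecord("NCT04813653", "cyclosporine", "Multiple Myeloma", "recruiting"),
        TrialRecord("NCT00131261", "belinostat", "Multiple Myeloma", "completed"),
        TrialRecord("NCT01502085", "vorinostat", "Multiple Myeloma", "completed"),
        TrialRecord("NCT00765102", "romidepsin", "Multiple Myeloma", "completed"),
    ]
    return links, approvals, trials
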