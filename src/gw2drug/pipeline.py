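"""End-to-end pipeline orchestration.

Stages run in order select → expand-ld → score → expand-ppi → map-drugs,
each reading and writing standard TSV intermediates so they can also be run
independently.  A run is fully determined by (inputs, config): rerunning
produces bit-identical outputs and report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import annotation_scoring as scoring
from . import drug_mapping, io_formats, ld_expansion, network_expansion, variant_selection

logger = logging.getLogger(__name__)

_DIALECTS = {
    "native": io_formats.ASSOCIATIONS_NATIVE,
    "gwas-catalog": io_formats.ASSOCIATIONS_GWAS_CATALOG,
}
_LD_DIALECTS = {
    "native": io_formats.LD_NATIVE,
    "haploreg": io_formats.LD_HAPLOREG,
}


@dataclass
class PipelineConfig:
    """Thresholds, input paths and output directory for one run."""

    associations: str = "associations.tsv"
    ld_proxies: str = "ld_proxies.tsv"
    eqtl: str = "eqtl.tsv"
    go_membership: str = "go_membership.tsv"
    pid_list: str = "pid_genes.txt"
    symbol_map: str = "symbol_map.tsv"
    ppi_edges: str = "ppi_edges.txt"
    drug_targets: str = "drug_targets.csv"
    approvals: str = "approvals.tsv"
    trials: str = "trials.tsv"
    out_dir: str = "gw2drug_out"

    p_threshold: float = 1e-8
    strict_p: bool = True
    r2_threshold: float = 0.80
    population: str = "ASN"
    risk_threshold: int = 2
    alpha: float = 0.05
    background_n: int = 20_000
    eqtl_tissue: str = "Whole_Blood"
    ppi_min_score: int = 400
    enrichment_correction: str = "none"  # "none" (raw p) or "bh"
    condition: str = "multiple myeloma"
    pharm_action_only: bool = False
    association_dialect: str = "native"
    ld_dialect: str = "native"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError(f"p_threshold out of (0,1]: {self.p_threshold}")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError(f"r2_threshold out of [0,1]: {self.r2_threshold}")
        if not (0 <= self.risk_threshold <= 6):
            raise ValueError(f"risk_threshold out of 0..6: {self.risk_threshold}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha out of (0,1]: {self.alpha}")
        if not (0 <= self.ppi_min_score <= 1000):
            raise ValueError(f"ppi_min_score out of [0,1000]: {self.ppi_min_score}")
        if not self.condition:
            raise ValueError("condition must be non-empty")
        if self.enrichment_correction not in ("none", "bh"):
            raise ValueError(
                f"unknown enrichment correction {self.enrichment_correction!r}"
            )
        if self.association_dialect not in _DIALECTS:
            raise ValueError(f"unknown association dialect {self.association_dialect!r}")
        if self.ld_dialect not in _LD_DIALECTS:
            raise ValueError(f"unknown LD dialect {self.ld_dialect!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def for_bundle_dir(cls, bundle_dir: str | Path, out_dir: str | Path,
                       **overrides) -> "PipelineConfig":
        """Point every input path at a written fixture bundle directory."""
        b = Path(bundle_dir)
        defaults = dict(
            associations=str(b / "associations.tsv"),
            ld_proxies=str(b / "ld_proxies.tsv"),
            eqtl=str(b / "eqtl.tsv"),
            go_membership=str(b / "go_membership.tsv"),
            pid_list=str(b / "pid_genes.txt"),
            symbol_map=str(b / "symbol_map.tsv"),
            ppi_edges=str(b / "ppi_edges.txt"),
            drug_targets=str(b / "drug_targets.csv"),
            approvals=str(b / "approvals.tsv"),
            trials=str(b / "trials.tsv"),
            out_dir=str(out_dir),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class RunReport:
    """Per-stage counts, output paths, and the config that produced them."""

    config: dict
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    risk_genes: list[str] = field(default_factory=list)
    status_counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunReport":
        return cls(**d)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages on the configured inputs.

    Intermediates and final tables are written under ``config.out_dir``.
    An empty association table is not an error: every downstream stage
    yields empty output and the report carries all-zero counts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())

    # --- select -----------------------------------------------------------
    assoc = io_formats.read_associations(
        config.associations, _DIALECTS[config.association_dialect],
        strict=config.strict_p,
    )
    report.counts["associations_in"] = len(assoc)
    selected = variant_selection.deduplicate_snps(
        variant_selection.filter_associations(assoc, config.p_threshold)
    )
    report.counts["significant_snps"] = len(selected)
    if not selected:
        logger.warning("no genome-wide significant SNPs; downstream stages empty")
    p_sel = out / "selected_snps.tsv"
    io_formats.write_associations(selected, p_sel)
    report.outputs["selected_snps"] = str(p_sel)

    # --- expand-ld --------------------------------------------------------
    ld_table = io_formats.read_linked_variants(
        config.ld_proxies, _LD_DIALECTS[config.ld_dialect]
    )
    proxies = ld_expansion.expand_ld(
        [r.rsid for r in selected], ld_table,
        config.r2_threshold, config.population,
    ) if selected else []
    report.counts["ld_proxies"] = len(proxies)
    gene_proxies = ld_expansion.collect_genes(proxies)
    report.counts["candidate_genes"] = len(gene_proxies)
    p_prox = out / "ld_proxies_selected.tsv"
    io_formats.write_linked_variants(proxies, p_prox)
    report.outputs["ld_proxies"] = str(p_prox)

    # --- score ------------------------------------------------------------
    eqtl = io_formats.read_eqtl_table(config.eqtl)
    membership = io_formats.read_go_membership(config.go_membership)
    pid = io_formats.read_pid_list(config.pid_list)
    flags = scoring.compute_flags(
        gene_proxies, eqtl, membership, pid,
        alpha=config.alpha, background_n=config.background_n,
        eqtl_tissue=config.eqtl_tissue,
        correction=config.enrichment_correction,
    )
    scores = scoring.score_genes(
        [gp.gene for gp in gene_proxies], flags, config.risk_threshold
    )
    risk = scoring.call_risk_genes(scores, config.risk_threshold)
    report.counts["risk_genes"] = len(risk)
    report.risk_genes = [s.gene.gencode_id for s in risk]
    p_scores = out / "gene_scores.tsv"
    scoring.scores_to_frame(scores).to_csv(p_scores, sep="\t", index=False)
    report.outputs["gene_scores"] = str(p_scores)

    # --- expand-ppi -------------------------------------------------------
    edges = io_formats.read_ppi_edges(config.ppi_edges)
    symbol_map = io_formats.read_symbol_map(config.symbol_map)
    expansion = network_expansion.expand_ppi(
        [s.gene for s in risk], edges, config.ppi_min_score, symbol_map
    )
    summary = network_expansion.summarize_expansion(expansion)
    report.counts["expanded_genes"] = summary.n_expanded
    report.counts["ppi_pairs"] = summary.n_pairs
    p_pairs = out / "ppi_pairs.tsv"
    with open(p_pairs, "w") as fh:
        fh.write("gene_a\tgene_b\tcombined_score\n")
        for a, b, s in expansion.pairs:
            fh.write(f"{a}\t{b}\t{s}\n")
    report.outputs["ppi_pairs"] = str(p_pairs)

    # --- map-drugs --------------------------------------------------------
    targets = io_formats.read_drug_targets(config.drug_targets)
    approvals = io_formats.read_approvals(config.approvals)
    registry = io_formats.read_trials(config.trials)
    candidates = drug_mapping.map_drugs(
        {g.gene_symbol for g in expansion.expanded_genes}, targets,
        pharm_action_only=config.pharm_action_only,
    )
    classified = drug_mapping.classify_all(
        candidates, approvals, registry, config.condition
    )
    counts, _lists = drug_mapping.partition_candidates(classified)
    report.counts["drug_candidates"] = len(classified)
    report.status_counts = counts
    p_net = out / "drug_gene_network.tsv"
    n_edges = io_formats.write_bipartite_edges(classified, p_net)
    report.counts["bipartite_edges"] = n_edges
    report.outputs["drug_gene_network"] = str(p_net)

    p_cand = out / "drug_candidates.tsv"
    with open(p_cand, "w") as fh:
        fh.write("drug_id\tdrug_name\tstatus\tpharm_action_any\ttarget_genes\tevidence\n")
        for c in classified:
            fh.write(
                f"{c.drug_id}\t{c.drug_name}\t{c.status}\t"
                f"{int(c.pharm_action_any)}\t{','.join(sorted(c.target_genes))}\t"
                f"{','.join(c.evidence)}\n"
            )
    report.outputs["drug_candidates"] = str(p_cand)

    render_report(report, out / "report")
    report.outputs["report"] = str(out / "report.json")
    return report


def render_report(report: RunReport, path_stem: str | Path) -> Path:
    """Write the report as JSON (machine) and aligned text (human).

    Returns the JSON path; :func:`parse_report` round-trips it.
    """
    stem = Path(path_stem)
    json_path = stem.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(stem.with_suffix(".txt"), "w") as fh:
        fh.write(f"gw2drug {report.version} run report\n")
        fh.write("=" * 34 + "\n\nstage counts\n")
        for k, v in report.counts.items():
            fh.write(f"  {k:<22s} {v}\n")
        fh.write("\ndrug status partition\n")
        for k, v in report.status_counts.items():
            fh.write(f"  {k:<22s} {v}\n")
        fh.write("\nrisk genes\n")
        for g in report.risk_genes:
            fh.write(f"  {g}\n")
        fh.write("\noutputs\n")
        for k, v in report.outputs.items():
            fh.write(f"  {k:<22s} {v}\n")
    return json_path


def parse_report(path: str | Path) -> RunReport:
    with open(path) as fh:
        return RunReport.from_dict(json.load(fh))
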