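"""LD proxy expansion and proxy-to-gene collection.

Lead SNPs are widened to all proxies in strong linkage disequilibrium
(r² > 0.80 by default, strict inequality) within one reference-panel
population (default "ASN", the 1000 Genomes Phase 1 Asian panel as exposed
by HaploReg v4.1).  Each seed is always retained as its own proxy with
r² = 1, synthesized if the LD table does not list it, so no lead SNP is
lost silently.  Proxies are then grouped by the gene they fall in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_formats import LinkedVariant

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.80
DEFAULT_POPULATION = "ASN"


@dataclass(frozen=True)
class GeneRecord:
    """A gene keyed by its GENCODE (Ensembl) stable id."""

    gencode_id: str
    gene_symbol: str = ""


@dataclass(frozen=True)
class GeneProxies:
    """A gene together with the LD proxies mapping to it."""

    gene: GeneRecord
    proxies: tuple[LinkedVariant, ...]


def expand_ld(
    seed_snps: list[str],
    ld_table: list[LinkedVariant],
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    population: str = DEFAULT_POPULATION,
) -> list[LinkedVariant]:
    """Return proxies of the seeds with r² strictly above the threshold.

    Restricted to the requested panel population; deduplicated on
    (query_rsid, proxy_rsid); every seed appears as its own proxy (r² = 1).
    Seeds absent from the LD table get a synthesized self-proxy with a
    logged warning.
    """
    if not (0.0 <= r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must be in [0,1], got {r2_threshold}")
    seeds = list(dict.fromkeys(seed_snps))  # preserve order, drop dupes
    seed_set = set(seeds)
    out: dict[tuple[str, str], LinkedVariant] = {}
    seeds_seen: set[str] = set()
    for lv in ld_table:
        if lv.query_rsid not in seed_set or lv.population != population:
            continue
        seeds_seen.add(lv.query_rsid)
        is_self = lv.proxy_rsid == lv.query_rsid
        if not is_self and lv.r_squared <= r2_threshold:
            continue
        key = (lv.query_rsid, lv.proxy_rsid)
        if key not in out:
            out[key] = lv
    for s in seeds:
        if (s, s) not in out:
            if s not in seeds_seen:
                logger.warning("seed SNP %s absent from LD table; keeping self-proxy", s)
            out[(s, s)] = LinkedVariant(
                query_rsid=s, proxy_rsid=s, r_squared=1.0, population=population
            )
    return list(out.values())


def collect_genes(proxies: list[LinkedVariant]) -> list[GeneProxies]:
    """Group proxies by the gene they fall in.

    Genes are deduplicated by GENCODE id; proxies with an empty gene field
    contribute no gene.  Output sorted by GENCODE id.
    """
    by_gene: dict[str, list[LinkedVariant]] = {}
    symbols: dict[str, str] = {}
    for lv in proxies:
        if not lv.gencode_id:
            continue
        by_gene.setdefault(lv.gencode_id, []).append(lv)
        if lv.gene_symbol and lv.gencode_id not in symbols:
            symbols[lv.gencode_id] = lv.gene_symbol
    return [
        GeneProxies(
            gene=GeneRecord(gencode_id=gid, gene_symbol=symbols.get(gid, "")),
            proxies=tuple(by_gene[gid]),
        )
        for gid in sorted(by_gene)
    ]
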