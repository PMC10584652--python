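"""One-hop expansion of the risk-gene set through a PPI edge list.

Risk genes rarely coincide with druggable targets, so the set is widened to
direct interaction partners: every edge with a combined confidence score of
at least ``min_score`` (STRING convention; default 400, "medium
confidence") touching a risk gene is retained, and its other endpoint
joins the expanded set.  One hop only — no transitive closure.

Edges are keyed by gene symbol; endpoints are bridged to GENCODE ids via
the bundle's symbol map, and edges with an unmappable endpoint are dropped
with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_formats import PPIEdge
from .ld_expansion import GeneRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 400


@dataclass(frozen=True)
class ExpansionResult:
    """Expanded gene set plus the retained interaction pairs."""

    risk_genes: tuple[GeneRecord, ...]
    expanded_genes: tuple[GeneRecord, ...]  # risk genes ∪ neighbors, sorted
    pairs: tuple[tuple[str, str, int], ...]  # (symbol_a, symbol_b, score), sorted
    dropped_unmapped: int = 0


def expand_ppi(
    risk_genes: list[GeneRecord],
    edges: list[PPIEdge],
    min_score: int = DEFAULT_MIN_SCORE,
    symbol_map: dict[str, str] | None = None,
) -> ExpansionResult:
    """Expand the risk set by one hop across high-confidence PPI edges.

    Retained pairs are edges with combined_score >= min_score incident to at
    least one risk gene; the expanded set is the risk genes plus their
    neighbors across retained pairs.  Outputs are deterministic
    (lexicographic order).  An empty risk set yields empty outputs with a
    warning.
    """
    if not 0 <= min_score <= 1000:
        raise ValueError(f"min_score must be in [0,1000], got {min_score}")
    if not risk_genes:
        logger.warning("empty risk-gene set; PPI expansion produces nothing")
        return ExpansionResult((), (), ())
    symbol_map = {k.upper(): v for k, v in (symbol_map or {}).items()}
    # risk genes are addressable by upper-cased symbol
    risk_by_symbol = {g.gene_symbol.upper(): g for g in risk_genes if g.gene_symbol}

    def bridge(symbol: str) -> GeneRecord | None:
        """Map an edge endpoint symbol to a GeneRecord, or None if unmappable."""
        up = symbol.upper()
        if up in risk_by_symbol:
            return risk_by_symbol[up]
        if up in symbol_map:
            return GeneRecord(gencode_id=symbol_map[up], gene_symbol=symbol)
        return None

    expanded: dict[str, GeneRecord] = {g.gencode_id: g for g in risk_genes}
    pairs: set[tuple[str, str, int]] = set()
    dropped = 0
    for e in edges:
        if e.combined_score < min_score:
            continue
        a, b = bridge(e.protein_a), bridge(e.protein_b)
        if a is None or b is None:
            dropped += 1
            continue
        a_risk = a.gene_symbol.upper() in risk_by_symbol
        b_risk = b.gene_symbol.upper() in risk_by_symbol
        if not (a_risk or b_risk):
            continue
        expanded.setdefault(a.gencode_id, a)
        expanded.setdefault(b.gencode_id, b)
        sa, sb = sorted((e.protein_a, e.protein_b))
        pairs.add((sa, sb, e.combined_score))
    if dropped:
        logger.info("dropped %d high-confidence edges with unmappable endpoints", dropped)
    return ExpansionResult(
        risk_genes=tuple(sorted(risk_genes, key=lambda g: g.gencode_id)),
        expanded_genes=tuple(
            sorted(expanded.values(), key=lambda g: g.gencode_id)
        ),
        pairs=tuple(sorted(pairs)),
        dropped_unmapped=dropped,
    )


@dataclass(frozen=True)
class ExpansionSummary:
    n_risk: int
    n_expanded: int
    n_pairs: int
    degree: dict[str, int] = field(default_factory=dict)


def summarize_expansion(result: ExpansionResult) -> ExpansionSummary:
    """Counts and per-gene degree over the retained pairs."""
    degree: dict[str, int] = {}
    for a, b, _ in result.pairs:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    summary = ExpansionSummary(
        n_risk=len(result.risk_genes),
        n_expanded=len(result.expanded_genes),
        n_pairs=len(result.pairs),
        degree=degree,
    )
    if summary.n_expanded < summary.n_risk:
        raise AssertionError("expanded set smaller than risk set")
    return summary
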