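"""Six-criterion functional annotation scoring of candidate genes.

Each candidate gene earns one point per criterion met, up to 6:

1. **missense** — at least one LD proxy in the gene is a missense variant;
2. **cis-eQTL** — a proxy has a significant whole-blood cis-eQTL effect on
   the gene;
3-5. **GO BP / CC / MF** — the gene belongs to at least one Gene Ontology
   term of that category enriched in the candidate set (upper-tail
   hypergeometric p < alpha against a protein-coding background);
6. **PID** — the gene is on the curated primary-immunodeficiency list.

Genes totalling at least the risk threshold (default 2) are called
biological risk genes.  Ranking is by descending total score, ties broken
by ascending GENCODE id — the deterministic order the published scoring
table uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import dataclasses
from math import exp, lgamma, log

import pandas as pd

from .io_formats import LinkedVariant
from .ld_expansion import GeneProxies, GeneRecord

DEFAULT_ALPHA = 0.05
DEFAULT_BACKGROUND_N = 20_000
DEFAULT_RISK_THRESHOLD = 2

FLAG_ORDER = ("missense", "cis_eqtl", "go_bp", "go_cc", "go_mf", "pid")
GO_CATEGORIES = ("BP", "CC", "MF")


@dataclass(frozen=True)
class AnnotationFlags:
    """The six binary annotation flags for one gene."""

    missense: int = 0
    cis_eqtl: int = 0
    go_bp: int = 0
    go_cc: int = 0
    go_mf: int = 0
    pid: int = 0

    def __post_init__(self) -> None:
        for name in FLAG_ORDER:
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"flag {name} must be 0 or 1, got {v!r}")

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, name) for name in FLAG_ORDER)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


@dataclass(frozen=True)
class GeneScore:
    """A gene's flags, 0-6 total, and risk call."""

    gene: GeneRecord
    flags: AnnotationFlags
    total: int
    is_risk: bool

    def __post_init__(self) -> None:
        if self.total != self.flags.total:
            raise ValueError("total must equal the sum of the six flags")


@dataclass(frozen=True)
class EnrichmentResult:
    """Upper-tail hypergeometric enrichment of one term in the query set."""

    term_id: str
    category: str  # BP | CC | MF | PID
    k: int  # overlap: query genes in the term
    K: int  # term size in the background
    n: int  # query-set size
    N: int  # background size
    p_value: float


# ---------------------------------------------------------------------------
# hypergeometric upper tail
# ---------------------------------------------------------------------------


def _log_comb(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    X counts successes when drawing ``n`` items without replacement from a
    population of ``N`` containing ``K`` successes.  The tail is summed in
    log space (log-gamma binomials, max-shifted exponentiation), which
    keeps it exact to well below 1e-12 relative error for the background
    sizes used here.
    """
    if not (0 <= K <= N and 0 <= n <= N and k >= 0):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if k <= lo:
        return 1.0
    if k > hi:
        return 0.0
    log_denom = _log_comb(N, n)
    logs = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom
        for i in range(k, hi + 1)
    ]
    m = max(logs)
    return min(1.0, exp(m + log(sum(exp(v - m) for v in logs))))


def enrich_terms(
    candidate_ids: set[str],
    membership: pd.DataFrame,
    background_n: int = DEFAULT_BACKGROUND_N,
    correction: str = "none",
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every term against the candidate set.

    ``membership`` has columns term_id, category, gencode_id and is taken as
    the term's full extension within the background (no GO-graph
    propagation).  The query size ``n`` is the candidate-set size.

    ``correction="bh"`` replaces each term's p-value with its
    Benjamini-Hochberg adjusted value, computed within its category; the
    default is raw p-values (annotation screens are conventionally
    thresholded uncorrected).
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"correction must be 'none' or 'bh', got {correction!r}")
    n = len(candidate_ids)
    out: list[EnrichmentResult] = []
    for (term_id, category), grp in membership.groupby(
        ["term_id", "category"], sort=True
    ):
        members = set(grp["gencode_id"])
        K = len(members)
        k = len(members & candidate_ids)
        p = hypergeometric_tail(k, K, n, background_n)
        out.append(EnrichmentResult(term_id, category, k, K, n, background_n, p))
    if correction == "bh" and out:
        from scipy.stats import false_discovery_control

        adjusted: list[EnrichmentResult] = []
        for cat in sorted({e.category for e in out}):
            in_cat = [e for e in out if e.category == cat]
            q = false_discovery_control([e.p_value for e in in_cat], method="bh")
            adjusted.extend(
                dataclasses.replace(e, p_value=float(qv))
                for e, qv in zip(in_cat, q)
            )
        out = sorted(adjusted, key=lambda e: (e.term_id, e.category))
    return out


# ---------------------------------------------------------------------------
# per-criterion flags
# ---------------------------------------------------------------------------


def flag_missense(gene: GeneRecord, proxies: tuple[LinkedVariant, ...]) -> int:
    """1 iff at least one (already r²-filtered) proxy in the gene is missense."""
    return int(
        any(p.consequence == "missense" and p.gencode_id == gene.gencode_id
            for p in proxies)
    )


def flag_cis_eqtl(
    gene: GeneRecord,
    proxies: tuple[LinkedVariant, ...],
    eqtl_table: pd.DataFrame,
    tissue: str = "Whole_Blood",
) -> int:
    """1 iff some proxy has a significant cis-eQTL on the gene in the tissue."""
    sub = eqtl_table[
        (eqtl_table["gencode_id"] == gene.gencode_id)
        & (eqtl_table["tissue"] == tissue)
        & (eqtl_table["significant"].str.lower() == "yes")
    ]
    if sub.empty:
        return 0
    proxy_ids = {p.proxy_rsid for p in proxies}
    return int(bool(proxy_ids & set(sub["rsid"])))


def flag_go_category(
    gene: GeneRecord,
    enrichment: list[EnrichmentResult],
    membership: pd.DataFrame,
    category: str,
    alpha: float = DEFAULT_ALPHA,
) -> int:
    """1 iff the gene belongs to >= 1 term of the category enriched at p < alpha."""
    if category not in GO_CATEGORIES:
        raise ValueError(f"category must be one of {GO_CATEGORIES}, got {category!r}")
    enriched = {
        e.term_id for e in enrichment if e.category == category and e.p_value < alpha
    }
    if not enriched:
        return 0
    rows = membership[
        (membership["category"] == category)
        & (membership["gencode_id"] == gene.gencode_id)
        & (membership["term_id"].isin(enriched))
    ]
    return int(not rows.empty)


def flag_pid(gene: GeneRecord, pid_list: set[str]) -> int:
    """1 iff the gene symbol (case-insensitive) or GENCODE id is on the PID list."""
    upper = {s.upper() for s in pid_list}
    return int(gene.gene_symbol.upper() in upper or gene.gencode_id.upper() in upper)


def compute_flags(
    gene_proxies: list[GeneProxies],
    eqtl_table: pd.DataFrame,
    go_membership: pd.DataFrame,
    pid_list: set[str],
    alpha: float = DEFAULT_ALPHA,
    background_n: int = DEFAULT_BACKGROUND_N,
    eqtl_tissue: str = "Whole_Blood",
    correction: str = "none",
) -> dict[str, AnnotationFlags]:
    """All six flags for every candidate gene, keyed by GENCODE id.

    GO enrichment is computed once over the whole candidate set, then each
    gene is flagged by membership in enriched terms.
    """
    candidate_ids = {gp.gene.gencode_id for gp in gene_proxies}
    enrichment = enrich_terms(candidate_ids, go_membership, background_n, correction)
    flags: dict[str, AnnotationFlags] = {}
    for gp in gene_proxies:
        flags[gp.gene.gencode_id] = AnnotationFlags(
            missense=flag_missense(gp.gene, gp.proxies),
            cis_eqtl=flag_cis_eqtl(gp.gene, gp.proxies, eqtl_table, eqtl_tissue),
            go_bp=flag_go_category(gp.gene, enrichment, go_membership, "BP", alpha),
            go_cc=flag_go_category(gp.gene, enrichment, go_membership, "CC", alpha),
            go_mf=flag_go_category(gp.gene, enrichment, go_membership, "MF", alpha),
            pid=flag_pid(gp.gene, pid_list),
        )
    return flags


# ---------------------------------------------------------------------------
# scoring and risk calls
# ---------------------------------------------------------------------------


def rank_key(score: GeneScore) -> tuple:
    """Sort key: descending total, then ascending GENCODE id, then symbol."""
    return (-score.total, score.gene.gencode_id, score.gene.gene_symbol)


def score_genes(
    genes: list[GeneRecord],
    flags: dict[str, AnnotationFlags],
    risk_threshold: int = DEFAULT_RISK_THRESHOLD,
) -> list[GeneScore]:
    """Total each gene's flags and call risk genes at the threshold.

    Genes missing from ``flags`` score all-zero.  Output is sorted by the
    ranking rule (descending total, ascending GENCODE id).
    """
    if not 0 <= risk_threshold <= 6:
        raise ValueError(f"risk_threshold must be in 0..6, got {risk_threshold}")
    scores = []
    for g in genes:
        f = flags.get(g.gencode_id, AnnotationFlags())
        scores.append(
            GeneScore(gene=g, flags=f, total=f.total, is_risk=f.total >= risk_threshold)
        )
    return sorted(scores, key=rank_key)


def call_risk_genes(scores: list[GeneScore], threshold: int) -> list[GeneScore]:
    """Subset of scores with total >= threshold, ranking preserved.

    Thresholds above 6 exceed the maximum possible total and return the
    empty set.
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    return [s for s in scores if s.total >= threshold]


def scores_to_frame(scores: list[GeneScore]) -> pd.DataFrame:
    """Scores table in the published layout: id, symbol, six flags, total."""
    rows = [
        {
            "GENCODE_id": s.gene.gencode_id,
            "GENCODE_name": s.gene.gene_symbol,
            "Missense": s.flags.missense,
            "Cis-eQTL": s.flags.cis_eqtl,
            "Biological process": s.flags.go_bp,
            "Cellular component": s.flags.go_cc,
            "Molecular function": s.flags.go_mf,
            "PID": s.flags.pid,
            "Total score": s.total,
        }
        for s in scores
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "GENCODE_id", "GENCODE_name", "Missense", "Cis-eQTL",
            "Biological process", "Cellular component", "Molecular function",
            "PID", "Total score",
        ],
    )
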