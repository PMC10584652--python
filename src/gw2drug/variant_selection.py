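"""Genome-wide significance filtering and lead-SNP deduplication.

The association scan keeps variants below the conventional genome-wide
significance level (p < 1e-8 by default, strict inequality).  Duplicate
rsIDs — the same locus reported by several studies — collapse to the single
record with the smallest p-value, i.e. the strongest evidence per locus.
"""

from __future__ import annotations

from .io_formats import VariantAssociation

GENOME_WIDE_SIGNIFICANCE = 1e-8


def filter_associations(
    records: list[VariantAssociation],
    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
    strict: bool = True,
) -> list[VariantAssociation]:
    """Keep records passing the significance threshold, in original order.

    ``strict=True`` (default) keeps p < threshold; ``strict=False`` keeps
    p <= threshold for sensitivity runs.
    """
    if not (0.0 < p_threshold <= 1.0):
        raise ValueError(f"p_threshold must be in (0,1], got {p_threshold}")
    if strict:
        return [r for r in records if r.p_value < p_threshold]
    return [r for r in records if r.p_value <= p_threshold]


def deduplicate_snps(records: list[VariantAssociation]) -> list[VariantAssociation]:
    """One record per rsID, keeping the minimum p-value.

    Output order is deterministic: ascending p-value, ties broken by rsID.
    """
    best: dict[str, VariantAssociation] = {}
    for r in records:
        cur = best.get(r.rsid)
        if cur is None or r.p_value < cur.p_value:
            best[r.rsid] = r
    return sorted(best.values(), key=lambda r: (r.p_value, r.rsid))
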