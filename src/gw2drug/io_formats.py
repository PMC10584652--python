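"""Readers and writers for every external table the pipeline touches.

All joins downstream are identifier-based (rsID or gene id), so readers only
have to deliver clean columns: no coordinate arithmetic, no strand handling.
Column naming differences between database export flavours are absorbed by a
declarative :class:`Dialect` so real snapshots and synthetic fixtures share
one code path.

Conventions
-----------
* coordinates are 1-based (dbSNP / GWAS-catalog convention);
* gene identity is canonicalized to the Ensembl/GENCODE id when present;
  symbol-only tables are matched case-insensitively via a symbol map;
* STRING-style combined scores are integers in [0, 1000].
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

NCT_PATTERN = re.compile(r"^NCT\d{8}$")


class FormatError(ValueError):
    """A table violated its format contract (missing column, bad value...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS lead-SNP association record."""

    rsid: str
    chromosome: str
    position: int
    p_value: float
    mapped_genes: tuple[str, ...] = ()
    study_id: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise FormatError("rsid must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise FormatError(f"p_value must be in (0,1], got {self.p_value!r}")
        if self.position < 1:
            raise FormatError(f"position must be >= 1, got {self.position!r}")


@dataclass(frozen=True)
class LinkedVariant:
    """One LD proxy of a lead SNP, with the gene the proxy falls in.

    A seed SNP listed as its own proxy carries ``r_squared == 1``.  One gene
    per row; multi-gene annotations must be pre-split by the reader.
    """

    query_rsid: str
    proxy_rsid: str
    r_squared: float
    population: str = "ASN"
    gencode_id: str = ""
    gene_symbol: str = ""
    consequence: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise FormatError(f"r_squared must be in [0,1], got {self.r_squared!r}")


@dataclass(frozen=True)
class PPIEdge:
    """Undirected protein-protein interaction edge, STRING score convention."""

    protein_a: str
    protein_b: str
    combined_score: int

    def __post_init__(self) -> None:
        if not (0 <= self.combined_score <= 1000):
            raise FormatError(
                f"combined_score must be in [0,1000], got {self.combined_score!r}"
            )

    def key(self) -> tuple[str, str]:
        """Canonical unordered endpoint pair."""
        return tuple(sorted((self.protein_a, self.protein_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class DrugTargetLink:
    """One drug -> target-gene link from a DrugBank-style CSV projection."""

    drug_id: str
    drug_name: str
    target_gene: str
    pharmacological_action: str = "unknown"  # yes | no | unknown
    groups: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pharmacological_action not in ("yes", "no", "unknown"):
            raise FormatError(
                "pharmacological_action must be yes/no/unknown, got "
                f"{self.pharmacological_action!r}"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One clinical-trial registry row."""

    nct_id: str
    drug_name: str
    condition: str
    status: str = ""

    def __post_init__(self) -> None:
        if not NCT_PATTERN.match(self.nct_id):
            raise FormatError(f"nct_id must match NCT + 8 digits, got {self.nct_id!r}")


# ---------------------------------------------------------------------------
# dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Declarative column mapping for one table flavour.

    ``columns`` maps canonical field names to the header used in the file.
    Fields absent from the mapping are treated as optional and left at their
    defaults when missing from the file.
    """

    name: str
    columns: Mapping[str, str]
    separator: str = "\t"
    list_separator: str = ","

    def resolve(self, header: Sequence[str], mandatory: Iterable[str]) -> dict[str, str]:
        """Map canonical fields to actual header names, checking mandatory ones."""
        out: dict[str, str] = {}
        for field_name, col in self.columns.items():
            if col in header:
                out[field_name] = col
        for m in mandatory:
            if m not in out:
                raise FormatError(
                    f"dialect {self.name!r}: mandatory column for field {m!r} "
                    f"({self.columns.get(m, '<unmapped>')}) not found in header {list(header)}"
                )
        return out


#: native fixture layout written by this package
ASSOCIATIONS_NATIVE = Dialect(
    name="native-associations",
    columns={
        "rsid": "rsid",
        "chromosome": "chromosome",
        "position": "position",
        "p_value": "p_value",
        "mapped_genes": "mapped_genes",
        "study_id": "study_id",
    },
)

#: GWAS catalog association export headers (v1.0 family)
ASSOCIATIONS_GWAS_CATALOG = Dialect(
    name="gwas-catalog",
    columns={
        "rsid": "SNPS",
        "chromosome": "CHR_ID",
        "position": "CHR_POS",
        "p_value": "P-VALUE",
        "mapped_genes": "MAPPED_GENE",
        "study_id": "STUDY ACCESSION",
    },
    list_separator=";",
)

LD_NATIVE = Dialect(
    name="native-ld",
    columns={
        "query_rsid": "query_rsid",
        "proxy_rsid": "proxy_rsid",
        "r_squared": "r_squared",
        "population": "population",
        "gencode_id": "gencode_id",
        "gene_symbol": "gene_symbol",
        "consequence": "consequence",
    },
)

#: HaploReg-like proxy table headers
LD_HAPLOREG = Dialect(
    name="haploreg",
    columns={
        "query_rsid": "query_snp_rsid",
        "proxy_rsid": "rsID",
        "r_squared": "r2",
        "population": "pop",
        "gencode_id": "GENCODE_id",
        "gene_symbol": "GENCODE_name",
        "consequence": "dbSNP_functional_annotation",
    },
)


def _read_table(path: str | Path, dialect: Dialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    return pd.read_csv(path, sep=dialect.separator, dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# associations
# ---------------------------------------------------------------------------


def read_associations(
    path: str | Path,
    dialect: Dialect = ASSOCIATIONS_NATIVE,
    strict: bool = True,
) -> list[VariantAssociation]:
    """Read a GWAS-catalog-style association table.

    In strict mode (default) a malformed p-value aborts with the offending
    row number; in permissive mode such rows are counted, logged and skipped
    (never silently dropped).
    """
    df = _read_table(path, dialect)
    cols = dialect.resolve(df.columns, mandatory=["rsid", "p_value"])
    records: list[VariantAssociation] = []
    rejected = 0
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        raw_p = str(row_d[cols["p_value"]]).strip()
        try:
            p = float(raw_p)
            if not (0.0 < p <= 1.0):
                raise ValueError(raw_p)
        except ValueError:
            if strict:
                raise FormatError(
                    f"{path}: malformed p-value {raw_p!r} in data row {i}"
                ) from None
            rejected += 1
            continue
        genes: tuple[str, ...] = ()
        if "mapped_genes" in cols:
            raw_genes = str(row_d[cols["mapped_genes"]])
            genes = tuple(
                g.strip() for g in raw_genes.split(dialect.list_separator) if g.strip()
            )
        pos = 1
        if "position" in cols:
            raw_pos = str(row_d[cols["position"]]).strip()
            if raw_pos:
                try:
                    pos = int(raw_pos)
                except ValueError:
                    raise FormatError(
                        f"{path}: malformed position {raw_pos!r} in data row {i}"
                    ) from None
        records.append(
            VariantAssociation(
                rsid=str(row_d[cols["rsid"]]).strip(),
                chromosome=str(row_d.get(cols.get("chromosome", ""), "")).strip(),
                position=pos,
                p_value=p,
                mapped_genes=genes,
                study_id=str(row_d.get(cols.get("study_id", ""), "")).strip(),
            )
        )
    if rejected:
        logger.warning("%s: rejected %d rows with malformed p-values", path, rejected)
    return records


def write_associations(
    records: Iterable[VariantAssociation],
    path: str | Path,
    dialect: Dialect = ASSOCIATIONS_NATIVE,
) -> int:
    """Write associations in the given dialect; returns the row count."""
    cols = dialect.columns
    rows = []
    for r in records:
        rows.append(
            {
                cols["rsid"]: r.rsid,
                cols["chromosome"]: r.chromosome,
                cols["position"]: r.position,
                cols["p_value"]: repr(r.p_value),
                cols["mapped_genes"]: dialect.list_separator.join(r.mapped_genes),
                cols["study_id"]: r.study_id,
            }
        )
    df = pd.DataFrame(rows, columns=[cols[f] for f in (
        "rsid", "chromosome", "position", "p_value", "mapped_genes", "study_id")])
    df.to_csv(path, sep=dialect.separator, index=False)
    return len(df)


# ---------------------------------------------------------------------------
# LD proxies
# ---------------------------------------------------------------------------


def read_linked_variants(
    path: str | Path, dialect: Dialect = LD_NATIVE
) -> list[LinkedVariant]:
    df = _read_table(path, dialect)
    cols = dialect.resolve(df.columns, mandatory=["query_rsid", "proxy_rsid", "r_squared"])
    out: list[LinkedVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        try:
            r2 = float(row_d[cols["r_squared"]])
        except ValueError:
            raise FormatError(
                f"{path}: malformed r_squared {row_d[cols['r_squared']]!r} in data row {i}"
            ) from None
        out.append(
            LinkedVariant(
                query_rsid=str(row_d[cols["query_rsid"]]).strip(),
                proxy_rsid=str(row_d[cols["proxy_rsid"]]).strip(),
                r_squared=r2,
                population=str(row_d.get(cols.get("population", ""), "ASN")).strip(),
                gencode_id=str(row_d.get(cols.get("gencode_id", ""), "")).strip(),
                gene_symbol=str(row_d.get(cols.get("gene_symbol", ""), "")).strip(),
                consequence=str(row_d.get(cols.get("consequence", ""), "")).strip(),
            )
        )
    return out


def write_linked_variants(
    records: Iterable[LinkedVariant], path: str | Path, dialect: Dialect = LD_NATIVE
) -> int:
    cols = dialect.columns
    rows = [
        {
            cols["query_rsid"]: r.query_rsid,
            cols["proxy_rsid"]: r.proxy_rsid,
            cols["r_squared"]: repr(r.r_squared),
            cols["population"]: r.population,
            cols["gencode_id"]: r.gencode_id,
            cols["gene_symbol"]: r.gene_symbol,
            cols["consequence"]: r.consequence,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=[cols[f] for f in (
        "query_rsid", "proxy_rsid", "r_squared", "population",
        "gencode_id", "gene_symbol", "consequence")])
    df.to_csv(path, sep=dialect.separator, index=False)
    return len(df)


# ---------------------------------------------------------------------------
# PPI edges (STRING protein-links format: whitespace separated)
# ---------------------------------------------------------------------------


def read_ppi_edges(path: str | Path, deduplicate: bool = True) -> list[PPIEdge]:
    """Read a STRING-style protein-links edge list.

    Whitespace- or tab-separated three columns (protein_a, protein_b, score),
    with or without the STRING header line.  Self-loops are removed (count
    logged).  With ``deduplicate``, symmetric duplicates collapse to one edge
    keeping the maximum score.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    edges: list[PPIEdge] = []
    self_loops = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if i == 1 and not parts[-1].lstrip("-").isdigit():
                continue  # header line
            if len(parts) != 3:
                raise FormatError(f"{path}: expected 3 columns in row {i}, got {len(parts)}")
            a, b, raw_score = parts
            try:
                score = int(raw_score)
            except ValueError:
                raise FormatError(f"{path}: malformed score {raw_score!r} in row {i}") from None
            if not (0 <= score <= 1000):
                raise FormatError(f"{path}: score {score} outside [0,1000] in row {i}")
            if a == b:
                self_loops += 1
                continue
            edges.append(PPIEdge(a, b, score))
    if self_loops:
        logger.info("%s: removed %d self-loop edges", path, self_loops)
    if deduplicate:
        best: dict[tuple[str, str], PPIEdge] = {}
        for e in edges:
            k = e.key()
            if k not in best or e.combined_score > best[k].combined_score:
                best[k] = e
        edges = list(best.values())
    return edges


def write_ppi_edges(edges: Iterable[PPIEdge], path: str | Path) -> int:
    with open(path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        n = 0
        for e in edges:
            fh.write(f"{e.protein_a} {e.protein_b} {e.combined_score}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# plain annotation tables (native TSV layouts)
# ---------------------------------------------------------------------------


def read_eqtl_table(path: str | Path) -> pd.DataFrame:
    """cis-eQTL table: rsid, gencode_id, tissue, significant (yes/no)."""
    df = _read_table(path, Dialect("native-eqtl", {}))
    for col in ("rsid", "gencode_id", "tissue", "significant"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


def read_go_membership(path: str | Path) -> pd.DataFrame:
    """GO membership table: term_id, category (BP/CC/MF), gencode_id."""
    df = _read_table(path, Dialect("native-go", {}))
    for col in ("term_id", "category", "gencode_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    bad = set(df["category"]) - {"BP", "CC", "MF"}
    if bad:
        raise FormatError(f"{path}: unknown GO categories {sorted(bad)}")
    return df


def read_pid_list(path: str | Path) -> set[str]:
    """IUIS-style primary-immunodeficiency gene list, one symbol per line."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.add(s)
    return symbols


def read_symbol_map(path: str | Path) -> dict[str, str]:
    """symbol -> GENCODE id mapping table (TSV: gene_symbol, gencode_id).

    Lookup keys are upper-cased so symbol matching is case-insensitive.
    """
    df = _read_table(path, Dialect("native-symbols", {}))
    for col in ("gene_symbol", "gencode_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return {s.upper(): g for s, g in zip(df["gene_symbol"], df["gencode_id"])}


def read_drug_targets(path: str | Path) -> list[DrugTargetLink]:
    """DrugBank-style CSV projection: drug_id, drug_name, target_gene,
    pharmacological_action, groups (pipe-separated).

    (drug_id, target_gene) pairs are unique after loading; duplicates keep
    the first occurrence with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("drug_id", "drug_name", "target_gene"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    seen: dict[tuple[str, str], DrugTargetLink] = {}
    dupes = 0
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        link = DrugTargetLink(
            drug_id=d["drug_id"],
            drug_name=d["drug_name"],
            target_gene=d["target_gene"],
            pharmacological_action=d.get("pharmacological_action", "unknown") or "unknown",
            groups=frozenset(g for g in d.get("groups", "").split("|") if g),
        )
        k = (link.drug_id, link.target_gene)
        if k in seen:
            dupes += 1
            continue
        seen[k] = link
    if dupes:
        logger.info("%s: dropped %d duplicate (drug, target) rows", path, dupes)
    return list(seen.values())


def read_trials(path: str | Path) -> list[TrialRecord]:
    """ClinicalTrials-style registry TSV: nct_id, drug_name, condition, status."""
    df = _read_table(path, Dialect("native-trials", {}))
    for col in ("nct_id", "drug_name", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        out.append(
            TrialRecord(
                nct_id=d["nct_id"],
                drug_name=d["drug_name"],
                condition=d["condition"],
                status=d.get("status", ""),
            )
        )
    return out


def read_approvals(path: str | Path) -> pd.DataFrame:
    """Approved-indication table: drug_name, condition, approval_id."""
    df = _read_table(path, Dialect("native-approvals", {}))
    for col in ("drug_name", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if "approval_id" not in df.columns:
        df = df.assign(approval_id="")
    return df


# ---------------------------------------------------------------------------
# bipartite drug-gene export
# ---------------------------------------------------------------------------

BIPARTITE_COLUMNS = ("drug_id", "drug_name", "target_gene", "status")


def write_bipartite_edges(candidates: Sequence, path: str | Path) -> int:
    """Export the drug-gene network as a TSV edge list, one row per
    (drug, target gene) pair with the drug's triage status.

    Returns the number of data rows written.  Re-readable with
    :func:`read_bipartite_edges` to an equal structure.
    """
    rows = []
    for c in candidates:
        if not c.target_genes:
            raise FormatError(f"candidate {c.drug_name!r} has no target genes")
        for g in sorted(c.target_genes):
            rows.append(
                {"drug_id": c.drug_id, "drug_name": c.drug_name,
                 "target_gene": g, "status": c.status or ""}
            )
    df = pd.DataFrame(rows, columns=list(BIPARTITE_COLUMNS))
    df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)
    return len(df)


def read_bipartite_edges(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, Dialect("native-bipartite", {}))
    missing = set(BIPARTITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
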