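"""Drug-target overlap and development-status triage.

The expanded gene set is intersected with a drug–target table; every drug
with at least one target in the set becomes a repurposing candidate.  Each
candidate is then triaged against the disease of interest:

* ``approved_for_disease`` — an approved-indication row matches the drug
  and condition;
* ``in_trial`` — at least one registry trial matches the drug and
  condition (the matched NCT ids are kept as evidence);
* ``novel`` — neither.

Precedence is approved > in_trial > novel.  Drug-name matching is
normalized (lower-case, trimmed, common salt/ester suffixes stripped)
because registry spellings vary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .io_formats import DrugTargetLink, TrialRecord

DEFAULT_CONDITION = "multiple myeloma"

#: suffix tokens stripped during drug-name normalization
SALT_SUFFIXES = (
    "sodium", "hydrochloride", "hcl", "sulfate", "sulphate", "phosphate",
    "acetate", "citrate", "maleate", "mesylate", "tartrate", "besylate",
    "anhydrous", "monohydrate", "dihydrate", "pivalate",
)

STATUS_APPROVED = "approved_for_disease"
STATUS_IN_TRIAL = "in_trial"
STATUS_NOVEL = "novel"
STATUSES = (STATUS_APPROVED, STATUS_IN_TRIAL, STATUS_NOVEL)


@dataclass(frozen=True)
class DrugCandidate:
    """A candidate drug, the risk/expanded genes it targets, and its triage."""

    drug_id: str
    drug_name: str
    target_genes: frozenset[str]
    pharm_action_any: bool = False
    status: str = ""  # one of STATUSES once classified
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.target_genes:
            raise ValueError(f"candidate {self.drug_name!r} must have >=1 target gene")
        if self.status and self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def normalize_drug_name(name: str, salt_suffixes: tuple[str, ...] = SALT_SUFFIXES) -> str:
    """Lower-case, trim, and strip trailing salt/ester tokens."""
    tokens = name.strip().lower().split()
    while len(tokens) > 1 and tokens[-1] in salt_suffixes:
        tokens.pop()
    return " ".join(tokens)


def map_drugs(
    expanded_genes: set[str],
    drug_targets: list[DrugTargetLink],
    pharm_action_only: bool = False,
) -> list[DrugCandidate]:
    """Overlap the expanded gene set with the drug–target table.

    Gene matching is by symbol, case-insensitive.  One candidate per drug
    with >= 1 target in the set; ``pharm_action_any`` records whether any
    targeting link is annotated with known pharmacological action.  With
    ``pharm_action_only`` (strict mode) only pharmacological_action = yes
    links count.  Output sorted by drug name then id.
    """
    gene_set = {g.upper() for g in expanded_genes}
    by_drug: dict[str, dict] = {}
    for link in drug_targets:
        if link.target_gene.upper() not in gene_set:
            continue
        if pharm_action_only and link.pharmacological_action != "yes":
            continue
        d = by_drug.setdefault(
            link.drug_id,
            {"name": link.drug_name, "targets": set(), "pharm": False},
        )
        d["targets"].add(link.target_gene)
        d["pharm"] = d["pharm"] or link.pharmacological_action == "yes"
    candidates = [
        DrugCandidate(
            drug_id=drug_id,
            drug_name=d["name"],
            target_genes=frozenset(d["targets"]),
            pharm_action_any=d["pharm"],
        )
        for drug_id, d in by_drug.items()
    ]
    return sorted(candidates, key=lambda c: (c.drug_name.lower(), c.drug_id))


def classify_drug_status(
    candidate: DrugCandidate,
    approvals: pd.DataFrame,
    registry: list[TrialRecord],
    condition: str = DEFAULT_CONDITION,
) -> DrugCandidate:
    """Assign the candidate's triage status for the condition.

    Approval matching: normalized drug name equal and condition substring
    match (case-insensitive).  Trial matching likewise; all matched NCT ids
    are recorded as evidence, sorted.
    """
    if not condition:
        raise ValueError("condition must be non-empty")
    cond = condition.strip().lower()
    name = normalize_drug_name(candidate.drug_name)

    approval_ids = []
    for row in approvals.itertuples(index=False):
        if (
            normalize_drug_name(row.drug_name) == name
            and cond in str(row.condition).lower()
        ):
            approval_ids.append(getattr(row, "approval_id", "") or "approval")
    if approval_ids:
        return replace(candidate, status=STATUS_APPROVED, evidence=tuple(sorted(approval_ids)))

    nct_ids = sorted(
        t.nct_id
        for t in registry
        if normalize_drug_name(t.drug_name) == name and cond in t.condition.lower()
    )
    if nct_ids:
        return replace(candidate, status=STATUS_IN_TRIAL, evidence=tuple(nct_ids))
    return replace(candidate, status=STATUS_NOVEL, evidence=())


def classify_all(
    candidates: list[DrugCandidate],
    approvals: pd.DataFrame,
    registry: list[TrialRecord],
    condition: str = DEFAULT_CONDITION,
) -> list[DrugCandidate]:
    return [classify_drug_status(c, approvals, registry, condition) for c in candidates]


def partition_candidates(
    candidates: list[DrugCandidate],
) -> tuple[dict[str, int], dict[str, list[DrugCandidate]]]:
    """Counts and per-status drug lists (sorted by drug name).

    Every candidate must already be classified; counts sum to the total.
    """
    counts = {s: 0 for s in STATUSES}
    lists: dict[str, list[DrugCandidate]] = {s: [] for s in STATUSES}
    for c in candidates:
        if c.status not in STATUSES:
            raise ValueError(f"unclassified candidate {c.drug_name!r}")
        counts[c.status] += 1
        lists[c.status].append(c)
    for s in STATUSES:
        lists[s].sort(key=lambda c: (c.drug_name.lower(), c.drug_id))
    assert sum(counts.values()) == len(candidates)
    return counts, lists
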