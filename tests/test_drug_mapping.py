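"""Drug-target overlap and clinical-status triage."""

import pandas as pd
import pytest

from gw2drug import drug_mapping as dm
from gw2drug.io_formats import DrugTargetLink, TrialRecord


def _link(drug_id, name, gene, pa="unknown"):
    return DrugTargetLink(drug_id, name, gene, pa, frozenset({"approved"}))


EMPTY_APPROVALS = pd.DataFrame(columns=["drug_name", "condition", "approval_id"])


class TestMapDrugs:
    def test_one_drug_two_expanded_targets(self):
        links = [_link("DB1", "alpha", "G1"), _link("DB1", "alpha", "G2"),
                 _link("DB1", "alpha", "G9")]
        (cand,) = dm.map_drugs({"G1", "G2"}, links)
        assert cand.target_genes == {"G1", "G2"}

    def test_drug_with_no_expanded_target_absent(self):
        links = [_link("DB1", "alpha", "G9")]
        assert dm.map_drugs({"G1"}, links) == []

    def test_gene_match_case_insensitive(self):
        (cand,) = dm.map_drugs({"hdac2"}, [_link("DB1", "alpha", "HDAC2")])
        assert cand.target_genes == {"HDAC2"}

    def test_pharm_action_flag_and_strict_mode(self):
        links = [_link("DB1", "alpha", "G1", "no"), _link("DB1", "alpha", "G2", "yes")]
        (cand,) = dm.map_drugs({"G1", "G2"}, links)
        assert cand.pharm_action_any
        (strict,) = dm.map_drugs({"G1", "G2"}, links, pharm_action_only=True)
        assert strict.target_genes == {"G2"}

    def test_matches_brute_force_join(self, rng):
        genes = [f"G{i}" for i in range(20)]
        expanded = set(rng.choice(genes, size=7, replace=False))
        links = [
            _link(f"DB{int(d)}", f"drug{int(d)}", genes[int(g)])
            for d, g in zip(rng.integers(0, 10, 80), rng.integers(0, 20, 80))
        ]
        got = {
            (c.drug_id, g) for c in dm.map_drugs(expanded, links)
            for g in c.target_genes
        }
        brute = {
            (l.drug_id, l.target_gene) for l in links if l.target_gene in expanded
        }
        assert got == brute


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Vorinostat", "vorinostat"),
            ("  belinostat  ", "belinostat"),
            ("cmpd001 hydrochloride", "cmpd001"),
            ("drug sodium phosphate", "drug"),
            ("sodium", "sodium"),  # lone token is the name itself
        ],
    )
    def test_salt_suffix_stripping(self, raw, expected):
        assert dm.normalize_drug_name(raw) == expected


class TestClassification:
    def _cand(self, name="alpha"):
        return dm.DrugCandidate("DB1", name, frozenset({"G1"}))

    def test_approval_row_wins(self):
        approvals = pd.DataFrame(
            [{"drug_name": "Alpha", "condition": "Multiple Myeloma",
              "approval_id": "A1"}]
        )
        registry = [TrialRecord("NCT00000001", "alpha", "Multiple Myeloma")]
        out = dm.classify_drug_status(self._cand(), approvals, registry)
        assert out.status == dm.STATUS_APPROVED
        assert out.evidence == ("A1",)

    def test_trial_match_records_nct_ids(self):
        registry = [
            TrialRecord("NCT00000002", "alpha hydrochloride", "Multiple Myeloma (MM)"),
            TrialRecord("NCT00000003", "alpha", "refractory multiple myeloma"),
            TrialRecord("NCT00000004", "alpha", "Psoriasis"),
            TrialRecord("NCT00000005", "other", "Multiple Myeloma"),
        ]
        out = dm.classify_drug_status(self._cand(), EMPTY_APPROVALS, registry)
        assert out.status == dm.STATUS_IN_TRIAL
        assert out.evidence == ("NCT00000002", "NCT00000003")

    def test_no_evidence_is_novel(self):
        out = dm.classify_drug_status(self._cand(), EMPTY_APPROVALS, [])
        assert out.status == dm.STATUS_NOVEL and out.evidence == ()

    def test_approval_for_other_condition_does_not_count(self):
        approvals = pd.DataFrame(
            [{"drug_name": "alpha", "condition": "Psoriasis", "approval_id": "A1"}]
        )
        out = dm.classify_drug_status(self._cand(), approvals, [])
        assert out.status == dm.STATUS_NOVEL

    def test_adding_a_trial_never_demotes_an_approved_drug(self):
        approvals = pd.DataFrame(
            [{"drug_name": "alpha", "condition": "multiple myeloma",
              "approval_id": "A1"}]
        )
        before = dm.classify_drug_status(self._cand(), approvals, [])
        after = dm.classify_drug_status(
            self._cand(), approvals,
            [TrialRecord("NCT00000009", "alpha", "Multiple Myeloma")],
        )
        assert before.status == after.status == dm.STATUS_APPROVED

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            dm.classify_drug_status(self._cand(), EMPTY_APPROVALS, [], condition="")


class TestPartition:
    def test_counts_sum_and_recount(self, rng):
        statuses = [dm.STATUSES[int(i)] for i in rng.integers(0, 3, 30)]
        cands = [
            dm.DrugCandidate(f"DB{i}", f"drug{i}", frozenset({"G1"}), status=s)
            for i, s in enumerate(statuses)
        ]
        counts, lists = dm.partition_candidates(cands)
        assert sum(counts.values()) == 30
        for s in dm.STATUSES:
            assert counts[s] == statuses.count(s) == len(lists[s])
            names = [c.drug_name for c in lists[s]]
            assert names == sorted(names)

    def test_empty_input(self):
        counts, lists = dm.partition_candidates([])
        assert counts == {s: 0 for s in dm.STATUSES}
        assert all(v == [] for v in lists.values())

    def test_unclassified_candidate_fatal(self):
        with pytest.raises(ValueError, match="unclassified"):
            dm.partition_candidates(
                [dm.DrugCandidate("DB1", "alpha", frozenset({"G1"}))]
            )


class TestPublishedDrugEvidence:
    """Triage of the drug-evidence fixture from the published worked example."""

    def test_panobinostat_is_the_sole_approved_drug(self, drug_fixture):
        links, approvals, trials = drug_fixture
        cands = dm.map_drugs({"CAMLG", "HDAC2"}, links)
        classified = dm.classify_all(cands, approvals, trials)
        counts, lists = dm.partition_candidates(classified)
        assert counts[dm.STATUS_APPROVED] == 1
        assert lists[dm.STATUS_APPROVED][0].drug_name == "panobinostat"

    def test_four_in_trial_drugs_carry_printed_nct_ids(self, drug_fixture):
        links, approvals, trials = drug_fixture
        classified = dm.classify_all(
            dm.map_drugs({"CAMLG", "HDAC2"}, links), approvals, trials
        )
        _, lists = dm.partition_candidates(classified)
        evidence = {c.drug_name: c.evidence for c in lists[dm.STATUS_IN_TRIAL]}
        assert evidence == {
            "cyclosporine": ("NCT04813653",),
            "belinostat": ("NCT00131261",),
            "vorinostat": ("NCT01502085",),
            "romidepsin": ("NCT00765102",),
        }

    def test_remaining_named_drugs_are_novel(self, drug_fixture):
        links, approvals, trials = drug_fixture
        classified = dm.classify_all(
            dm.map_drugs({"CAMLG", "HDAC2"}, links), approvals, trials
        )
        _, lists = dm.partition_candidates(classified)
        novel = {c.drug_name for c in lists[dm.STATUS_NOVEL]}
        assert novel == {"theophylline", "aminophylline", "oxtriphylline", "tixocortol"}
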