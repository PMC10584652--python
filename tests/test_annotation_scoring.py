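"""Six-criterion scoring, hypergeometric enrichment, risk-gene calls."""

from fractions import Fraction
from math import comb

import pandas as pd
import pytest
import scipy.stats as st_scipy
from hypothesis import given, settings
from hypothesis import strategies as st

from gw2drug import annotation_scoring as sc
from gw2drug.io_formats import LinkedVariant
from gw2drug.ld_expansion import GeneProxies, GeneRecord


def exact_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Full-support enumeration oracle for the upper-tail probability."""
    lo, hi = max(0, n - (N - K)), min(K, n)
    return sum(
        (Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
         for i in range(max(k, lo), hi + 1)),
        Fraction(0),
    )


class TestHypergeometricTail:
    def test_k_zero_is_whole_support(self):
        assert sc.hypergeometric_tail(0, 4, 3, 10) == 1.0

    def test_k_beyond_support_is_zero(self):
        assert sc.hypergeometric_tail(4, 4, 3, 10) == 0.0
        assert sc.hypergeometric_tail(5, 4, 8, 10) == 0.0

    def test_worked_example_is_one_third(self):
        # sum_{i>=2} C(4,i) C(6,3-i) / C(10,3) = (6*6 + 4*1)/120 = 1/3
        assert exact_tail(2, 4, 3, 10) == Fraction(1, 3)
        assert sc.hypergeometric_tail(2, 4, 3, 10) == pytest.approx(1 / 3, rel=1e-14)

    @pytest.mark.parametrize("N", [10, 25, 60])
    def test_matches_enumeration_exactly(self, N):
        for K in range(N + 1):
            for n in range(0, N + 1, 3):
                for k in range(min(K, n) + 2):
                    got = sc.hypergeometric_tail(k, K, n, N)
                    want = float(exact_tail(k, K, n, N))
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-15)

    def test_matches_scipy_survival_function_at_scale(self, rng):
        """Independent cross-check against scipy's hypergeom.sf at N ≤ 1000."""
        for _ in range(300):
            N = int(rng.integers(1, 1001))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 2))
            assert sc.hypergeometric_tail(k, K, n, N) == pytest.approx(
                float(st_scipy.hypergeom.sf(k - 1, N, K, n)), rel=1e-9, abs=1e-13
            )

    def test_non_increasing_in_k(self):
        for K, n, N in [(4, 3, 10), (10, 10, 30), (7, 15, 40)]:
            tails = [sc.hypergeometric_tail(k, K, n, N) for k in range(min(K, n) + 2)]
            assert all(a >= b for a, b in zip(tails, tails[1:]))

    def test_invalid_parameters_fatal(self):
        with pytest.raises(ValueError):
            sc.hypergeometric_tail(1, 11, 3, 10)
        with pytest.raises(ValueError):
            sc.hypergeometric_tail(-1, 2, 3, 10)


def _gene(gid="ENSG1", sym="G1"):
    return GeneRecord(gencode_id=gid, gene_symbol=sym)


def _proxy(gene, cons="intronic", rsid="rsp1"):
    return LinkedVariant(query_rsid="rs1", proxy_rsid=rsid, r_squared=0.9,
                         gencode_id=gene.gencode_id, gene_symbol=gene.gene_symbol,
                         consequence=cons)


class TestFlags:
    def test_missense_requires_a_missense_proxy_in_the_gene(self):
        g = _gene()
        assert sc.flag_missense(g, (_proxy(g, "missense"),)) == 1
        assert sc.flag_missense(g, (_proxy(g, "intronic"), _proxy(g, "utr3"))) == 0

    def test_missense_ignores_proxies_of_other_genes(self):
        g, other = _gene(), _gene("ENSG2", "G2")
        assert sc.flag_missense(g, (_proxy(other, "missense"),)) == 0

    def test_cis_eqtl_requires_blood_tissue_and_significance(self):
        g = _gene()
        proxies = (_proxy(g, rsid="rs42"),)
        base = {"rsid": "rs42", "gencode_id": "ENSG1"}
        eqtl = pd.DataFrame([
            {**base, "tissue": "Liver", "significant": "yes"},
            {**base, "tissue": "Whole_Blood", "significant": "no"},
        ])
        assert sc.flag_cis_eqtl(g, proxies, eqtl) == 0
        eqtl2 = pd.DataFrame([{**base, "tissue": "Whole_Blood", "significant": "yes"}])
        assert sc.flag_cis_eqtl(g, proxies, eqtl2) == 1

    def test_cis_eqtl_requires_the_record_to_hit_a_proxy(self):
        g = _gene()
        eqtl = pd.DataFrame([{"rsid": "rs_not_a_proxy", "gencode_id": "ENSG1",
                              "tissue": "Whole_Blood", "significant": "yes"}])
        assert sc.flag_cis_eqtl(g, (_proxy(g, rsid="rs42"),), eqtl) == 0

    def test_go_flag_needs_an_enriched_term_containing_the_gene(self):
        g = _gene()
        membership = pd.DataFrame([
            {"term_id": "GO:1", "category": "BP", "gencode_id": "ENSG1"},
            {"term_id": "GO:2", "category": "BP", "gencode_id": "ENSG1"},
        ])
        enr_hit = [sc.EnrichmentResult("GO:1", "BP", 1, 1, 5, 20000, 0.01)]
        enr_miss = [sc.EnrichmentResult("GO:2", "BP", 1, 40, 5, 20000, 0.30)]
        assert sc.flag_go_category(g, enr_hit, membership, "BP") == 1
        assert sc.flag_go_category(g, enr_miss, membership, "BP") == 0

    def test_go_flag_respects_category(self):
        g = _gene()
        membership = pd.DataFrame(
            [{"term_id": "GO:1", "category": "CC", "gencode_id": "ENSG1"}]
        )
        enr = [sc.EnrichmentResult("GO:1", "CC", 1, 1, 5, 20000, 0.01)]
        assert sc.flag_go_category(g, enr, membership, "CC") == 1
        assert sc.flag_go_category(g, enr, membership, "BP") == 0

    def test_pid_flag_is_case_insensitive(self):
        g = GeneRecord("ENSG00000240505", "TNFRSF13B")
        assert sc.flag_pid(g, {"TNFRSF13B"}) == 1
        assert sc.flag_pid(g, {"tnfrsf13b"}) == 1
        assert sc.flag_pid(g, {"BTK"}) == 0

    def test_bh_correction_is_monotone_and_conservative(self):
        """BH-adjusted p-values never fall below the raw ones and preserve
        their within-category ordering."""
        membership = pd.DataFrame(
            [{"term_id": f"GO:{t}", "category": "BP", "gencode_id": g}
             for t, genes in enumerate([["A"], ["A", "B"], ["X", "Y", "Z"]])
             for g in genes]
        )
        raw = sc.enrich_terms({"A", "B"}, membership, background_n=50)
        adj = sc.enrich_terms({"A", "B"}, membership, background_n=50,
                              correction="bh")
        raw_p = {e.term_id: e.p_value for e in raw}
        adj_p = {e.term_id: e.p_value for e in adj}
        assert set(raw_p) == set(adj_p)
        for tid in raw_p:
            assert adj_p[tid] >= raw_p[tid] - 1e-15
        ordered = sorted(raw_p, key=raw_p.get)
        assert sorted(ordered, key=adj_p.get) == ordered

    def test_enrich_terms_counts(self):
        membership = pd.DataFrame([
            {"term_id": "GO:1", "category": "BP", "gencode_id": g}
            for g in ("A", "B", "C", "D")
        ])
        (res,) = sc.enrich_terms({"A", "B", "X"}, membership, background_n=10)
        assert (res.k, res.K, res.n, res.N) == (2, 4, 3, 10)
        assert res.p_value == pytest.approx(1 / 3, rel=1e-12)


class TestScoring:
    def _scores(self, flag_rows, threshold=2):
        genes = [_gene(f"ENSG{i}", f"G{i}") for i in range(len(flag_rows))]
        flags = {
            g.gencode_id: sc.AnnotationFlags(**dict(zip(sc.FLAG_ORDER, row)))
            for g, row in zip(genes, flag_rows)
        }
        return sc.score_genes(genes, flags, threshold)

    def test_total_is_flag_sum_and_risk_at_threshold(self):
        scores = self._scores([(1, 1, 1, 1, 1, 0), (0, 0, 0, 0, 0, 0),
                               (1, 0, 0, 0, 0, 1)])
        by_id = {s.gene.gencode_id: s for s in scores}
        assert by_id["ENSG0"].total == 5 and by_id["ENSG0"].is_risk
        assert by_id["ENSG1"].total == 0 and not by_id["ENSG1"].is_risk
        assert by_id["ENSG2"].total == 2 and by_id["ENSG2"].is_risk

    def test_ranking_descending_total_then_gencode_id(self):
        scores = self._scores([(0, 1, 1, 0, 0, 0), (1, 1, 1, 1, 0, 0),
                               (0, 0, 1, 1, 0, 0)])
        assert [s.gene.gencode_id for s in scores] == ["ENSG1", "ENSG0", "ENSG2"]

    def test_threshold_above_maximum_returns_empty(self):
        scores = self._scores([(1, 1, 1, 1, 1, 1)])
        assert sc.call_risk_genes(scores, 7) == []

    def test_risk_sets_nest_in_threshold(self):
        scores = self._scores(
            [(1, 1, 1, 1, 1, 0), (1, 1, 1, 0, 0, 0), (1, 1, 0, 0, 0, 0),
             (1, 0, 0, 0, 0, 0), (0, 0, 0, 0, 0, 0)]
        )
        for t in range(6):
            hi = {s.gene.gencode_id for s in sc.call_risk_genes(scores, t + 1)}
            lo = {s.gene.gencode_id for s in sc.call_risk_genes(scores, t)}
            assert hi <= lo


@settings(derandomize=True, max_examples=60)
@given(
    flags=st.tuples(*[st.integers(0, 1)] * 6),
    idx=st.integers(0, 5),
)
def test_setting_a_flag_never_decreases_total_or_rank(flags, idx):
    """Flipping any flag 0→1 can only raise a gene's total and its rank."""
    raised = list(flags)
    raised[idx] = 1
    f0 = sc.AnnotationFlags(**dict(zip(sc.FLAG_ORDER, flags)))
    f1 = sc.AnnotationFlags(**dict(zip(sc.FLAG_ORDER, raised)))
    assert f1.total >= f0.total
    g = GeneRecord("ENSG1", "G1")
    s0 = sc.GeneScore(g, f0, f0.total, f0.total >= 2)
    s1 = sc.GeneScore(g, f1, f1.total, f1.total >= 2)
    assert sc.rank_key(s1) <= sc.rank_key(s0)


class TestPublishedMatrix:
    """Reproduction of the published 14 x 6 annotation matrix."""

    def test_all_totals_match_printed_column(self, table1):
        flag_cols = ["Missense", "Cis-eQTL", "Biological process",
                     "Cellular component", "Molecular function", "PID"]
        assert (table1[flag_cols].sum(axis=1) == table1["Total score"]).all()

    def test_scoring_reproduces_printed_totals_and_order(self, table1, table1_scores_input):
        genes, flags = table1_scores_input
        scores = sc.score_genes(genes, flags, 2)
        assert [s.gene.gene_symbol for s in scores] == list(table1["GENCODE_name"])
        assert [s.total for s in scores] == list(table1["Total score"])

    def test_named_flag_examples(self, table1_scores_input):
        _, flags = table1_scores_input
        assert flags["ENSG00000168411"].missense == 1       # RFWD3
        assert flags["ENSG00000164649"].missense == 0       # CDCA7L
        assert flags["ENSG00000100281"].cis_eqtl == 0       # HMGXB4
        assert flags["ENSG00000204525"].cis_eqtl == 1       # HLA-C
        assert flags["ENSG00000025770"].go_bp == 1          # NCAPH2
        assert flags["ENSG00000025770"].go_mf == 0
        assert flags["ENSG00000240505"].pid == 1            # TNFRSF13B

    def test_risk_calls_at_all_printed_thresholds(self, table1_scores_input):
        genes, flags = table1_scores_input
        scores = sc.score_genes(genes, flags, 2)
        assert len(sc.call_risk_genes(scores, 2)) == 14
        top = sc.call_risk_genes(scores, 3)
        assert [s.gene.gene_symbol for s in top] == ["RFWD3", "HMGXB4", "CDCA7L", "CCHCR1"]
        assert [s.gene.gene_symbol for s in sc.call_risk_genes(scores, 5)] == ["RFWD3"]
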