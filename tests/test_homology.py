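import numpy as np
import pytest

from strainkit.homology import (
    MissingTaxonomyError,
    AlignmentHit,
    SearchParams,
    WordSizeError,
    call_orthologs,
    classify_hgt,
    search,
    summarize_hgt,
)
from strainkit.io_formats import TaxonomyLabel

from .oracles import smith_waterman_affine


def _random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


def _mutated_copy(rng, seq, rate):
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        else:
            out.append(c)
    return "".join(out)


class TestSearch:
    def test_self_hit_is_perfect(self):
        rng = np.random.default_rng(0)
        gene = _random_seq(rng, 300)
        hits = search([("g1", gene)], [("g1", gene)], SearchParams(alphabet="nt"))
        assert hits and hits[0].is_self
        assert hits[0].percent_identity == 100.0
        assert hits[0].query_coverage == 1.0
        assert hits[0].e_value <= 1e-5

    def test_no_shared_word_no_hits(self):
        # query of pure A/C words, database of pure G/T: no 11-mer can be shared
        hits = search([("q", "AC" * 100)], [("s", "GT" * 100)], SearchParams(alphabet="nt"))
        assert hits == []

    def test_word_size_longer_than_sequences_rejected(self):
        with pytest.raises(WordSizeError):
            search([("q", "ACGTA")], [("s", "ACGTA")], SearchParams(alphabet="nt"))

    def test_raw_score_equals_dynamic_programming_oracle(self):
        # every reported hit's raw score must equal the full Smith-Waterman
        # score of that pair (no seeding loss above the word threshold)
        rng = np.random.default_rng(42)
        params = SearchParams(alphabet="nt")
        for i in range(20):
            n = int(rng.integers(100, 301))
            a = _random_seq(rng, n)
            b = _mutated_copy(rng, a, 0.15)
            hits = search([(f"q{i}", a)], [(f"s{i}", b)], params)
            assert hits, "mutated copy must be found"
            expected = smith_waterman_affine(a, b, params.match, params.mismatch,
                                             params.open_gap, params.extend_gap)
            assert hits[0].raw_score == pytest.approx(expected)

    def test_hits_sorted_by_bit_score_within_query(self):
        rng = np.random.default_rng(3)
        gene = _random_seq(rng, 300)
        db = [("near", _mutated_copy(rng, gene, 0.02)),
              ("far", _mutated_copy(rng, gene, 0.20))]
        hits = search([("q", gene)], db, SearchParams(alphabet="nt"))
        assert [h.subject_id for h in hits] == ["near", "far"]


class TestCallOrthologs:
    def _hits(self, pairs):
        """Hand-built hit list: (query, subject, bit) with tiny e-values."""
        return [AlignmentHit(q, s, 99.0, 100, 1, 0, 0, 100, 0, 100, bit, bit, 1e-30, 1.0)
                for q, s, bit in pairs]

    def test_identical_gene_sets_all_rbh(self):
        rng = np.random.default_rng(1)
        genes_a = [(f"a{i}", _random_seq(rng, 240)) for i in range(10)]
        genes_b = [(f"b{i}", seq) for i, (_, seq) in enumerate(genes_a)]
        params = SearchParams(alphabet="nt")
        pairs, spec_a, spec_b = call_orthologs(
            search(genes_a, genes_b, params), search(genes_b, genes_a, params),
            genes_a=[g for g, _ in genes_a], genes_b=[g for g, _ in genes_b])
        assert len(pairs) == 10
        assert spec_a == [] and spec_b == []
        assert {(p.gene_a, p.gene_b) for p in pairs} == {(f"a{i}", f"b{i}")
                                                         for i in range(10)}

    def test_extra_gene_without_homolog_is_specific(self):
        rng = np.random.default_rng(2)
        shared = _random_seq(rng, 240)
        genes_a = [("a0", shared), ("a_extra", _random_seq(rng, 240))]
        genes_b = [("b0", shared)]
        params = SearchParams(alphabet="nt")
        pairs, spec_a, spec_b = call_orthologs(
            search(genes_a, genes_b, params), search(genes_b, genes_a, params),
            genes_a=["a0", "a_extra"], genes_b=["b0"])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a0", "b0")]
        assert spec_a == ["a_extra"] and spec_b == []

    def test_duplicated_gene_tie_breaks_to_one_pair(self):
        # genome A holds two identical copies a1, a2; genome B one copy b.
        # b's best hit ties and resolves lexicographically to a1; exactly
        # one reciprocal pair results (hand-enumerated hit table).
        hits_ab = self._hits([("a1", "b", 50.0), ("a2", "b", 50.0)])
        hits_ba = self._hits([("b", "a1", 50.0), ("b", "a2", 50.0)])
        pairs, spec_a, spec_b = call_orthologs(hits_ab, hits_ba,
                                               genes_a=["a1", "a2"], genes_b=["b"])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b")]
        # a2 has hits, so it is not specific despite losing the tie
        assert spec_a == [] and spec_b == []

    def test_rbh_symmetry(self):
        rng = np.random.default_rng(7)
        genes_a = [(f"a{i}", _random_seq(rng, 200)) for i in range(6)]
        genes_b = [(f"b{i}", _mutated_copy(rng, seq, 0.05))
                   for i, (_, seq) in enumerate(genes_a)]
        params = SearchParams(alphabet="nt")
        hits_ab = search(genes_a, genes_b, params)
        hits_ba = search(genes_b, genes_a, params)
        pairs_fwd, _, _ = call_orthologs(hits_ab, hits_ba)
        pairs_rev, _, _ = call_orthologs(hits_ba, hits_ab)
        assert {(p.gene_a, p.gene_b) for p in pairs_fwd} == \
            {(p.gene_b, p.gene_a) for p in pairs_rev}

    def test_empty_inputs_make_all_genes_specific(self):
        pairs, spec_a, spec_b = call_orthologs([], [], genes_a=["a0"], genes_b=["b0"])
        assert pairs == [] and spec_a == ["a0"] and spec_b == ["b0"]


class TestClassifyHgt:
    TAX = {
        "f1": TaxonomyLabel("f1", "Sphingobacteriales", "Bacteroidetes"),
        "o1": TaxonomyLabel("o1", "Flavobacteriales", "Bacteroidetes"),
        "o2": TaxonomyLabel("o2", "Cytophagales", "Bacteroidetes"),
    }

    def _hit(self, subject, bit=50.0):
        return AlignmentHit("g", subject, 95.0, 100, 5, 0, 0, 100, 0, 100, bit, bit,
                            1e-20, 1.0)

    def test_all_hits_outside_focal_order_is_hgt(self):
        call = classify_hgt("g", [self._hit("o1", 60.0), self._hit("o2", 40.0)],
                            self.TAX, "Sphingobacteriales")
        assert call.is_hgt
        assert call.donor_order == "Flavobacteriales"   # order of the best hit

    def test_single_focal_hit_negates_hgt(self):
        call = classify_hgt("g", [self._hit("o1", 60.0), self._hit("f1", 10.0)],
                            self.TAX, "Sphingobacteriales")
        assert not call.is_hgt and call.donor_order is None

    def test_zero_hits_is_not_hgt(self):
        call = classify_hgt("g", [], self.TAX, "Sphingobacteriales")
        assert not call.is_hgt and call.n_hits == 0

    def test_excluded_subjects_are_ignored(self):
        call = classify_hgt("g", [self._hit("f1", 90.0), self._hit("o1", 50.0)],
                            self.TAX, "Sphingobacteriales", exclude_subjects={"f1"})
        assert call.is_hgt and call.donor_order == "Flavobacteriales"

    def test_missing_taxonomy_raises(self):
        with pytest.raises(MissingTaxonomyError):
            classify_hgt("g", [self._hit("unknown")], self.TAX, "Sphingobacteriales")


class TestSummarizeHgt:
    def test_no_hgt_gives_empty_tables(self):
        calls = [classify_hgt("g", [], TestClassifyHgt.TAX, "Sphingobacteriales")]
        orders, cats = summarize_hgt(calls, {})
        assert orders.empty and cats.empty

    def test_order_histogram_and_percentages(self):
        from strainkit.homology import HgtCall
        calls = ([HgtCall(f"g{i}", True, "Flavobacteriales") for i in range(3)]
                 + [HgtCall("g3", True, "Cytophagales")]
                 + [HgtCall("g4", False)])
        categories = {"g0": "K", "g1": "K", "g2": "B", "g3": "B"}
        orders, cats = summarize_hgt(calls, categories)
        assert list(orders.itertuples(index=False, name=None)) == [
            ("Flavobacteriales", 3), ("Cytophagales", 1)]
        assert cats["percent"].sum() == pytest.approx(100.0)
        assert set(cats["category"]) == {"K", "B"}
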