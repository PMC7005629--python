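"""Evidence lexicon matching, DTM subsetting, and variant-evidence association."""

import pytest

from mtmine import build_dtm, ingest, preprocess
from mtmine.evidence import (
    CATEGORIES,
    EvidenceLexicon,
    LexiconError,
    apply_audit,
    apply_multiple_reports_rule,
    associate,
    subset_dtm,
    write_association_tsv,
)


def _corpus(reference, texts):
    return [preprocess(ingest(f"p{i}", t, reference)) for i, t in enumerate(texts)]


class TestLexicon:
    def test_default_covers_minable_criteria(self, lexicon):
        assert set(lexicon.categories) == set(CATEGORIES)
        # conservation criteria are computed, never mined
        assert "phastcons" not in " ".join(c for c in lexicon.categories)

    def test_empty_lexicon_rejected(self):
        with pytest.raises(LexiconError):
            EvidenceLexicon({})

    def test_uppercase_pattern_rejected(self):
        with pytest.raises(LexiconError):
            EvidenceLexicon({"heteroplasmy": ("Heteroplasmy",)})

    def test_prefix_wildcard(self, lexicon):
        hits = lexicon.match_tokens(["heteroplasmic", "heteroplasmy", "other"])
        assert hits == {"heteroplasmy": 2}

    def test_phrase_matching_needs_adjacency(self, lexicon):
        assert lexicon.match_tokens(["respiratory", "chain"]) == {"biochemistry_oxphos": 1}
        assert lexicon.match_tokens(["respiratory", "gap", "chain"]) == {}

    def test_match_text_on_raw_abstract(self, lexicon):
        hits = lexicon.match_text("Transmitochondrial cybrids showed a defect.")
        assert "cybrid_steadystate" in hits


class TestSubsetDtm:
    def test_variant_and_evidence_hits(self, reference, lexicon):
        docs = _corpus(reference, ["m.8839G>C in cybrids", "no signal here"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assert vhits.to_records(index=False).tolist() == [("p0", "m.8839G>C", 1)]
        assert ("p0", "cybrid_steadystate", 1) in ehits.to_records(index=False).tolist()
        assert not (ehits.doc_id == "p1").any()

    def test_no_variant_columns(self, reference, lexicon):
        docs = _corpus(reference, ["just words myopathy"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assert vhits.empty
        assert ehits.iloc[0].category == "disease_phenotype"

    def test_empty_lexicon_is_misconfiguration(self, reference):
        docs = _corpus(reference, ["words"])
        dtm = build_dtm(docs)
        hollow = EvidenceLexicon.__new__(EvidenceLexicon)
        object.__setattr__(hollow, "categories", {"heteroplasmy": ()})
        with pytest.raises(LexiconError):
            subset_dtm(dtm, hollow, [])


class TestAssociate:
    def test_one_variant_two_categories(self, reference, lexicon):
        docs = _corpus(reference, ["m.8839G>C with heteroplasmy and myopathy"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assocs = associate(docs, vhits, ehits)
        cats = {a.category for a in assocs}
        assert {"heteroplasmy", "disease_phenotype"} <= cats
        assert all(a.supporting_docs == ("p0",) for a in assocs)
        assert all("m.8839G" in a.snippets["p0"] for a in assocs)

    def test_variant_without_evidence_yields_nothing(self, reference, lexicon):
        docs = _corpus(reference, ["m.8839G>C alone in text"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assert associate(docs, vhits, ehits) == []

    def test_same_pair_in_two_docs_groups(self, reference, lexicon):
        texts = ["m.8839G>C and myopathy", "again m.8839G>C with myopathy"]
        docs = _corpus(reference, texts)
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assocs = [a for a in associate(docs, vhits, ehits)
                  if a.category == "disease_phenotype"]
        assert len(assocs) == 1
        assert assocs[0].supporting_docs == ("p0", "p1")

    def test_window_widening_is_monotone(self, reference, lexicon):
        filler = " ".join(["filler"] * 30)
        texts = [
            f"m.8839G>C heteroplasmy nearby",
            f"m.8993T>G {filler} myopathy far away",
        ]
        docs = _corpus(reference, texts)
        dtm = build_dtm(docs)
        terms = ["m.8839G>C", "m.8993T>G"]
        vhits, ehits = subset_dtm(dtm, lexicon, terms, documents=docs)
        narrow = associate(docs, vhits, ehits, window=3, lexicon=lexicon)
        wide = associate(docs, vhits, ehits, window=100, lexicon=lexicon)
        doc_scope = associate(docs, vhits, ehits)
        def pairs(assocs):
            return {(a.hgvs, a.category, d) for a in assocs for d in a.supporting_docs}
        assert pairs(narrow) <= pairs(wide) <= pairs(doc_scope)
        assert ("m.8993T>G", "disease_phenotype", "p1") not in pairs(narrow)
        assert ("m.8993T>G", "disease_phenotype", "p1") in pairs(doc_scope)

    def test_association_members_present_in_dtm(self, reference, lexicon):
        texts = ["m.8839G>C cybrids", "m.8993T>G segregation", "nothing"]
        docs = _corpus(reference, texts)
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C", "m.8993T>G"], documents=docs)
        for a in associate(docs, vhits, ehits):
            for d in a.supporting_docs:
                assert dtm.count(d, a.hgvs) > 0


class TestMultipleReportsRule:
    def _assoc(self, reference, lexicon, texts):
        docs = _corpus(reference, texts)
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        return associate(docs, vhits, ehits)

    def test_two_distinct_docs_true(self, reference, lexicon):
        assocs = self._assoc(
            reference, lexicon, ["m.8839G>C myopathy", "m.8839G>C syndrome"]
        )
        assert apply_multiple_reports_rule(assocs)["m.8839G>C"] is True

    def test_single_doc_false(self, reference, lexicon):
        assocs = self._assoc(reference, lexicon, ["m.8839G>C myopathy"])
        assert apply_multiple_reports_rule(assocs)["m.8839G>C"] is False

    def test_nonasserting_categories_do_not_count(self, reference, lexicon):
        assocs = self._assoc(
            reference, lexicon, ["m.8839G>C heteroplasmy", "m.8839G>C segregation"]
        )
        assert apply_multiple_reports_rule(assocs)["m.8839G>C"] is False


class TestAudit:
    def test_rejected_association_excluded_from_rule(self, reference, lexicon):
        docs = _corpus(reference, ["m.8839G>C myopathy", "m.8839G>C syndrome"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assocs = associate(docs, vhits, ehits)
        audited = apply_audit(assocs, {("m.8839G>C", "disease_phenotype"): "rejected"})
        assert apply_multiple_reports_rule(audited)["m.8839G>C"] is False

    def test_audit_tsv(self, reference, lexicon, tmp_path):
        docs = _corpus(reference, ["m.8839G>C myopathy"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assocs = associate(docs, vhits, ehits)
        audit = tmp_path / "audit.tsv"
        audit.write_text("hgvs\tcategory\tdecision\nm.8839G>C\tdisease_phenotype\tconfirmed\n")
        audited = apply_audit(assocs, audit)
        flags = {a.category: a.analyst_flag for a in audited}
        assert flags["disease_phenotype"] == "confirmed"

    def test_bad_decision_rejected(self, reference, lexicon):
        docs = _corpus(reference, ["m.8839G>C myopathy"])
        dtm = build_dtm(docs)
        vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
        assocs = associate(docs, vhits, ehits)
        with pytest.raises(ValueError):
            apply_audit(assocs, {("m.8839G>C", "disease_phenotype"): "maybe"})


def test_association_tsv_export(reference, lexicon, tmp_path):
    docs = _corpus(reference, ["m.8839G>C cybrids study"])
    dtm = build_dtm(docs)
    vhits, ehits = subset_dtm(dtm, lexicon, ["m.8839G>C"], documents=docs)
    assocs = associate(docs, vhits, ehits)
    out = tmp_path / "assoc.tsv"
    write_association_tsv(assocs, out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("hgvs\tcategory")
    assert any("cybrid_steadystate" in l for l in lines[1:])
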