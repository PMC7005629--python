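"""Corpus preprocessing, mention protection, and the Document-Term Matrix."""

from collections import Counter

import pytest

from mtmine import build_dtm, ingest, preprocess
from mtmine.corpus import CorpusError, default_stopwords, load_corpus_dir, normalize_text


class TestIngest:
    def test_mentions_scanned_with_offsets(self, reference):
        doc = ingest("p1", "m.8839G > C causes NARP", reference)
        assert len(doc.mentions) == 1
        assert doc.mentions[0].offset == 0
        assert not doc.preprocessed

    def test_empty_document(self, reference):
        doc = ingest("p2", "", reference)
        assert doc.mentions == [] and doc.raw_text == ""

    def test_undecodable_bytes_rejected(self, reference):
        with pytest.raises(CorpusError, match="p3"):
            ingest("p3", b"\xff\xfe\x00bad", reference)

    def test_typographic_characters_normalized(self, reference):
        # the non-ASCII hyphen variants common in extracted PDF text
        doc = ingest("p4", "m.8839G > C and MT‐ATP6", reference)
        assert len(doc.mentions) == 1
        assert doc.mentions[0].hgvs == "m.8839G>C"

    def test_metadata_lines_stripped(self, reference):
        text = "doi:10.1000/xyz\nThe cybrids were heteroplasmic.\nPage 3 of 9\n"
        doc = ingest("p5", text, reference)
        assert "doi" not in doc.raw_text and "Page" not in doc.raw_text
        assert "cybrids" in doc.raw_text


class TestPreprocess:
    def test_stated_cleaning_steps(self, reference):
        doc = ingest("p1", "The cybrids WERE heteroplasmic.", reference)
        assert preprocess(doc).tokens == ["cybrids", "heteroplasmic"]

    def test_mention_survives_cleaning(self, reference):
        doc = ingest("p2", "m.8839G > C segregates", reference)
        assert preprocess(doc).tokens == ["m.8839G>C", "segregates"]

    def test_all_stopword_input(self, reference):
        doc = ingest("p3", "the and of were", reference)
        assert preprocess(doc).tokens == []

    def test_every_complete_mention_becomes_one_term(self, reference):
        text = "We found m.8839G>C, A3243G and 8993G; also m.15990C alone."
        doc = preprocess(ingest("p4", text, reference))
        complete = [m.hgvs for m in doc.mentions if m.status == "complete"]
        for hgvs in complete:
            assert doc.tokens.count(hgvs) == 1

    def test_idempotent_on_clean_streams(self, reference):
        doc = preprocess(ingest("p5", "cybrids m.8839G>C segregates myopathy", reference))
        again = preprocess(ingest("p6", " ".join(doc.tokens), reference))
        assert again.tokens == doc.tokens

    def test_custom_stopwords(self, reference):
        doc = ingest("p7", "alpha beta gamma", reference)
        assert preprocess(doc, stopwords={"beta"}).tokens == ["alpha", "gamma"]

    def test_default_stopword_list_nonempty(self):
        stop = default_stopwords()
        assert {"the", "and", "were", "of"} <= stop


class TestBuildDtm:
    def _docs(self, reference, texts):
        return [preprocess(ingest(f"d{i}", t, reference)) for i, t in enumerate(texts)]

    def test_counts_match_brute_force(self, reference):
        docs = self._docs(reference, ["alpha beta beta", "beta gamma"])
        dtm = build_dtm(docs)
        assert dtm.count("d0", "alpha") == 1
        assert dtm.count("d0", "beta") == 2
        assert dtm.count("d1", "beta") == 1
        assert dtm.count("d1", "gamma") == 1
        assert dtm.count("d0", "gamma") == 0

    def test_row_sums_equal_token_counts(self, reference):
        texts = [
            "cybrids heteroplasmic m.8839G>C myopathy",
            "segregation analysis muscle biopsy m.8839G>C m.8839G>C",
            "",
        ]
        docs = self._docs(reference, texts)
        dtm = build_dtm(docs)
        sums = dtm.counts.sum(axis=1).A1
        for i, doc in enumerate(docs):
            assert sums[i] == len(doc.tokens)

    def test_brute_force_oracle_random_corpus(self, reference):
        import random

        rng = random.Random(42)
        vocab = ["aa", "bb", "cc", "dd", "ee"]
        texts = [" ".join(rng.choices(vocab, k=rng.randint(0, 30))) for _ in range(20)]
        docs = self._docs(reference, texts)
        dtm = build_dtm(docs)
        for i, doc in enumerate(docs):
            expected = Counter(doc.tokens)
            row = dtm.counts[i].toarray().ravel()
            got = {dtm.terms[j]: int(c) for j, c in enumerate(row) if c}
            assert got == dict(expected)

    def test_agrees_with_countvectorizer(self, reference):
        """Independent cross-check against scikit-learn's counting."""
        from sklearn.feature_extraction.text import CountVectorizer

        texts = ["alpha beta beta gamma", "beta gamma gamma delta", "alpha delta"]
        docs = self._docs(reference, texts)
        dtm = build_dtm(docs)
        vec = CountVectorizer(analyzer=str.split)
        ours = {(docs[i].doc_id, t): dtm.count(docs[i].doc_id, t)
                for i in range(len(docs)) for t in dtm.terms}
        X = vec.fit_transform([" ".join(d.tokens) for d in docs])
        names = vec.get_feature_names_out()
        theirs = {(docs[i].doc_id, names[j]): int(X[i, j])
                  for i in range(len(docs)) for j in range(len(names))}
        assert ours == theirs

    def test_empty_corpus(self):
        dtm = build_dtm([])
        assert dtm.counts.shape == (0, 0)

    def test_unpreprocessed_document_rejected(self, reference):
        doc = ingest("p", "some text", reference)
        with pytest.raises(CorpusError):
            build_dtm([doc])

    def test_mtx_export_roundtrip(self, reference, tmp_path):
        import scipy.io

        docs = self._docs(reference, ["alpha beta", "beta"])
        dtm = build_dtm(docs)
        dtm.write_mtx(tmp_path / "dtm")
        back = scipy.io.mmread(str(tmp_path / "dtm.mtx"))
        assert (back.toarray() == dtm.counts.toarray()).all()
        assert (tmp_path / "dtm.terms.txt").read_text().split() == dtm.terms


def test_load_corpus_dir(reference, tmp_path):
    (tmp_path / "111.txt").write_text("m.8839G>C in cybrids")
    (tmp_path / "222.txt").write_text("plain text")
    docs = load_corpus_dir(tmp_path, reference)
    assert [d.doc_id for d in docs] == ["111", "222"]
    assert len(docs[0].mentions) == 1


def test_normalize_text_keeps_body():
    out = normalize_text("body line\nCopyright 2018 Publisher\n")
    assert out.strip() == "body line"
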