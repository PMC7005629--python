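"""Functional-evidence keyword mining and variant-evidence association.

The pathogenicity criteria that can be mined from text (multiple reports,
heteroplasmy, segregation, histochemistry, OXPHOS biochemistry,
cybrid/steady-state studies, single-fiber studies, disease phenotype) are
each backed by a small lexicon of keyword patterns.  The two conservation
criteria (PhastCons, PhyloP) are computed quantities, never mined; they
enter the scoring profile as boolean inputs supplied per variant.

Patterns are lowercase; a trailing ``*`` makes a prefix pattern
(``heteroplasm*`` matches ``heteroplasmy`` and ``heteroplasmic``), and a
pattern containing spaces is a phrase matched against consecutive cleaned
tokens (``respiratory chain``).  The bundled default lexicon is a curated
starting point built from the criterion wording and is fully overridable.

Association is document-scope by default — a variant and a category
co-occurring anywhere in the same document are associated, and a raw-text
snippet around the variant mention is extracted so an analyst can confirm
or reject the pairing (the audit file); a +/-N-token window is available
for stricter pairing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import Document, DocumentTermMatrix

CATEGORIES = (
    "multiple_reports",
    "heteroplasmy",
    "segregation",
    "histochemistry",
    "biochemistry_oxphos",
    "cybrid_steadystate",
    "single_fiber",
    "disease_phenotype",
)

#: categories whose presence asserts pathogenicity (feed the multiple-reports rule)
PATHOGENICITY_ASSERTING = ("disease_phenotype", "multiple_reports")


class LexiconError(ValueError):
    pass


def _clean_pattern_tokens(pattern: str) -> list[str]:
    import re

    return re.sub(r"[^a-z0-9*]+", " ", pattern.lower()).split()


@dataclass(frozen=True)
class EvidenceLexicon:
    """Criterion name -> keyword patterns (prefix ``*`` and phrases allowed)."""

    categories: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.categories or not any(self.categories.values()):
            raise LexiconError("empty lexicon")
        for name, patterns in self.categories.items():
            if name not in CATEGORIES:
                raise LexiconError(f"unknown criterion category {name!r}")
            for p in patterns:
                if p != p.lower():
                    raise LexiconError(f"pattern {p!r} must be lowercase")

    @classmethod
    def default(cls) -> "EvidenceLexicon":
        text = resources.files("mtmine.data").joinpath("lexicon.json").read_text()
        return cls.from_mapping(json.loads(text))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[str]]) -> "EvidenceLexicon":
        return cls({k: tuple(v) for k, v in mapping.items()})

    @classmethod
    def from_json(cls, path: str | Path) -> "EvidenceLexicon":
        return cls.from_mapping(json.loads(Path(path).read_text()))

    def unigram_patterns(self, category: str) -> list[str]:
        return [p for p in self.categories[category] if len(_clean_pattern_tokens(p)) == 1]

    def phrase_patterns(self, category: str) -> list[list[str]]:
        out = []
        for p in self.categories[category]:
            toks = _clean_pattern_tokens(p)
            if len(toks) > 1:
                out.append(toks)
        return out

    @staticmethod
    def _token_matches(pattern: str, token: str) -> bool:
        if pattern.endswith("*"):
            return token.startswith(pattern[:-1])
        return token == pattern

    def match_tokens(self, tokens: Sequence[str]) -> dict[str, int]:
        """Category -> total keyword occurrences in a cleaned token stream."""
        hits: dict[str, int] = {}
        for category in self.categories:
            n = 0
            for pattern in self.unigram_patterns(category):
                n += sum(1 for t in tokens if self._token_matches(pattern, t))
            for phrase in self.phrase_patterns(category):
                k = len(phrase)
                for i in range(len(tokens) - k + 1):
                    if all(self._token_matches(p, tokens[i + j]) for j, p in enumerate(phrase)):
                        n += 1
            if n:
                hits[category] = n
        return hits

    def match_text(self, text: str) -> dict[str, list[str]]:
        """Category -> matched patterns, on raw (uncleaned) text."""
        import re

        tokens = re.sub(r"[^a-z0-9]+", " ", text.lower()).split()
        out: dict[str, list[str]] = {}
        for category, patterns in self.categories.items():
            for pattern in patterns:
                toks = _clean_pattern_tokens(pattern)
                k = len(toks)
                found = any(
                    all(self._token_matches(p, tokens[i + j]) for j, p in enumerate(toks))
                    for i in range(len(tokens) - k + 1)
                )
                if found:
                    out.setdefault(category, []).append(pattern)
        return out


@dataclass(frozen=True)
class VariantEvidenceAssociation:
    """A variant linked to an evidence category by document co-occurrence."""

    hgvs: str
    category: str
    supporting_docs: tuple[str, ...]
    snippets: Mapping[str, str] = field(default_factory=dict, compare=False)
    analyst_flag: str = "auto"  # auto | confirmed | rejected


def subset_dtm(
    dtm: DocumentTermMatrix,
    lexicon: EvidenceLexicon,
    variant_terms: Iterable[str],
    documents: Sequence[Document] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Subset the DTM into variant hits and evidence-category hits.

    Variant hits: one row (doc_id, hgvs, count) per variant-term column
    with a positive count.  Evidence hits: (doc_id, category, count),
    aggregating all unigram pattern columns of a category; phrase patterns
    need token order, which the DTM has discarded, so they are counted on
    the documents' token streams when ``documents`` is given.
    """
    if not any(lexicon.categories.values()):
        raise LexiconError("empty lexicon")
    term_index = {t: j for j, t in enumerate(dtm.terms)}
    vrows = []
    wanted = sorted(set(variant_terms))
    csc = dtm.counts.tocsc()
    for term in wanted:
        j = term_index.get(term)
        if j is None:
            continue
        col = csc.getcol(j).tocoo()
        for i, c in zip(col.row, col.data):
            if c > 0:
                vrows.append((dtm.doc_ids[i], term, int(c)))
    vrows.sort()
    variant_hits = pd.DataFrame(vrows, columns=["doc_id", "hgvs", "count"])

    erows: dict[tuple[str, str], int] = {}
    for category in lexicon.categories:
        for pattern in lexicon.unigram_patterns(category):
            for j, term in enumerate(dtm.terms):
                if lexicon._token_matches(pattern, term):
                    col = csc.getcol(j).tocoo()
                    for i, c in zip(col.row, col.data):
                        key = (dtm.doc_ids[i], category)
                        erows[key] = erows.get(key, 0) + int(c)
    if documents is not None:
        by_id = {d.doc_id: d for d in documents}
        for doc_id in dtm.doc_ids:
            doc = by_id.get(doc_id)
            if doc is None or not doc.preprocessed:
                continue
            for category in lexicon.categories:
                n = 0
                toks = doc.tokens
                for phrase in lexicon.phrase_patterns(category):
                    k = len(phrase)
                    for i in range(len(toks) - k + 1):
                        if all(
                            lexicon._token_matches(p, toks[i + j])
                            for j, p in enumerate(phrase)
                        ):
                            n += 1
                if n:
                    key = (doc_id, category)
                    erows[key] = erows.get(key, 0) + n
    evidence_hits = pd.DataFrame(
        sorted((d, c, n) for (d, c), n in erows.items()),
        columns=["doc_id", "category", "count"],
    )
    return variant_hits, evidence_hits


def _snippet(doc: Document, hgvs: str, width: int) -> str:
    for m in doc.mentions:
        if m.hgvs == hgvs:
            lo = max(0, m.offset - width)
            hi = min(len(doc.raw_text), m.offset + len(m.raw_text) + width)
            return doc.raw_text[lo:hi].replace("\n", " ")
    return ""


def associate(
    documents: Sequence[Document],
    variant_hits: pd.DataFrame,
    evidence_hits: pd.DataFrame,
    window: int | None = None,
    lexicon: EvidenceLexicon | None = None,
    snippet_width: int = 120,
) -> list[VariantEvidenceAssociation]:
    """Pair variants with evidence categories per document and group.

    ``window=None`` (default) means document scope: every (variant,
    category) present in the same document is associated.  An integer
    window requires at least one category keyword within that many cleaned
    tokens of a mention of the variant (needs ``lexicon`` to locate the
    keywords).  One association is returned per (hgvs, category), with all
    supporting documents and a raw-text snippet per document.
    """
    if window is not None:
        if lexicon is None:
            raise ValueError("token-window association requires a lexicon")
        return _associate_windowed(
            documents, variant_hits, evidence_hits, lexicon, window, snippet_width
        )
    by_id = {d.doc_id: d for d in documents}
    pairs: dict[tuple[str, str], list[str]] = {}
    evid_by_doc: dict[str, list[str]] = {}
    for row in evidence_hits.itertuples(index=False):
        evid_by_doc.setdefault(row.doc_id, []).append(row.category)
    for row in variant_hits.itertuples(index=False):
        for category in evid_by_doc.get(row.doc_id, ()):
            key = (row.hgvs, category)
            docs = pairs.setdefault(key, [])
            if row.doc_id not in docs:
                docs.append(row.doc_id)
    out = []
    for (hgvs, category), doc_ids in sorted(pairs.items()):
        snippets = {
            d: _snippet(by_id[d], hgvs, snippet_width) for d in doc_ids if d in by_id
        }
        out.append(
            VariantEvidenceAssociation(hgvs, category, tuple(doc_ids), snippets)
        )
    return out


def _associate_windowed(
    documents: Sequence[Document],
    variant_hits: pd.DataFrame,
    evidence_hits: pd.DataFrame,
    lexicon: EvidenceLexicon,
    window: int,
    snippet_width: int = 120,
) -> list[VariantEvidenceAssociation]:
    # keyword within `window` cleaned tokens of a variant-term occurrence
    by_id = {d.doc_id: d for d in documents}
    doc_pairs: dict[tuple[str, str], list[str]] = {}
    for doc in documents:
        if not doc.preprocessed:
            continue
        toks = doc.tokens
        var_pos: dict[str, list[int]] = {}
        for i, t in enumerate(toks):
            if t.startswith("m.") and ">" in t:
                var_pos.setdefault(t, []).append(i)
        cat_pos: dict[str, list[int]] = {c: [] for c in lexicon.categories}
        for category in lexicon.categories:
            for pattern in lexicon.unigram_patterns(category):
                cat_pos[category].extend(
                    i for i, t in enumerate(toks) if lexicon._token_matches(pattern, t)
                )
            for phrase in lexicon.phrase_patterns(category):
                k = len(phrase)
                cat_pos[category].extend(
                    i
                    for i in range(len(toks) - k + 1)
                    if all(lexicon._token_matches(p, toks[i + j]) for j, p in enumerate(phrase))
                )
        for hgvs, vps in var_pos.items():
            for category, cps in cat_pos.items():
                if any(abs(v - c) <= window for v in vps for c in cps):
                    docs = doc_pairs.setdefault((hgvs, category), [])
                    if doc.doc_id not in docs:
                        docs.append(doc.doc_id)
    out = []
    for (hgvs, category), doc_ids in sorted(doc_pairs.items()):
        snippets = {d: _snippet(by_id[d], hgvs, snippet_width) for d in doc_ids}
        out.append(VariantEvidenceAssociation(hgvs, category, tuple(doc_ids), snippets))
    return out


def apply_audit(
    associations: Sequence[VariantEvidenceAssociation],
    audit: Mapping[tuple[str, str], str] | str | Path,
) -> list[VariantEvidenceAssociation]:
    """Merge analyst decisions: (hgvs, category) -> confirmed | rejected.

    ``audit`` may be a mapping or a TSV path with columns hgvs, category,
    decision.  Unreviewed associations keep ``auto``.
    """
    if not isinstance(audit, Mapping):
        table = {}
        with open(audit, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                table[(row["hgvs"], row["category"])] = row["decision"]
        audit = table
    out = []
    for assoc in associations:
        decision = audit.get((assoc.hgvs, assoc.category))
        if decision is not None:
            if decision not in ("confirmed", "rejected"):
                raise ValueError(f"bad audit decision {decision!r}")
            assoc = replace(assoc, analyst_flag=decision)
        out.append(assoc)
    return out


def apply_multiple_reports_rule(
    associations: Sequence[VariantEvidenceAssociation],
) -> dict[str, bool]:
    """Per-variant: pathogenicity asserted by at least two distinct documents.

    True iff the variant has support from >= 2 distinct doc_ids across the
    pathogenicity-asserting categories (rejected associations ignored).
    """
    docs_by_variant: dict[str, set[str]] = {}
    for assoc in associations:
        if assoc.analyst_flag == "rejected":
            continue
        if assoc.category in PATHOGENICITY_ASSERTING:
            docs_by_variant.setdefault(assoc.hgvs, set()).update(assoc.supporting_docs)
    variants = {a.hgvs for a in associations}
    return {v: len(docs_by_variant.get(v, ())) >= 2 for v in sorted(variants)}


def write_association_tsv(
    associations: Sequence[VariantEvidenceAssociation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["hgvs", "category", "n_docs", "doc_ids", "analyst_flag", "snippet"])
        for a in associations:
            first = a.snippets.get(a.supporting_docs[0], "") if a.supporting_docs else ""
            writer.writerow(
                [a.hgvs, a.category, len(a.supporting_docs), ";".join(a.supporting_docs),
                 a.analyst_flag, first]
            )
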