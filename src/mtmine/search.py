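"""Literature-search pipeline: query construction, PMID merging, screening.

For each mitochondrial locus two query families are built against PubMed:
a *gene-name* query (locus name OR each synonym, ANDed with the fixed terms
"human", "mitochondrial", "variant" to suppress false hits) and a
*variant-name* query per HGVS string.  Query execution goes through a
pluggable retrieval backend: a local fixture store for reproducible,
offline runs, and a thin NCBI E-utilities client for live use (the live
client is network-dependent and deliberately untested).  Retrieved PMID
lists are merged into a unique, first-seen-ordered list with per-query
provenance, and each abstract is screened: it is kept iff it contains at
least one complete variant mention or at least one functional-evidence
keyword.
"""

from __future__ import annotations

import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .evidence import EvidenceLexicon
from .grammar import scan_text
from .reference import LocusSpan, ReferenceSequence, VariantRecord

FIXED_TERMS = ("human", "mitochondrial", "variant")


@dataclass(frozen=True)
class Query:
    """One PubMed query: a boolean term expression tagged with its origin."""

    locus: str
    terms: str
    kind: str  # gene_name | variant_name

    def __post_init__(self) -> None:
        if self.kind not in ("gene_name", "variant_name"):
            raise ValueError(f"unknown query kind {self.kind!r}")


@dataclass
class PmidSet:
    """Unique PMIDs in first-seen order, with per-PMID query provenance."""

    pmids: list[str] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def add(self, pmid: str, query: Query) -> None:
        if pmid not in self.provenance:
            self.pmids.append(pmid)
            self.provenance[pmid] = []
        if query.terms not in self.provenance[pmid]:
            self.provenance[pmid].append(query.terms)

    def __len__(self) -> int:
        return len(self.pmids)

    def __contains__(self, pmid: str) -> bool:
        return pmid in self.provenance


@dataclass(frozen=True)
class ScreeningResult:
    pmid: str
    decision: str  # keep | discard
    reasons: tuple[str, ...]


def build_gene_query(locus: LocusSpan) -> Query:
    """(name OR synonyms) AND human AND mitochondrial AND variant."""
    names = [locus.name, *locus.synonyms]
    name_expr = " OR ".join(f'"{n}"' for n in names)
    if len(names) > 1:
        name_expr = f"({name_expr})"
    fixed = " AND ".join(f'"{t}"' for t in FIXED_TERMS)
    return Query(locus=locus.name, terms=f"{name_expr} AND {fixed}", kind="gene_name")


def build_variant_queries(
    records: Iterable[VariantRecord], locus: str = ""
) -> list[Query]:
    """One query per unique HGVS string (overlap double-listing deduplicated)."""
    seen: dict[str, str] = {}
    for rec in records:
        if rec.hgvs not in seen:
            seen[rec.hgvs] = rec.locus or locus or ""
    return [
        Query(locus=loc, terms=f'"{hgvs}"', kind="variant_name")
        for hgvs, loc in seen.items()
    ]


def merge_pmids(result_sets: Sequence[tuple[Query, Sequence[str]]]) -> PmidSet:
    """Union of per-query PMID lists, first-seen order, provenance retained."""
    merged = PmidSet()
    for query, pmids in result_sets:
        for pmid in pmids:
            merged.add(str(pmid), query)
    return merged


def screen_abstract(
    pmid: str,
    abstract: str,
    lexicon: EvidenceLexicon,
    reference: ReferenceSequence,
) -> ScreeningResult:
    """Keep an abstract iff it mentions a variant or a functional-evidence keyword."""
    reasons: list[str] = []
    for mention in scan_text(abstract, reference):
        if mention.status == "complete":
            reasons.append(f"variant:{mention.hgvs}")
    for category, patterns in sorted(lexicon.match_text(abstract).items()):
        for pattern in patterns:
            reasons.append(f"keyword:{category}:{pattern}")
    decision = "keep" if reasons else "discard"
    return ScreeningResult(pmid=pmid, decision=decision, reasons=tuple(reasons))


class RetrievalBackend(Protocol):
    """Contract for PMID search and abstract fetch."""

    def search(self, query: Query) -> list[str]: ...

    def fetch_abstract(self, pmid: str) -> str: ...


class FixtureStore:
    """Offline backend over a directory: ``queries.json`` + ``abstracts.json``.

    ``queries.json`` maps the serialized query term expression to a PMID
    list; ``abstracts.json`` maps PMID to abstract text.  Unknown queries
    return no hits.  Deterministic by construction.
    """

    def __init__(self, directory: str | Path):
        directory = Path(directory)
        self._queries: dict[str, list[str]] = json.loads(
            (directory / "queries.json").read_text()
        )
        self._abstracts: dict[str, str] = json.loads(
            (directory / "abstracts.json").read_text()
        )

    def search(self, query: Query) -> list[str]:
        return [str(p) for p in self._queries.get(query.terms, [])]

    def fetch_abstract(self, pmid: str) -> str:
        return self._abstracts.get(str(pmid), "")


class EntrezBackend:
    """Minimal live NCBI E-utilities client (esearch + efetch).

    Requires network access; respects a requests-per-second cap and passes
    the contact email / API key NCBI asks for.  Not exercised by the test
    suite — use :class:`FixtureStore` for reproducible runs.
    """

    BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"

    def __init__(
        self,
        email: str,
        api_key: str | None = None,
        requests_per_second: float = 3.0,
        retmax: int = 10000,
    ):
        self.email = email
        self.api_key = api_key
        self.min_interval = 1.0 / requests_per_second
        self.retmax = retmax
        self._last_request = 0.0

    def _get(self, endpoint: str, params: dict[str, str]) -> str:
        wait = self.min_interval - (time.monotonic() - self._last_request)
        if wait > 0:
            time.sleep(wait)
        params = {**params, "email": self.email, "tool": "mtmine"}
        if self.api_key:
            params["api_key"] = self.api_key
        url = f"{self.BASE}/{endpoint}?{urllib.parse.urlencode(params)}"
        with urllib.request.urlopen(url, timeout=60) as resp:
            body = resp.read().decode("utf-8", errors="replace")
        self._last_request = time.monotonic()
        return body

    def search(self, query: Query) -> list[str]:
        body = self._get(
            "esearch.fcgi",
            {"db": "pubmed", "term": query.terms, "retmax": str(self.retmax),
             "retmode": "json"},
        )
        return list(json.loads(body)["esearchresult"]["idlist"])

    def fetch_abstract(self, pmid: str) -> str:
        return self._get(
            "efetch.fcgi",
            {"db": "pubmed", "id": str(pmid), "rettype": "abstract", "retmode": "text"},
        )


def run_data_mining(
    backend: RetrievalBackend,
    catalogue: Sequence[LocusSpan],
    reference: ReferenceSequence,
    lexicon: EvidenceLexicon,
    variant_records: Sequence[VariantRecord] = (),
) -> tuple[PmidSet, list[ScreeningResult]]:
    """Full search stage: build queries, retrieve, merge, screen abstracts."""
    queries = [build_gene_query(locus) for locus in catalogue]
    queries += build_variant_queries(variant_records)
    result_sets = [(q, backend.search(q)) for q in queries]
    merged = merge_pmids(result_sets)
    screening = [
        screen_abstract(pmid, backend.fetch_abstract(pmid), lexicon, reference)
        for pmid in merged.pmids
    ]
    return merged, screening
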