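"""End-to-end text mining: documents in, annotation table out.

Chains the stages: ingest (mention scan) -> preprocess -> DTM -> subset
against the enumerated variant universe and the evidence lexicon ->
document-scope association -> criteria profiles -> scoring -> annotation
table.  Conservation booleans (PhastCons/PhyloP) are external inputs, so
profiles built purely from text default them (and any unmined criterion)
to False explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotate import AnnotationTable, compile_table
from .corpus import Document, DocumentTermMatrix, build_dtm, preprocess
from .evidence import (
    CATEGORIES,
    EvidenceLexicon,
    VariantEvidenceAssociation,
    apply_audit,
    apply_multiple_reports_rule,
    associate,
    subset_dtm,
)
from .reference import LocusSpan, ReferenceSequence, variant_universe
from .scoring import CriteriaProfile, ScoreResult, ScoringConfig, DEFAULT_CONFIG, score

#: criteria filled straight from a same-named mined evidence category
_MINED_CRITERIA = (
    "heteroplasmy",
    "segregation",
    "histochemistry",
    "biochemistry_oxphos",
    "cybrid_steadystate",
    "single_fiber",
)


def build_profiles(
    associations: Sequence[VariantEvidenceAssociation],
    conservation: Mapping[str, tuple[bool, bool]] | None = None,
) -> dict[str, CriteriaProfile]:
    """Criteria profiles from mined associations plus external conservation.

    ``conservation`` maps hgvs -> (phastcons_conserved, phylop_conserved);
    variants absent from it get (False, False).  ``multiple_reports``
    follows the two-distinct-documents rule over pathogenicity-asserting
    categories; rejected associations never contribute.
    """
    conservation = conservation or {}
    multi = apply_multiple_reports_rule(associations)
    cats_by_variant: dict[str, set[str]] = {}
    for assoc in associations:
        if assoc.analyst_flag == "rejected":
            continue
        cats_by_variant.setdefault(assoc.hgvs, set()).add(assoc.category)
    profiles = {}
    for hgvs, cats in sorted(cats_by_variant.items()):
        phast, phylo = conservation.get(hgvs, (False, False))
        values = {name: name in cats for name in _MINED_CRITERIA}
        values["multiple_reports"] = multi.get(hgvs, False)
        values["phastcons_conserved"] = bool(phast)
        values["phylop_conserved"] = bool(phylo)
        profiles[hgvs] = CriteriaProfile.from_mapping(values)
    return profiles


@dataclass
class MiningResult:
    """Everything the text-mining stage produced, stage by stage."""

    documents: list[Document]
    dtm: DocumentTermMatrix
    variant_hits: object
    evidence_hits: object
    associations: list[VariantEvidenceAssociation]
    profiles: dict[str, CriteriaProfile]
    scores: dict[str, ScoreResult]
    table: AnnotationTable


def run_text_mining(
    documents: Sequence[Document],
    reference: ReferenceSequence,
    catalogue: Sequence[LocusSpan],
    lexicon: EvidenceLexicon | None = None,
    conservation: Mapping[str, tuple[bool, bool]] | None = None,
    audit: Mapping[tuple[str, str], str] | None = None,
    window: int | None = None,
    scoring_config: ScoringConfig = DEFAULT_CONFIG,
    stopwords: Sequence[str] | None = None,
) -> MiningResult:
    """Run the full text-mining chain over ingested documents."""
    lexicon = lexicon or EvidenceLexicon.default()
    docs = [preprocess(d, stopwords) if not d.preprocessed else d for d in documents]
    dtm = build_dtm(docs)
    universe = variant_universe(catalogue, reference)
    variant_hits, evidence_hits = subset_dtm(dtm, lexicon, universe, documents=docs)
    associations = associate(docs, variant_hits, evidence_hits, window=window, lexicon=lexicon)
    if audit:
        associations = apply_audit(associations, audit)
    profiles = build_profiles(associations, conservation)
    scores = {h: score(p, scoring_config) for h, p in profiles.items()}
    table = compile_table(
        associations, catalogue, reference, profiles=profiles, scores=scores
    )
    return MiningResult(
        documents=list(docs),
        dtm=dtm,
        variant_hits=variant_hits,
        evidence_hits=evidence_hits,
        associations=associations,
        profiles=profiles,
        scores=scores,
        table=table,
    )
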