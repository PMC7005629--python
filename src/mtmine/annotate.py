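"""Final annotation tables and database-comparison statistics.

The annotation table has one row per (variant, containing locus) pair —
a variant in the ATP8/ATP6 overlap yields two rows — carrying the mined
evidence categories with their supporting PMIDs, the scoring profile,
the weighted score and tier, and review snippets.  Variants whose only
mined evidence is segregation are flagged ``likely_association_only``:
segregation suggests a genotype-phenotype link but is not stand-alone
proof of pathogenicity.

The comparison summary reproduces the shared/only set arithmetic used to
benchmark a mined variant set against an external database (Mitomap-style
TSV of HGVS + locus class): per locus class the external count, pipeline
count, shared count and the two "only" counts, a totals row, and the
additional-information percentage 100 * only_pipeline_total /
pipeline_total rounded half-up to two decimals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

from .evidence import VariantEvidenceAssociation
from .grammar import parse_mention
from .reference import LocusSpan, ReferenceSequence, loci_at_position
from .scoring import CriteriaProfile, ScoreResult

#: Table-style row order for locus classes
CLASS_ORDER = ("protein_coding", "D_loop", "rRNA", "tRNA")

CAVEAT_SEGREGATION_ONLY = "likely_association_only"


@dataclass(frozen=True)
class AnnotationRow:
    hgvs: str
    position: int
    locus: str
    locus_type: str
    categories: Mapping[str, tuple[str, ...]]  # category -> supporting doc ids
    profile: CriteriaProfile | None
    total: int | None
    tier: str | None
    snippets: Mapping[str, str] = field(default_factory=dict, compare=False)
    caveats: tuple[str, ...] = ()


@dataclass
class AnnotationTable:
    rows: list[AnnotationRow]
    rejected: list[tuple[str, str]]  # (hgvs, reason)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "hgvs": r.hgvs,
                    "position": r.position,
                    "locus": r.locus,
                    "locus_type": r.locus_type,
                    "categories": ";".join(sorted(r.categories)),
                    "n_docs": len({d for ds in r.categories.values() for d in ds}),
                    "total": r.total,
                    "tier": r.tier,
                    "caveats": ";".join(r.caveats),
                }
                for r in self.rows
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def write_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.rows:
                fh.write(
                    json.dumps(
                        {
                            "hgvs": r.hgvs,
                            "position": r.position,
                            "locus": r.locus,
                            "locus_type": r.locus_type,
                            "categories": {k: list(v) for k, v in r.categories.items()},
                            "profile": r.profile.as_dict() if r.profile else None,
                            "total": r.total,
                            "tier": r.tier,
                            "snippets": dict(r.snippets),
                            "caveats": list(r.caveats),
                        }
                    )
                    + "\n"
                )


def compile_table(
    associations: Sequence[VariantEvidenceAssociation],
    catalogue: Sequence[LocusSpan],
    reference: ReferenceSequence,
    profiles: Mapping[str, CriteriaProfile] | None = None,
    scores: Mapping[str, ScoreResult] | None = None,
    include_rejected_associations: bool = False,
) -> AnnotationTable:
    """Compile one annotation row per (variant, containing locus).

    A variant whose HGVS string is not in the enumeration universe (bad
    position, reference mismatch, alt equal to ref) is rejected with a
    reason rather than silently dropped.  Rows are sorted by (position,
    alt, catalogue order of locus); variants outside every locus get a
    single row with locus ``intergenic``.
    """
    types = {l.name: l.locus_type for l in catalogue}
    order = {l.name: i for i, l in enumerate(catalogue)}
    by_variant: dict[str, dict[str, tuple[str, ...]]] = {}
    snippets: dict[str, dict[str, str]] = {}
    for assoc in associations:
        if assoc.analyst_flag == "rejected" and not include_rejected_associations:
            continue
        by_variant.setdefault(assoc.hgvs, {})[assoc.category] = assoc.supporting_docs
        snippets.setdefault(assoc.hgvs, {}).update(assoc.snippets)

    rows: list[AnnotationRow] = []
    rejected: list[tuple[str, str]] = []
    for hgvs in sorted(by_variant):
        mention = parse_mention(hgvs, reference)
        if mention is None:
            rejected.append((hgvs, "not parseable as a potential substitution"))
            continue
        if mention.status != "complete":
            rejected.append((hgvs, f"outside enumeration universe ({mention.status})"))
            continue
        categories = by_variant[hgvs]
        caveats = (
            (CAVEAT_SEGREGATION_ONLY,) if set(categories) == {"segregation"} else ()
        )
        profile = profiles.get(hgvs) if profiles else None
        result = scores.get(hgvs) if scores else None
        loci = loci_at_position(catalogue, mention.position) or ["intergenic"]
        for locus in loci:
            rows.append(
                AnnotationRow(
                    hgvs=hgvs,
                    position=mention.position,
                    locus=locus,
                    locus_type=types.get(locus, "intergenic"),
                    categories=categories,
                    profile=profile,
                    total=result.total if result else None,
                    tier=result.tier if result else None,
                    snippets=snippets.get(hgvs, {}),
                    caveats=caveats,
                )
            )
    rows.sort(key=lambda r: (r.position, r.hgvs, order.get(r.locus, len(order))))
    return AnnotationTable(rows=rows, rejected=rejected)


@dataclass(frozen=True)
class ComparisonRow:
    locus_type: str
    external_count: int
    pipeline_count: int
    shared_count: int
    only_external: int
    only_pipeline: int


@dataclass(frozen=True)
class ComparisonSummary:
    rows: tuple[ComparisonRow, ...]
    totals: ComparisonRow
    additional_info_percentage: float

    def to_dataframe(self):
        import pandas as pd

        records = [r.__dict__ for r in (*self.rows, self.totals)]
        return pd.DataFrame(records)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        with open(path, "w", newline="") as fh:
            df.to_csv(fh, sep="\t", index=False)
            fh.write(f"# additional_info_percentage\t{self.additional_info_percentage:.2f}\n")


def _round2_half_up(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_comparison_counts(
    counts: Mapping[str, tuple[int, int, int]]
) -> ComparisonSummary:
    """Build a summary from per-class (external, pipeline, shared) counts.

    The two "only" columns and the totals row follow by set algebra:
    only_external = external - shared, only_pipeline = pipeline - shared.
    """
    rows = []
    for locus_type in (*CLASS_ORDER, *sorted(set(counts) - set(CLASS_ORDER))):
        if locus_type not in counts:
            continue
        ext, pipe, shared = counts[locus_type]
        if shared > min(ext, pipe):
            raise ValueError(f"{locus_type}: shared {shared} exceeds a set size")
        rows.append(
            ComparisonRow(locus_type, ext, pipe, shared, ext - shared, pipe - shared)
        )
    totals = ComparisonRow(
        "total",
        sum(r.external_count for r in rows),
        sum(r.pipeline_count for r in rows),
        sum(r.shared_count for r in rows),
        sum(r.only_external for r in rows),
        sum(r.only_pipeline for r in rows),
    )
    if totals.pipeline_count == 0:
        pct = 0.0
    else:
        pct = _round2_half_up(
            Decimal(100 * totals.only_pipeline) / Decimal(totals.pipeline_count)
        )
    return ComparisonSummary(tuple(rows), totals, pct)


def summarize_comparison_columns(
    counts: Mapping[str, tuple[int, int, int, int, int]]
) -> ComparisonSummary:
    """Totals and percentage from fully specified comparison rows.

    Each row gives all five columns as published: (external, pipeline,
    shared, only_external, only_pipeline).  Unlike
    :func:`summarize_comparison_counts` no set-algebra identity is
    enforced, so externally curated tables whose only-counts reflect
    additional filtering can be summarized as printed.
    """
    rows = []
    for locus_type in (*CLASS_ORDER, *sorted(set(counts) - set(CLASS_ORDER))):
        if locus_type not in counts:
            continue
        rows.append(ComparisonRow(locus_type, *counts[locus_type]))
    totals = ComparisonRow(
        "total",
        sum(r.external_count for r in rows),
        sum(r.pipeline_count for r in rows),
        sum(r.shared_count for r in rows),
        sum(r.only_external for r in rows),
        sum(r.only_pipeline for r in rows),
    )
    if totals.pipeline_count == 0:
        pct = 0.0
    else:
        pct = _round2_half_up(
            Decimal(100 * totals.only_pipeline) / Decimal(totals.pipeline_count)
        )
    return ComparisonSummary(tuple(rows), totals, pct)


def _check_normalized(hgvs_set: set[str], reference: ReferenceSequence, label: str) -> None:
    for hgvs in hgvs_set:
        mention = parse_mention(hgvs, reference)
        if (
            mention is None
            or mention.token_format != "m.[POS][REF]>[ALT]"
            or mention.hgvs != hgvs
        ):
            raise ValueError(f"{label}: un-normalized variant key {hgvs!r}")


def compare_variant_sets(
    pipeline: Mapping[str, set[str]],
    external: Mapping[str, set[str]],
    reference: ReferenceSequence | None = None,
) -> ComparisonSummary:
    """Compare mined vs external variant sets, grouped by locus class.

    Inputs map locus class -> set of normalized HGVS strings.  When a
    reference is given, keys are checked to be canonical ``m.{pos}{ref}>{alt}``
    strings and a mismatch raises.
    """
    counts: dict[str, tuple[int, int, int]] = {}
    for locus_type in sorted(set(pipeline) | set(external)):
        p = set(pipeline.get(locus_type, set()))
        e = set(external.get(locus_type, set()))
        if reference is not None:
            _check_normalized(p, reference, f"pipeline/{locus_type}")
            _check_normalized(e, reference, f"external/{locus_type}")
        counts[locus_type] = (len(e), len(p), len(p & e))
    return summarize_comparison_counts(counts)


def read_variant_set_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV of (hgvs, locus_type) into locus class -> HGVS set."""
    out: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["locus_type"], set()).add(row["hgvs"])
    return out
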