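"""Weighted pathogenicity scoring for mitochondrial tRNA variants.

The scoring system assigns each variant points over nine boolean criteria
(Yarham-style, as refined for mtDNA tRNA variants):

    criterion                                weight
    ----------------------------------------------
    described pathogenic by >1 report           2
    PhastCons inter-mammalian conservation      1
    PhyloP inter-mammalian conservation         1
    heteroplasmy evidence                       2
    segregation of mutation with disease        2
    histochemical evidence                      2
    biochemical OXPHOS defect (CI/CIII/CIV)     2
    cybrid or mt-tRNA steady-state evidence     5
    single-fiber segregation with defect        3

The total ranges 0-20.  Tier thresholds are not part of the weight table;
the defaults here follow the Yarham convention (<=6 neutral polymorphism,
7-10 possibly pathogenic, >=11 definitely pathogenic, with "definitely"
additionally requiring functional gold-standard evidence — cybrid /
steady-state or single-fiber — without which a high score is capped at
"possibly pathogenic").  Both the boundaries and the gold-standard clause
are configurable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

WEIGHTS: dict[str, int] = {
    "multiple_reports": 2,
    "phastcons_conserved": 1,
    "phylop_conserved": 1,
    "heteroplasmy": 2,
    "segregation": 2,
    "histochemistry": 2,
    "biochemistry_oxphos": 2,
    "cybrid_steadystate": 5,
    "single_fiber": 3,
}

MAX_SCORE = sum(WEIGHTS.values())  # 20

NEUTRAL = "neutral_polymorphism"
POSSIBLY = "possibly_pathogenic"
DEFINITELY = "definitely_pathogenic"
TIER_ORDER = (NEUTRAL, POSSIBLY, DEFINITELY)

#: criteria counted as functional gold standard for the top tier
GOLD_CRITERIA = ("cybrid_steadystate", "single_fiber")


class IncompleteProfileError(ValueError):
    """A criterion is missing and defaulting was not explicitly allowed."""


@dataclass(frozen=True)
class CriteriaProfile:
    """The nine scoring booleans for one variant."""

    multiple_reports: bool
    phastcons_conserved: bool
    phylop_conserved: bool
    heteroplasmy: bool
    segregation: bool
    histochemistry: bool
    biochemistry_oxphos: bool
    cybrid_steadystate: bool
    single_fiber: bool

    @classmethod
    def from_mapping(
        cls, values: Mapping[str, bool], default_missing: bool = False
    ) -> "CriteriaProfile":
        """Build a profile; missing criteria are an error unless explicitly defaulted.

        Silent false-filling would inflate apparent neutrality, so
        ``default_missing=True`` must be opted into.
        """
        names = [f.name for f in fields(cls)]
        unknown = set(values) - set(names)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        missing = [n for n in names if n not in values]
        if missing and not default_missing:
            raise IncompleteProfileError(f"missing criteria: {missing}")
        return cls(**{n: bool(values.get(n, False)) for n in names})

    def as_dict(self) -> dict[str, bool]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ScoringConfig:
    """Tier boundaries and the functional-evidence clause for the top tier."""

    possibly_min: int = 7
    definitely_min: int = 11
    require_gold_for_definite: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.possibly_min <= self.definitely_min <= MAX_SCORE:
            raise ValueError("tier boundaries must satisfy 0 < possibly <= definite <= 20")


DEFAULT_CONFIG = ScoringConfig()


@dataclass(frozen=True)
class ScoreResult:
    """Total points, the per-criterion breakdown, and the assigned tier."""

    total: int
    per_criterion: Mapping[str, int]
    tier: str


def classify(total: int, config: ScoringConfig = DEFAULT_CONFIG) -> str:
    """Map a point total to a tier (pure threshold rule, monotone in points)."""
    if not 0 <= total <= MAX_SCORE:
        raise ValueError(f"total {total} outside 0..{MAX_SCORE}")
    if total >= config.definitely_min:
        return DEFINITELY
    if total >= config.possibly_min:
        return POSSIBLY
    return NEUTRAL


def score(
    profile: CriteriaProfile, config: ScoringConfig = DEFAULT_CONFIG
) -> ScoreResult:
    """Score one profile: weighted sum plus tier assignment.

    With the default config, a total in the "definitely pathogenic" range
    is demoted to "possibly pathogenic" when neither cybrid/steady-state
    nor single-fiber evidence is present.
    """
    per = {name: (WEIGHTS[name] if getattr(profile, name) else 0) for name in WEIGHTS}
    total = sum(per.values())
    tier = classify(total, config)
    if (
        tier == DEFINITELY
        and config.require_gold_for_definite
        and not any(getattr(profile, g) for g in GOLD_CRITERIA)
    ):
        tier = POSSIBLY
    return ScoreResult(total=total, per_criterion=per, tier=tier)


def score_table(
    in_tsv: str | Path,
    out_tsv: str | Path,
    config: ScoringConfig = DEFAULT_CONFIG,
    default_missing: bool = False,
) -> int:
    """Batch mode: TSV (hgvs + nine boolean columns) -> TSV with points and tier.

    Boolean cells accept yes/no, true/false, 1/0 (case-insensitive).
    Returns the number of variants scored.
    """
    truthy = {"yes", "true", "1", "y"}
    falsy = {"no", "false", "0", "n"}
    n = 0
    with open(in_tsv, newline="") as fin, open(out_tsv, "w", newline="") as fout:
        reader = csv.DictReader(fin, delimiter="\t")
        writer = csv.writer(fout, delimiter="\t")
        writer.writerow(["hgvs", *WEIGHTS, "total", "tier"])
        for row in reader:
            values = {}
            for name in WEIGHTS:
                if name in row and row[name] is not None:
                    cell = row[name].strip().lower()
                    if cell == "":
                        continue  # blank cell = missing criterion
                    if cell in truthy:
                        values[name] = True
                    elif cell in falsy:
                        values[name] = False
                    else:
                        raise ValueError(f"{row['hgvs']}: bad boolean {row[name]!r} for {name}")
            profile = CriteriaProfile.from_mapping(values, default_missing=default_missing)
            result = score(profile, config)
            writer.writerow(
                [row["hgvs"], *(result.per_criterion[name] for name in WEIGHTS),
                 result.total, result.tier]
            )
            n += 1
    return n
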