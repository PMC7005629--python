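"""Recognition and normalization of mitochondrial variant mentions in text.

Mitochondrial substitutions appear in the literature under several token
conventions besides canonical HGVS.  Five formats are recognized, in this
order of precedence:

    1. ``m.[POS][REF]>[ALT]``   e.g. ``m.8839G>C``, ``m.8839G > C``
    2. ``m.[POS][REF][ALT]``    e.g. ``m.8839GC``
    3. ``[REF][POS][ALT]``      e.g. ``A3243G``
    4. ``[POS][ALT]``           e.g. ``8993G``
    5. ``m.[POS][REF]``         e.g. ``m.15990C``  (no alternate allele)

Every candidate is validated against the reference: a stated reference
allele that disagrees with the rCRS base yields a ``ref_discordant``
mention; format 5 yields ``incomplete`` (no alternate allele); the bare
``[POS][ALT]`` form, which is ambiguous with ordinary numerals, is accepted
only when the position is in range and the reference base differs from the
stated alternate, so ``figure 3A``-style tokens at positions whose reference
happens to be ``A`` are rejected by the validation itself.  Matching is
case-insensitive and tolerates one space on each side of ``>``.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .reference import MT_LENGTH, ReferenceSequence

TOKEN_FORMATS = (
    "m.[POS][REF]>[ALT]",
    "m.[POS][REF][ALT]",
    "[REF][POS][ALT]",
    "[POS][ALT]",
    "m.[POS][REF]",
)

COMPLETE = "complete"
INCOMPLETE = "incomplete"
REF_DISCORDANT = "ref_discordant"

# token must not continue an alphanumeric run on either side
_L = r"(?<![A-Za-z0-9.>])"
_R = r"(?![A-Za-z0-9.>])"
# N is a legal stated reference (the rCRS 3107 placeholder) but never an alt
_PATTERNS: tuple[tuple[str, re.Pattern[str]], ...] = (
    ("m.[POS][REF]>[ALT]",
     re.compile(_L + r"m\.(\d{1,5})([ACGTN]) ?> ?([ACGT])" + _R, re.IGNORECASE)),
    ("m.[POS][REF][ALT]",
     re.compile(_L + r"m\.(\d{1,5})([ACGTN])([ACGT])" + _R, re.IGNORECASE)),
    ("[REF][POS][ALT]",
     re.compile(_L + r"([ACGTN])(\d{1,5})([ACGT])" + _R, re.IGNORECASE)),
    ("[POS][ALT]",
     re.compile(_L + r"(\d{1,5})([ACGT])" + _R, re.IGNORECASE)),
    ("m.[POS][REF]",
     re.compile(_L + r"m\.(\d{1,5})([ACGTN])" + _R, re.IGNORECASE)),
)


@dataclass(frozen=True)
class VariantMention:
    """A variant token recognized in text, validated against the reference."""

    raw_text: str
    token_format: str
    position: int
    ref: str | None
    alt: str | None
    status: str
    offset: int = -1

    @property
    def hgvs(self) -> str | None:
        """Normalized name; only complete mentions normalize."""
        if self.status != COMPLETE:
            return None
        return f"m.{self.position}{self.ref}>{self.alt}"

    @property
    def stated_name(self) -> str:
        """Deterministic rendering of what the text claims, any status."""
        if self.alt is None:
            return f"m.{self.position}{self.ref}"
        return f"m.{self.position}{self.ref}>{self.alt}"


def _groups_to_fields(fmt: str, groups: tuple[str, ...]) -> tuple[int, str | None, str | None]:
    if fmt == "[REF][POS][ALT]":
        ref, pos, alt = groups
    elif fmt == "[POS][ALT]":
        (pos, alt), ref = groups, None
    elif fmt == "m.[POS][REF]":
        (pos, ref), alt = groups, None
    else:
        pos, ref, alt = groups
    return int(pos), ref.upper() if ref else None, alt.upper() if alt else None


def _make_mention(
    fmt: str,
    raw: str,
    offset: int,
    groups: tuple[str, ...],
    reference: ReferenceSequence,
) -> VariantMention | None:
    position, ref, alt = _groups_to_fields(fmt, groups)
    if not 1 <= position <= MT_LENGTH:
        return None
    true_ref = reference.base_at(position)
    if ref is None:  # [POS][ALT]: complete the reference allele
        if alt == true_ref:
            return None  # alt equal to reference: not a substitution token
        ref, status = true_ref, COMPLETE
    elif ref != true_ref:
        status = REF_DISCORDANT
    elif alt is None:
        status = INCOMPLETE
    elif alt == ref:
        return None
    else:
        status = COMPLETE
    return VariantMention(raw, fmt, position, ref, alt, status, offset)


def parse_mention(token: str, reference: ReferenceSequence) -> VariantMention | None:
    """Parse a single candidate token span.

    Formats are tried in precedence order against the whole (stripped)
    token; the first that matches and validates wins.  Returns ``None``
    for spans that are not variant mentions (bad symbols, out-of-range
    positions, or a bare ``[POS][ALT]`` whose alt equals the reference).
    """
    token = token.strip()
    for fmt, pattern in _PATTERNS:
        m = pattern.fullmatch(token)
        if m:
            mention = _make_mention(fmt, token, 0, m.groups(), reference)
            if mention is not None:
                return mention
    return None


def scan_text(text: str, reference: ReferenceSequence) -> list[VariantMention]:
    """Find all non-overlapping variant mentions in a document, left to right.

    When candidate matches overlap, the longest wins; at equal length the
    earlier format in precedence order wins.  Offsets index into ``text``.
    """
    candidates: list[tuple[int, int, int, VariantMention]] = []
    for fmt_index, (fmt, pattern) in enumerate(_PATTERNS):
        for m in pattern.finditer(text):
            mention = _make_mention(fmt, m.group(0), m.start(), m.groups(), reference)
            if mention is not None:
                candidates.append((m.start(), -(m.end() - m.start()), fmt_index, mention))
    candidates.sort()
    chosen: list[VariantMention] = []
    last_end = -1
    for start, neg_len, _, mention in sorted(
        candidates, key=lambda c: (c[0], c[1], c[2])
    ):
        end = start - neg_len
        if start >= last_end:
            chosen.append(mention)
            last_end = end
        # overlapping, lower-priority candidate: dropped
    return chosen


def write_mention_tsv(
    mentions_by_doc: dict[str, Sequence[VariantMention]], path: str | Path
) -> None:
    """Export mentions as TSV: doc, offset, raw, format, position, ref, alt, status, hgvs."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["doc_id", "offset", "raw_text", "format", "position", "ref", "alt", "status", "hgvs"]
        )
        for doc_id, mentions in mentions_by_doc.items():
            for m in mentions:
                writer.writerow(
                    [doc_id, m.offset, m.raw_text, m.token_format, m.position,
                     m.ref or "", m.alt or "", m.status, m.hgvs or ""]
                )
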