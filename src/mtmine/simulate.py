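"""Synthetic literature corpus with planted variant mentions and keywords.

Real inputs to the pipeline are abstracts and extracted full texts, which
are paywalled and non-redistributable; this generator emulates them so the
whole mining chain is testable offline.  Each document is plausible filler
prose interleaved with planted variant tokens (rendered in one of the five
literature formats, sampled from a configurable mix), planted evidence
keywords drawn from the lexicon, and optional decoys: years, ``n=3243``
sample sizes, out-of-range positions and reference-discordant tokens,
which stress the disambiguation and validation rules.  A ground-truth
manifest records every plant with its offset plus the global
(variant, category, document) triple set; the same seed reproduces the
corpus byte for byte.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .evidence import EvidenceLexicon
from .grammar import TOKEN_FORMATS
from .reference import MT_LENGTH, ALLELES, ReferenceSequence

_DEF_FORMAT_MIX = {fmt: 1 / len(TOKEN_FORMATS) for fmt in TOKEN_FORMATS}


def _filler_words() -> list[str]:
    text = resources.files("mtmine.data").joinpath("wordlist.txt").read_text()
    return [w for w in text.split() if w]


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for one generated corpus."""

    n_docs: int = 50
    variants_per_doc: tuple[int, int] = (1, 3)  # uniform inclusive range
    categories_per_doc: tuple[int, int] = (1, 2)
    format_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_FORMAT_MIX))
    category_mix: Mapping[str, float] | None = None  # None = uniform over lexicon
    decoy_density: float = 0.0  # expected decoys per document
    discordant_rate: float = 0.0  # probability a planted variant states a wrong ref
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.format_mix.values()) - 1) > 1e-9:
            raise ValueError("format_mix probabilities must sum to 1")
        unknown = set(self.format_mix) - set(TOKEN_FORMATS)
        if unknown:
            raise ValueError(f"unknown token formats {sorted(unknown)}")
        if self.category_mix is not None and abs(sum(self.category_mix.values()) - 1) > 1e-9:
            raise ValueError("category_mix probabilities must sum to 1")


@dataclass
class PlantedMention:
    raw: str
    token_format: str
    offset: int
    position: int
    ref: str
    alt: str | None
    hgvs: str | None  # None for incomplete-format or discordant plants
    discordant: bool = False


@dataclass
class GroundTruthManifest:
    """Exact record of what was planted where."""

    mentions: dict[str, list[PlantedMention]] = field(default_factory=dict)
    keywords: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    decoys: dict[str, list[tuple[str, int]]] = field(default_factory=dict)

    @property
    def triples(self) -> set[tuple[str, str, str]]:
        """(hgvs, category, doc_id) for every complete, concordant plant."""
        out = set()
        for doc_id, plants in self.mentions.items():
            variants = {p.hgvs for p in plants if p.hgvs}
            categories = {c for c, _ in self.keywords.get(doc_id, [])}
            out.update((v, c, doc_id) for v in variants for c in categories)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "mentions": {
                    d: [p.__dict__ for p in plants] for d, plants in self.mentions.items()
                },
                "keywords": {d: list(map(list, kws)) for d, kws in self.keywords.items()},
                "decoys": {d: list(map(list, ds)) for d, ds in self.decoys.items()},
            },
            indent=1,
        )


def _render(fmt: str, position: int, ref: str, alt: str | None, rng: random.Random) -> str:
    if fmt == "m.[POS][REF]>[ALT]":
        sep = rng.choice([">", " > "])
        return f"m.{position}{ref}{sep}{alt}"
    if fmt == "m.[POS][REF][ALT]":
        return f"m.{position}{ref}{alt}"
    if fmt == "[REF][POS][ALT]":
        return f"{ref}{position}{alt}"
    if fmt == "[POS][ALT]":
        return f"{position}{alt}"
    if fmt == "m.[POS][REF]":
        return f"m.{position}{ref}"
    raise ValueError(f"unknown format {fmt!r}")


def _surface_form(pattern: str) -> str:
    # stripping a trailing * leaves a prefix that matches the pattern itself
    return pattern.replace("*", "")


def _weighted_choice(rng: random.Random, mix: Mapping[str, float]) -> str:
    items = sorted(mix.items())
    return rng.choices([k for k, _ in items], weights=[w for _, w in items], k=1)[0]


def generate(
    spec: CorpusSpec,
    reference: ReferenceSequence,
    lexicon: EvidenceLexicon | None = None,
) -> tuple[list[tuple[str, str]], GroundTruthManifest]:
    """Generate ``[(doc_id, text), ...]`` plus the exact manifest.

    Planted variants are reference-consistent (the stated ref is the rCRS
    allele) except for the ``discordant_rate`` fraction, which state a
    deliberately wrong reference allele and are recorded as such.
    """
    lexicon = lexicon or EvidenceLexicon.default()
    cat_mix = spec.category_mix or {
        c: 1 / len(lexicon.categories) for c in lexicon.categories
    }
    words = _filler_words()
    rng = random.Random(spec.seed)
    manifest = GroundTruthManifest()
    documents: list[tuple[str, str]] = []

    for d in range(spec.n_docs):
        doc_id = f"9{spec.seed % 1000:03d}{d:05d}"
        n_var = rng.randint(*spec.variants_per_doc)
        n_cat = rng.randint(*spec.categories_per_doc)
        n_decoy = _poisson(rng, spec.decoy_density)

        plants: list[tuple[str, object]] = []  # (kind, payload)
        for _ in range(n_var):
            position = rng.randint(1, MT_LENGTH)
            while reference.base_at(position) == "N":
                position = rng.randint(1, MT_LENGTH)
            true_ref = reference.base_at(position)
            alt = rng.choice([a for a in ALLELES if a != true_ref])
            fmt = _weighted_choice(rng, spec.format_mix)
            discordant = (
                fmt not in ("[POS][ALT]",)  # completed-ref format cannot be discordant
                and rng.random() < spec.discordant_rate
            )
            stated_ref = (
                rng.choice([a for a in ALLELES if a not in (true_ref,)])
                if discordant
                else true_ref
            )
            if fmt == "[REF][POS][ALT]" and stated_ref == alt:
                # REF==ALT renders an invalid substitution; restate concordantly
                stated_ref, discordant = true_ref, False
            raw = _render(fmt, position, stated_ref, alt, rng)
            complete = fmt != "m.[POS][REF]" and not discordant
            plants.append(
                (
                    "mention",
                    PlantedMention(
                        raw=raw,
                        token_format=fmt,
                        offset=-1,
                        position=position,
                        ref=stated_ref,
                        alt=None if fmt == "m.[POS][REF]" else alt,
                        hgvs=f"m.{position}{true_ref}>{alt}" if complete else None,
                        discordant=discordant,
                    ),
                )
            )
        for _ in range(n_cat):
            category = _weighted_choice(rng, cat_mix)
            pattern = rng.choice(sorted(lexicon.categories[category]))
            plants.append(("keyword", (category, _surface_form(pattern))))
        for _ in range(n_decoy):
            kind = rng.choice(["year", "samplesize", "out_of_range"])
            if kind == "year":
                token = f"in {rng.randint(1970, 2018)} the"
            elif kind == "samplesize":
                token = f"n={rng.randint(1, MT_LENGTH)}"
            else:
                token = (
                    f"m.{rng.randint(MT_LENGTH + 1, 99999)}"
                    f"{rng.choice(ALLELES)}>{rng.choice(ALLELES)}"
                )
            plants.append(("decoy", token))
        rng.shuffle(plants)

        # assemble: filler sentences with plants inserted between words
        pieces: list[str] = []
        offset = 0
        doc_mentions: list[PlantedMention] = []
        doc_keywords: list[tuple[str, str]] = []
        doc_decoys: list[tuple[str, int]] = []

        def _emit(piece: str) -> int:
            nonlocal offset
            start = offset
            pieces.append(piece)
            offset += len(piece)
            return start

        for kind, payload in plants:
            for _ in range(rng.randint(1, 2)):
                sentence = " ".join(rng.choices(words, k=rng.randint(5, 10)))
                _emit(sentence.capitalize() + ". ")
            if kind == "mention":
                payload.offset = _emit(payload.raw)
                doc_mentions.append(payload)
            elif kind == "keyword":
                category, surface = payload
                _emit(surface)
                doc_keywords.append((category, surface))
            else:
                start = _emit(payload)
                doc_decoys.append((payload, start))
            _emit(" was " + rng.choice(words) + ". ")
        sentence = " ".join(rng.choices(words, k=rng.randint(5, 10)))
        _emit(sentence.capitalize() + ".")

        documents.append((doc_id, "".join(pieces)))
        manifest.mentions[doc_id] = doc_mentions
        manifest.keywords[doc_id] = doc_keywords
        manifest.decoys[doc_id] = doc_decoys
    return documents, manifest


def _poisson(rng: random.Random, lam: float) -> int:
    if lam <= 0:
        return 0
    # Knuth's method; lambdas here are tiny
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def write_corpus(
    documents: Sequence[tuple[str, str]],
    manifest: GroundTruthManifest,
    out_dir: str | Path,
) -> None:
    """Write ``<pmid>.txt`` files plus ``manifest.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for doc_id, text in documents:
        (out_dir / f"{doc_id}.txt").write_text(text)
    (out_dir / "manifest.json").write_text(manifest.to_json())
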