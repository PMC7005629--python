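"""Corpus ingestion, preprocessing and Document-Term Matrix construction.

Cleaning follows the usual text-mining recipe: lowercase, strip punctuation
and special symbols, collapse whitespace, drop stopwords.  Those steps
destroy variant tokens (``m.8839G>C`` would come out as ``m``, ``8839g``,
``c``), so variant mentions are scanned on the raw text *first* and each
mention span is masked with an opaque alphanumeric placeholder that passes
through the cleaning untouched; after tokenization the placeholders are
replaced by the mention's normalized name, so every complete mention
survives as exactly one ``m.{pos}{ref}>{alt}`` term.

Text is Unicode-normalized at ingestion (NFKC, typographic hyphens and
quotes mapped to ASCII) and optional header/footer metadata lines are
stripped there too, so mention offsets are valid in the stored
``Document.raw_text``.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp

from .grammar import VariantMention, scan_text
from .reference import ReferenceSequence

_TRANSLATE = str.maketrans(
    {
        "‐": "-", "‑": "-", "‒": "-", "–": "-", "—": "-",
        "‘": "'", "’": "'", "“": '"', "”": '"',
        " ": " ", " ": " ", " ": " ",
    }
)

#: default header/footer line patterns treated as metadata, not body text
DEFAULT_METADATA_PATTERNS = (
    r"^\s*doi:\s*\S+\s*$",
    r"^\s*https?://\S+\s*$",
    r"^\s*page\s+\d+(\s+of\s+\d+)?\s*$",
    r"^\s*downloaded\s+from\b.*$",
    r"^\s*(copyright|©)\b.*$",
)

_PLACEHOLDER = "xmtvar{}x"
_PLACEHOLDER_RE = re.compile(r"^xmtvar(\d+)x$")


def default_stopwords() -> frozenset[str]:
    """The bundled English stopword list."""
    text = resources.files("mtmine.data").joinpath("stopwords.txt").read_text()
    return frozenset(w for w in text.split() if w)


class CorpusError(ValueError):
    pass


@dataclass
class Document:
    """One literature document: raw text, its variant mentions, and tokens."""

    doc_id: str
    raw_text: str
    mentions: list[VariantMention] = field(default_factory=list)
    tokens: list[str] | None = None

    @property
    def preprocessed(self) -> bool:
        return self.tokens is not None


def normalize_text(text: str, metadata_patterns: Sequence[str] | None = None) -> str:
    """NFKC-normalize, ASCII-ify typographic punctuation, drop metadata lines."""
    text = unicodedata.normalize("NFKC", text).translate(_TRANSLATE)
    patterns = DEFAULT_METADATA_PATTERNS if metadata_patterns is None else metadata_patterns
    if patterns:
        regexes = [re.compile(p, re.IGNORECASE) for p in patterns]
        lines = [
            line for line in text.split("\n")
            if not any(r.match(line) for r in regexes)
        ]
        text = "\n".join(lines)
    return text


def ingest(
    doc_id: str,
    text: str | bytes,
    reference: ReferenceSequence,
    metadata_patterns: Sequence[str] | None = None,
) -> Document:
    """Build a Document: normalize, strip metadata lines, scan for mentions.

    Mention offsets refer to the stored (normalized) ``raw_text``.
    """
    if isinstance(text, bytes):
        try:
            text = text.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise CorpusError(f"document {doc_id!r}: undecodable input: {exc}") from exc
    raw = normalize_text(text, metadata_patterns)
    return Document(doc_id=doc_id, raw_text=raw, mentions=scan_text(raw, reference))


def _canonical_term(mention: VariantMention) -> str:
    # complete mentions normalize to HGVS; incomplete/discordant keep their
    # stated rendering, which can never collide with a true-reference HGVS key
    return mention.hgvs or mention.stated_name


def preprocess(document: Document, stopwords: Iterable[str] | None = None) -> Document:
    """Populate ``document.tokens`` (in place; also returned).

    Pipeline: mask mention spans with placeholders -> lowercase -> map
    punctuation and special symbols to spaces -> whitespace tokenize ->
    drop stopwords -> unmask placeholders to normalized variant terms.
    """
    stop = frozenset(stopwords) if stopwords is not None else default_stopwords()
    text = document.raw_text
    pieces: list[str] = []
    cursor = 0
    for i, mention in enumerate(document.mentions):
        pieces.append(text[cursor : mention.offset])
        pieces.append(f" {_PLACEHOLDER.format(i)} ")
        cursor = mention.offset + len(mention.raw_text)
    pieces.append(text[cursor:])
    masked = "".join(pieces).lower()
    cleaned = re.sub(r"[^a-z0-9]+", " ", masked)
    tokens: list[str] = []
    for tok in cleaned.split():
        m = _PLACEHOLDER_RE.match(tok)
        if m:
            tokens.append(_canonical_term(document.mentions[int(m.group(1))]))
        elif tok not in stop:
            tokens.append(tok)
    document.tokens = tokens
    return document


@dataclass
class DocumentTermMatrix:
    """Documents x terms nonnegative count matrix (CSR)."""

    doc_ids: list[str]
    terms: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.doc_ids), len(self.terms)):
            raise CorpusError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.doc_ids)} docs x {len(self.terms)} terms"
            )
        if len(set(self.terms)) != len(self.terms):
            raise CorpusError("duplicate terms in vocabulary")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise CorpusError("negative counts")

    def count(self, doc_id: str, term: str) -> int:
        i = self.doc_ids.index(doc_id)
        try:
            j = self.terms.index(term)
        except ValueError:
            return 0
        return int(self.counts[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame.sparse.from_spmatrix(
            self.counts, index=self.doc_ids, columns=self.terms
        )

    def write_mtx(self, prefix: str | Path) -> None:
        """Write ``<prefix>.mtx`` plus ``<prefix>.terms.txt`` / ``.docs.txt``."""
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), self.counts)
        prefix.with_suffix(".terms.txt").write_text("\n".join(self.terms) + "\n")
        prefix.with_suffix(".docs.txt").write_text("\n".join(self.doc_ids) + "\n")


def build_dtm(documents: Sequence[Document]) -> DocumentTermMatrix:
    """Count tokens per document into a sparse DTM (vocabulary sorted)."""
    for doc in documents:
        if not doc.preprocessed:
            raise CorpusError(f"document {doc.doc_id!r} has not been preprocessed")
    vocab = sorted({t for doc in documents for t in doc.tokens})
    index = {t: j for j, t in enumerate(vocab)}
    rows, cols, data = [], [], []
    for i, doc in enumerate(documents):
        seen: dict[int, int] = {}
        for tok in doc.tokens:
            j = index[tok]
            seen[j] = seen.get(j, 0) + 1
        for j, c in seen.items():
            rows.append(i)
            cols.append(j)
            data.append(c)
    counts = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(documents), len(vocab)), dtype=np.int64
    )
    return DocumentTermMatrix([d.doc_id for d in documents], vocab, counts)


def load_corpus_dir(
    directory: str | Path,
    reference: ReferenceSequence,
    metadata_patterns: Sequence[str] | None = None,
) -> list[Document]:
    """Ingest every ``<pmid>.txt`` file in a directory (sorted by name)."""
    docs = []
    for path in sorted(Path(directory).glob("*.txt")):
        docs.append(ingest(path.stem, path.read_text(), reference, metadata_patterns))
    return docs
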