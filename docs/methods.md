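# Methods

## Variant space

Coordinates are 1-based and inclusive against the rCRS (NC_012920.1), as in
HGVS `m.` notation. The locus catalogue carries the standard NC_012920.1
gene spans: 13 protein-coding genes (11,395 bases), 22 tRNAs (1,508 bases),
2 rRNAs (2,513 bases) and the D-loop, modelled as the origin-spanning pair
of segments 16024–16569 and 1–576 (1,122 bases). Enumeration yields the
three non-reference alleles at every position of every selected locus, so
per-locus dataset sizes are exactly 3 × locus length (tRNA 4,524, rRNA
7,539, D-loop 3,366, protein-coding 34,185); a position inside k
overlapping loci (the *MT-ATP8*/*MT-ATP6* and *MT-ND4L*/*MT-ND4* overlaps,
the abutting tRNAs) contributes one record per allele to each containing
locus, a deliberate double-counting that makes per-locus sets
self-contained. Intergenic positions are enumerable in genome-wide mode but
belong to no per-locus set.

Position 3107 of the rCRS is the placeholder `N` kept to preserve
historical numbering. It contributes three substitution records like any
other position; the excluded allele is the historical base C whose removal
the placeholder marks, so its alternates are A, G, T and its HGVS renders
as `m.3107N>{alt}`.

The bundled sequence (`data/rcrs_synthetic.fasta`) is a synthetic stand-in:
16,569 bases drawn from the approximate mtDNA base composition, `N` at
3107, and the reference alleles of well-known literature variants (3243A,
8993T, 8839G, 15132T, 2236T, 16362T, 15990C, 7480T, 8344A, 11778G, …)
planted at their true positions. Everything that depends only on spans
(all counts above) is exact; base identities at unplanted positions are
not the true rCRS, which matters only to reference validation of mentions
at those positions. Supplying a true rCRS FASTA to `load_reference`
replaces the stand-in transparently.

## Mention grammar

Five token formats are recognized, in precedence order:
`m.[POS][REF]>[ALT]`, `m.[POS][REF][ALT]`, `[REF][POS][ALT]`, `[POS][ALT]`,
`m.[POS][REF]`. Matching is case-insensitive, tolerates one space on each
side of `>`, and requires tokens to be isolated from surrounding
alphanumeric runs (so `A3243G` does not also yield `3243G`, and decimals
like `3.3243` yield nothing). When candidate spans overlap, the longest
match wins, then the earlier format. `N` is a legal stated reference behind
the `m.` prefix (position 3107) but never an alternate.

Validation against the reference is the disambiguation filter: positions
outside 1..16,569 are not mentions; a stated reference disagreeing with the
rCRS base gives `ref_discordant`; the alt-only `[POS][ALT]` form — which is
ambiguous with figure labels and years — is accepted only when the
reference at that position differs from the stated alternate. Discordant
mentions are retained in scan output (they are reviewable) but never reach
annotation; `m.[POS][REF]` mentions are `incomplete` and carry no variant
identity.

## Corpus and DTM

Preprocessing follows the standard recipe — lowercase, punctuation and
special-symbol removal, whitespace tokenization, stopword removal
(a bundled ~140-word English list, configurable) — with one deliberate
reordering: mentions are scanned on the raw text *before* cleaning and
masked with alphanumeric placeholders, because cleaning destroys tokens
like `m.8839G>C` irrecoverably. After tokenization each placeholder is
restored as the mention's normalized name, so every complete mention
appears as exactly one HGVS term. Ingestion NFKC-normalizes text and maps
typographic hyphens/quotes to ASCII (extracted PDF text is full of them)
and strips configurable header/footer metadata lines; offsets refer to this
stored text. PDF-to-text conversion is outside the contract — the pipeline
starts at plain text keyed by PMID.

The DTM is a documents × sorted-vocabulary sparse integer matrix counted
directly from the token lists (exported as MatrixMarket with sidecar term
and document files). Counting is deliberately transparent — it is one of
the independently-oracled operations — and is cross-checked against
scikit-learn's `CountVectorizer` in the tests.

## Evidence mining and association

Each minable criterion is backed by lowercase keyword patterns: a trailing
`*` makes a prefix pattern, a pattern with spaces is a phrase matched
against consecutive cleaned tokens (phrases cannot be DTM columns, which
are unigrams, so they are counted on the token streams). The bundled
lexicon is a curated starting point derived from the criterion wording
(heteroplasm\*, segregat\*, histochem\*, "respiratory chain", cybrid\*,
"steady state", "single fiber", disease/phenotype terms, …) and is fully
overridable by JSON config; the two conservation criteria are computed
quantities and are never mined — they enter as per-variant boolean inputs.

Association is document-scope by default: a variant term and a category
co-occurring in a document are paired, with a raw-text snippet (default
±120 characters) around the mention extracted for analyst review; this
mirrors a curation workflow in which a human checks context rather than an
algorithm. A stricter ±N-token window is available; association sets are
monotone nondecreasing as the window widens to document scope. An audit
file of per-(variant, category) confirmed/rejected decisions can be merged;
rejected associations are excluded from profiles and tables.

"Multiple reports" is operationalized as: pathogenicity-asserting support
(the disease-phenotype or pathogenicity-wording categories) from at least
two distinct document ids. Distinct PMIDs are a proxy for independent
reports; independent pedigrees cannot be distinguished from text alone.

## Scoring

Weights are fixed: multiple reports 2, PhastCons 1, PhyloP 1, heteroplasmy
2, segregation 2, histochemistry 2, OXPHOS biochemistry 2,
cybrid/steady-state 5, single-fiber 3; totals span 0–20 and conservation
contributes at most 2. Tier boundaries are a convention layered on top
(they are not part of the weight table): neutral polymorphism ≤6, possibly
pathogenic 7–10, definitely pathogenic ≥11 — with the top tier additionally
requiring cybrid/steady-state or single-fiber evidence, without which a
high score is capped at "possibly". Both boundaries and the gold-standard
clause are configurable. Profiles with missing criteria are refused unless
defaulting to `false` is explicitly requested; silent defaults would
inflate apparent neutrality.

## Database comparison

Mined and external variant sets, grouped by locus class, are compared by
set algebra: shared = intersection, only-X = difference, totals by column
sum, and the additional-information percentage
100 × only_pipeline_total / pipeline_total rounded half-up to two decimals.
A second constructor consumes fully printed comparison rows (all five
columns as given, identities not enforced) so externally curated tables
whose only-columns reflect additional filtering can be summarized exactly
as published.

## Synthetic corpus

The generator emulates the input the pipeline would see after PDF
extraction: filler prose from a bundled neutral word list, interleaved with
planted variant tokens (format sampled from a configurable mix over the
five formats), planted category keywords (surface forms derived from the
lexicon patterns so they match by construction), and optional decoys —
years, `n=…` sample sizes, out-of-range positions, and reference-discordant
tokens at a configurable rate. Defaults: 50 documents, 1–3 variants and 1–2
categories per document, uniform format and category mixes, no decoys.
The manifest records every plant with its character offset and exposes the
(variant, category, document) triple set for complete, concordant plants;
incomplete-format plants (`m.[POS][REF]`) carry no variant identity and are
recorded but excluded from triples. The same seed reproduces the corpus
byte for byte.

What passing recovery tests shows — and does not. On decoy-free corpora
the pipeline's precision and recall against the manifest are exactly 1.0,
and with decoys no discordant or out-of-range token reaches the annotation
table. The generator does not emulate PDF layout damage (hyphenation,
column interleaving), novel phrasings outside the lexicon, negated or
speculative statements, or variant–evidence pairs split across sentences
with contrasting referents; on real literature, recall is bounded by the
lexicon and precision by document-scope co-occurrence, which is why the
analyst audit step exists.

## Search stage

Gene-name queries OR the locus name with its synonyms and AND the fixed
terms "human", "mitochondrial", "variant"; variant-name queries quote one
HGVS string each, deduplicated. PMID lists merge by first-seen order with
per-query provenance. Abstract screening keeps a document iff it contains
at least one complete mention or one lexicon keyword ("functional studies
and/or variant" read as OR). Retrieval is a backend interface: the fixture
store (JSON of query → PMIDs, PMID → abstract) makes runs bit-identical and
offline; the live E-utilities client (stdlib urllib, rate-capped, contact
email and optional API key) exists for real use and is intentionally
untested, since live PubMed counts drift and cannot anchor tests.

## Numerical and procedural choices

- Percentage rounding: decimal half-up to 2 places (banker's rounding would
  differ on exact halves).
- Problem sizes in tests and the acceptance script (50-document corpora,
  400-document corpora for mix calibration, 100 random set pairs, the full
  512-profile sweep, round-trip over the full enumeration) were chosen so
  the whole suite completes in well under a minute while still exercising
  every code path exhaustively where the space is finite.
- Acceptance-script randomness derives entirely from `--seed`; enumeration,
  scoring and comparison arithmetic are deterministic.

## Known limitations

- The protein-coding per-locus total (34,185 = 3 × 11,395) follows the
  standard NC_012920.1 CDS spans; published per-locus tallies using other
  boundary conventions (e.g. including flanking bases) will differ.
- Mention recognition does not cover protein-level (p.) notation, rsIDs, or
  insertion/deletion syntax.
- The bare `[POS][ALT]` rule trades recall for precision: a genuine mention
  at a position whose reference equals the stated alternate is
  unrecoverable by design.
- Relation extraction is co-occurrence, not parsing: no negation handling,
  no cross-sentence coreference.
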