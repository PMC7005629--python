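# mtmine

Literature mining and pathogenicity annotation of human mitochondrial DNA
variants.

Human mtDNA is a 16,569-bp circular genome encoding 13 proteins, 22 tRNAs
and 2 rRNAs, plus the non-coding D-loop control region. Any position can in
principle carry three single-nucleotide substitutions against the revised
Cambridge Reference Sequence (rCRS, NC_012920.1), and the clinical status of
most of those potential variants is unknown: the evidence that settles it —
heteroplasmy, segregation with disease, histochemical and biochemical
defects, trans-mitochondrial cybrid and single-fiber studies — is scattered
through decades of literature, where the same variant is written as
`m.3243A>G`, `A3243G`, `3243G`, `m.3243AG` or `m.3243A` depending on the
journal and year.

`mtmine` is a toolkit for clinicians and curators of mtDNA variant
databases. It:

- enumerates the complete space of potential substitutions per locus
  (3 per base; positions inside overlapping genes such as *MT-ATP8*/*MT-ATP6*
  are attributed to each containing locus);
- recognizes variant mentions in text across the five token formats above,
  validating every candidate against the rCRS allele — a stated reference
  that disagrees is flagged `ref_discordant`, a bare `[POS][ALT]` numeral is
  accepted only when it passes reference validation;
- builds PubMed queries (gene name + synonyms AND "human", "mitochondrial",
  "variant"; one query per HGVS name), merges PMID lists and screens
  abstracts, through a pluggable backend (offline fixture store, or a live
  E-utilities client);
- constructs a Document-Term Matrix with variant tokens protected from the
  destructive cleaning steps, subsets it against the variant universe and a
  configurable functional-evidence keyword lexicon, and associates variants
  with evidence categories per document;
- scores tRNA variants with the weighted criteria system
  (multiple reports 2, PhastCons 1, PhyloP 1, heteroplasmy 2, segregation 2,
  histochemistry 2, OXPHOS biochemistry 2, cybrid/steady-state 5,
  single-fiber 3; range 0–20; tiers neutral ≤6, possibly 7–10, definitely
  ≥11 with functional gold-standard evidence required for the top tier);
- compiles annotation tables and shared/only comparison statistics against
  external variant databases.

The bundled sequence fixture is a clearly labelled **synthetic stand-in**
for the rCRS (correct length, `N` at position 3107, the reference alleles of
well-known literature variants planted at their true positions); the locus
coordinate table is the standard NC_012920.1 annotation and is exact, so all
per-locus counts are exact.

## Worked example

```python
import mtmine as m

reference, catalogue = m.load_reference()
print(m.per_locus_counts(catalogue, reference))
# {'protein_coding': 34185, 'tRNA': 4524, 'rRNA': 7539, 'D_loop': 3366}

mention = m.parse_mention("A3243G", reference)
print(mention.hgvs, mention.token_format, mention.status)
# m.3243A>G [REF][POS][ALT] complete

texts = [
    ("28000001", "The proband carried m.8839G > C with marked heteroplasmy and myopathy."),
    ("28000002", "Transmitochondrial cybrids confirmed m.8839G>C; segregation was noted."),
]
docs = [m.ingest(pmid, text, reference) for pmid, text in texts]
result = m.run_text_mining(docs, reference, catalogue)
for a in result.associations:
    print(a.hgvs, a.category, a.supporting_docs)
# m.8839G>C cybrid_steadystate ('28000002',)
# m.8839G>C disease_phenotype ('28000001',)
# m.8839G>C heteroplasmy ('28000001',)
# m.8839G>C segregation ('28000002',)
sr = result.scores["m.8839G>C"]
print(sr.total, sr.tier)
# 9 possibly_pathogenic
```

The 4,524 tRNA records are 3 substitutions for each of the 1,508 tRNA bases;
`m.8839G>C` (an *MT-ATP6* variant reported in NARP syndrome) collects four
evidence categories across the two documents and scores
2 (heteroplasmy) + 2 (segregation) + 5 (cybrids) = 9 points — "possibly
pathogenic", since only one document asserts pathogenicity and no
conservation input was supplied.

The same stages are available from the shell:

```bash
mtmine enumerate --locus-type tRNA --out trna.tsv
mtmine simulate --n-docs 50 --seed 7 --out corpus/
mtmine mine --corpus corpus/ --out annotations.tsv
mtmine score --in criteria.tsv --out scores.tsv
mtmine compare --pipeline mined.tsv --external mitomap.tsv --out table.tsv
```

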