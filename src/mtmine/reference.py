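"""Mitochondrial reference sequence, locus catalogue, and variant-space enumeration.

The human mitochondrial genome is a 16,569-bp circular molecule carrying 37
genes (13 protein-coding, 22 tRNA, 2 rRNA) plus the non-coding control region
(D-loop), which spans the origin and is modelled here as the two segments
16024-16569 and 1-576.  Coordinates are 1-based and inclusive, as in HGVS
``m.`` notation against the revised Cambridge Reference Sequence (rCRS,
NC_012920.1).  Position 3107 of the rCRS is the placeholder symbol ``N``,
kept to preserve historical numbering.

The bundled sequence fixture (``data/rcrs_synthetic.fasta``) is a synthetic
stand-in for the rCRS: correct length, ``N`` at 3107, and the reference
alleles of the well-known literature variants planted at their true
positions.  The locus table (``data/nc_012920_loci.tsv``) carries the
standard NC_012920.1 gene coordinates and is exact.

Enumeration produces, for every position of every selected locus, the three
non-reference substitutions.  A position lying inside k overlapping loci
(e.g. the ATP8/ATP6 overlap) contributes one record per allele to each
locus's set, so per-locus counts intentionally double-count overlaps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

MT_LENGTH = 16569
N_POSITION = 3107
#: allele excluded at the rCRS ``N`` placeholder: the historical CRS base
N_POSITION_HISTORICAL_BASE = "C"
ALLELES = ("A", "C", "G", "T")
LOCUS_TYPES = ("protein_coding", "tRNA", "rRNA", "D_loop")


class ReferenceError(ValueError):
    """Raised when the bundled or user-supplied reference fails validation."""


@dataclass(frozen=True)
class ReferenceSequence:
    """The mitochondrial reference as an immutable 1-based sequence."""

    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != MT_LENGTH:
            raise ReferenceError(
                f"reference length {len(self.bases)} != {MT_LENGTH}"
            )
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ReferenceError(f"non-nucleotide symbols in reference: {sorted(bad)}")
        if self.bases[N_POSITION - 1] != "N":
            raise ReferenceError(f"position {N_POSITION} must be the placeholder N")
        if self.bases.count("N") != 1:
            raise ReferenceError("exactly one N (position 3107) is allowed")

    def __len__(self) -> int:
        return MT_LENGTH

    def base_at(self, position: int) -> str:
        """Reference allele at a 1-based position."""
        if not 1 <= position <= MT_LENGTH:
            raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
        return self.bases[position - 1]


@dataclass(frozen=True)
class LocusSpan:
    """One catalogued locus: name, synonyms, class, strand and its segment(s)."""

    name: str
    synonyms: tuple[str, ...]
    locus_type: str
    segments: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        if self.locus_type not in LOCUS_TYPES:
            raise ReferenceError(f"{self.name}: unknown locus_type {self.locus_type!r}")
        if self.strand not in ("heavy", "light"):
            raise ReferenceError(f"{self.name}: unknown strand {self.strand!r}")
        for start, end in self.segments:
            if not 1 <= start <= end <= MT_LENGTH:
                raise ReferenceError(
                    f"{self.name}: segment {start}-{end} outside 1..{MT_LENGTH}"
                )

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.segments)

    def contains(self, position: int) -> bool:
        return any(start <= position <= end for start, end in self.segments)

    def positions(self) -> Iterable[int]:
        for start, end in self.segments:
            yield from range(start, end + 1)


@dataclass(frozen=True)
class VariantRecord:
    """One potential single-nucleotide substitution against the reference.

    ``locus`` is the locus this record is attributed to in a per-locus
    dataset (``None`` for an intergenic record in genome-wide mode);
    ``loci`` lists every locus containing the position, so a record in the
    ATP8/ATP6 overlap attributed to ATP8 still knows it also lies in ATP6.
    """

    position: int
    ref: str
    alt: str
    locus: str | None = field(default=None, compare=True)
    loci: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.position}")
        if self.alt not in ALLELES:
            raise ValueError(f"invalid alt allele {self.alt!r}")

    @property
    def hgvs(self) -> str:
        return f"m.{self.position}{self.ref}>{self.alt}"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("mtmine.data").joinpath(name)))


def load_reference(
    fasta: str | Path | None = None,
    loci_tsv: str | Path | None = None,
) -> tuple[ReferenceSequence, list[LocusSpan]]:
    """Load the reference sequence and locus catalogue.

    With no arguments, the bundled fixtures are used: the synthetic rCRS
    stand-in and the NC_012920.1 locus table.  Returns a validated
    ``(ReferenceSequence, catalogue)`` pair; the catalogue holds exactly
    13 protein-coding, 22 tRNA, 2 rRNA loci and 1 D-loop region.
    """
    fasta = Path(fasta) if fasta is not None else _data_path("rcrs_synthetic.fasta")
    loci_tsv = Path(loci_tsv) if loci_tsv is not None else _data_path("nc_012920_loci.tsv")

    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ReferenceError(f"{fasta}: expected a single FASTA record, found {len(records)}")
    reference = ReferenceSequence(str(records[0].seq).upper())

    catalogue: list[LocusSpan] = []
    with open(loci_tsv, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                segments = tuple(
                    (int(a), int(b))
                    for a, b in (seg.split("-") for seg in row["segments"].split(";"))
                )
                catalogue.append(
                    LocusSpan(
                        name=row["name"],
                        synonyms=tuple(s for s in row["synonyms"].split(";") if s),
                        locus_type=row["locus_type"],
                        segments=segments,
                        strand=row["strand"],
                    )
                )
            except (KeyError, ValueError, ReferenceError) as exc:
                raise ReferenceError(f"{loci_tsv} line {i} ({row.get('name', '?')}): {exc}") from exc
    _validate_catalogue(catalogue)
    return reference, catalogue


def _validate_catalogue(catalogue: Sequence[LocusSpan]) -> None:
    counts = {t: sum(1 for l in catalogue if l.locus_type == t) for t in LOCUS_TYPES}
    expected = {"protein_coding": 13, "tRNA": 22, "rRNA": 2, "D_loop": 1}
    if counts != expected:
        raise ReferenceError(f"catalogue composition {counts} != {expected}")
    names = [l.name for l in catalogue]
    if len(set(names)) != len(names):
        raise ReferenceError("duplicate locus names in catalogue")


def loci_at_position(catalogue: Sequence[LocusSpan], position: int) -> list[str]:
    """Names of all loci whose segments contain the position (catalogue order).

    Overlapping genes (ATP8/ATP6, ND4L/ND4, the abutting tRNAs) return more
    than one name; intergenic positions return an empty list.
    """
    if not 1 <= position <= MT_LENGTH:
        raise ValueError(f"position {position} outside 1..{MT_LENGTH}")
    return [locus.name for locus in catalogue if locus.contains(position)]


def _alts_for(ref: str) -> tuple[str, ...]:
    if ref == "N":
        # the placeholder contributes the three alleles that are not the
        # historical base whose deletion it marks
        return tuple(a for a in ALLELES if a != N_POSITION_HISTORICAL_BASE)
    return tuple(a for a in ALLELES if a != ref)


def enumerate_variants(
    catalogue: Sequence[LocusSpan],
    reference: ReferenceSequence,
    locus_type: str | None = None,
    include_intergenic: bool = False,
) -> list[VariantRecord]:
    """Enumerate every potential substitution in the selected loci.

    Each position of each selected locus yields exactly three records (the
    non-reference alleles) attributed to that locus, so a position inside k
    overlapping loci contributes 3k records and per-locus dataset sizes are
    exactly 3 x locus length.  With ``include_intergenic`` (genome-wide mode
    only), positions outside every locus are emitted with ``locus=None``;
    they never appear in any per-locus set.  Records are sorted by
    (position, alt), ties broken by catalogue order of the attributed locus.
    """
    if locus_type is not None and locus_type not in LOCUS_TYPES:
        raise ValueError(f"unknown locus_type {locus_type!r}")
    selected = [l for l in catalogue if locus_type is None or l.locus_type == locus_type]
    order = {l.name: i for i, l in enumerate(catalogue)}
    containing = {}  # position -> tuple of containing locus names, lazily filled
    out: list[VariantRecord] = []

    def _emit(pos: int, locus_name: str | None) -> None:
        ref = reference.base_at(pos)
        if pos not in containing:
            containing[pos] = tuple(loci_at_position(catalogue, pos))
        for alt in _alts_for(ref):
            out.append(
                VariantRecord(pos, ref, alt, locus=locus_name, loci=containing[pos])
            )

    for locus in selected:
        for pos in locus.positions():
            _emit(pos, locus.name)
    if include_intergenic and locus_type is None:
        genic = {p for locus in catalogue for p in locus.positions()}
        for pos in range(1, MT_LENGTH + 1):
            if pos not in genic:
                _emit(pos, None)
    out.sort(key=lambda r: (r.position, r.alt, order.get(r.locus, len(order))))
    return out


def per_locus_counts(
    catalogue: Sequence[LocusSpan], reference: ReferenceSequence
) -> dict[str, int]:
    """Number of potential substitutions per locus class (overlaps double-counted).

    This is the per-class dataset size: 3 records per base of each locus,
    summed over loci, so bases shared by overlapping genes count once per
    containing locus.
    """
    counts: dict[str, int] = {t: 0 for t in LOCUS_TYPES}
    for locus in catalogue:
        counts[locus.locus_type] += 3 * locus.length
    return counts


def variant_universe(
    catalogue: Sequence[LocusSpan],
    reference: ReferenceSequence,
    include_intergenic: bool = True,
) -> set[str]:
    """All valid normalized HGVS strings (genome-wide), for membership checks."""
    universe: set[str] = set()
    for pos in range(1, MT_LENGTH + 1):
        ref = reference.base_at(pos)
        for alt in _alts_for(ref):
            if include_intergenic or loci_at_position(catalogue, pos):
                universe.add(f"m.{pos}{ref}>{alt}")
    return universe


def write_enumeration_tsv(
    records: Sequence[VariantRecord],
    path: str | Path,
    catalogue: Sequence[LocusSpan] | None = None,
) -> None:
    """Write enumeration as TSV: hgvs, position, ref, alt, locus, locus_type."""
    types = {l.name: l.locus_type for l in catalogue} if catalogue else {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["hgvs", "position", "ref", "alt", "locus", "locus_type", "all_loci"])
        for rec in records:
            writer.writerow(
                [
                    rec.hgvs,
                    rec.position,
                    rec.ref,
                    rec.alt,
                    rec.locus or "",
                    types.get(rec.locus, "intergenic" if rec.locus is None else ""),
                    ";".join(rec.loci),
                ]
            )


def write_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """VCF-compatible export (CHROM=chrM, 1-based POS, REF, ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chrM,length={MT_LENGTH}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in records:
            info = f"LOCI={','.join(rec.loci)}" if rec.loci else "."
            fh.write(f"chrM\t{rec.position}\t{rec.hgvs}\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n")
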