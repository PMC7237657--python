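"""Genomic landscape of the locus: intervals, annotated elements and
restriction-fragment maps.

The 11p15.5 imprinted region is modelled as a set of annotated intervals
(genes, imprinting control regions, CTCF-site clusters, enhancers, 3C
primers) on a single coordinate axis, plus a restriction-fragment map
obtained by in-silico digestion of the region's sequence.  Coordinates are
0-based half-open (BED convention) everywhere in memory and in BED I/O;
1-based closed coordinates appear only in human-readable reports.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Element categories recognised in annotation files.
ELEMENT_KINDS = frozenset(
    {"gene", "ICR", "CTCF_cluster", "enhancer", "anchor_primer", "test_primer"}
)

#: IUPAC nucleotide alphabet accepted in sequences to digest.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) for {self.name!r}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class AnnotatedElement:
    """A regulatory element, gene or 3C primer anchored on the region."""

    interval: GenomicInterval
    kind: str
    orientation_note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValidationError(
                f"unknown element kind {self.kind!r}; expected one of {sorted(ELEMENT_KINDS)}"
            )

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass(frozen=True)
class RestrictionEnzymeSpec:
    """A restriction enzyme as a recognition motif plus top-strand cut offset."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or set(self.recognition) - set("ACGT"):
            raise ValidationError(
                f"recognition motif must be non-empty A/C/G/T, got {self.recognition!r}"
            )
        if not (0 <= self.cut_offset <= len(self.recognition)):
            raise ValidationError("cut_offset must lie within the recognition motif")


#: Enzymes used by the 3C protocol (primary digest and re-digest). Both
#: motifs are palindromic, so top-strand scanning is lossless.
ENZYMES: dict[str, RestrictionEnzymeSpec] = {
    "BglII": RestrictionEnzymeSpec("BglII", "AGATCT", 1),
    "BamHI": RestrictionEnzymeSpec("BamHI", "GGATCC", 1),
}


@dataclass(frozen=True)
class RestrictionFragment:
    """One fragment of a complete digest; fragments tile the region."""

    index: int
    interval: GenomicInterval
    enzyme: str

    @property
    def name(self) -> str:
        return self.interval.name


def parse_elements(path: str | Path) -> list[AnnotatedElement]:
    """Read a 5-column BED-like file (chrom, start, end, name, kind).

    Blank lines and ``#`` comments are skipped.  Elements are returned in
    coordinate order regardless of file order.

    Raises
    ------
    ParseError
        On a malformed line (names the line number).
    ValidationError
        On an unknown element kind or an invalid interval.
    """
    path = Path(path)
    elements: list[AnnotatedElement] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(
                    f"{path.name} line {lineno}: expected 5 columns "
                    f"(chrom start end name kind), got {len(fields)}"
                )
            chrom, start_s, end_s, name, kind = fields[:5]
            note = fields[5] if len(fields) > 5 else ""
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            try:
                interval = GenomicInterval(chrom, start, end, name=name)
                elements.append(AnnotatedElement(interval, kind, note))
            except ValidationError as exc:
                raise ValidationError(f"{path.name} line {lineno}: {exc}") from exc
    elements.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return elements


def write_elements(elements: Iterable[AnnotatedElement], path: str | Path) -> None:
    """Write elements as the 5-column BED-like TSV read by :func:`parse_elements`."""
    with Path(path).open("w") as fh:
        for e in elements:
            iv = e.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name, e.kind]
            if e.orientation_note:
                cols.append(e.orientation_note)
            fh.write("\t".join(cols) + "\n")


def read_region_fasta(path: str | Path) -> tuple[str, str]:
    """Return (record id, uppercase sequence) of the first FASTA record."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def digest_sequence(
    seq: str,
    region_start: int,
    enzyme: RestrictionEnzymeSpec,
    chrom: str = "chr11",
) -> list[RestrictionFragment]:
    """In-silico complete digest of a linear sequence.

    Cut positions are every non-overlapping motif occurrence start (scanned
    greedily left to right) plus the enzyme's top-strand cut offset.  The
    returned fragments tile ``[region_start, region_start + len(seq))``
    exactly; a sequence without sites yields a single fragment.
    """
    if not seq:
        raise ValidationError("sequence must be non-empty")
    seq = seq.upper()
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValidationError(f"non-IUPAC characters in sequence: {sorted(bad)}")

    motif = enzyme.recognition
    cuts: list[int] = []
    i = seq.find(motif)
    while i != -1:
        cut = i + enzyme.cut_offset
        if 0 < cut < len(seq):
            cuts.append(cut)
        i = seq.find(motif, i + len(motif))

    bounds = [0] + cuts + [len(seq)]
    fragments = []
    for idx, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        iv = GenomicInterval(
            chrom, region_start + lo, region_start + hi, name=f"frag_{idx:03d}"
        )
        fragments.append(RestrictionFragment(idx, iv, enzyme.name))
    return fragments


@dataclass(frozen=True)
class FragmentAxis:
    """The fragment coordinate axis of one 3C anchor.

    ``anchor`` is the fragment containing the anchor primer; ``tests`` are
    the coordinate-ordered fragments covered by test primers.
    """

    anchor: RestrictionFragment
    tests: tuple[RestrictionFragment, ...]

    @property
    def test_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.tests)


def _fragment_for(
    primer: AnnotatedElement, fragments: Sequence[RestrictionFragment]
) -> RestrictionFragment:
    starts = [f.interval.start for f in fragments]
    i = bisect_right(starts, primer.interval.start) - 1
    if i < 0:
        raise ValidationError(f"primer {primer.name!r} lies before the fragment map")
    frag = fragments[i]
    if frag.interval.contains(primer.interval):
        return frag
    if primer.interval.start < frag.interval.end < primer.interval.end:
        raise ValidationError(
            f"primer {primer.name!r} straddles the restriction site at "
            f"{frag.interval.end}; redesign or drop it"
        )
    raise ValidationError(f"primer {primer.name!r} lies outside the fragment map")


def locate_fragments(
    primers: Iterable[AnnotatedElement],
    fragments: Sequence[RestrictionFragment],
    anchor_name: str,
) -> FragmentAxis:
    """Assign 3C primers to restriction fragments and build an anchor's axis.

    Every primer must fall entirely inside one fragment (a primer spanning a
    cut site is rejected).  Multiple test primers in the same fragment
    collapse to a single axis entry with a logged warning.
    """
    primers = [p for p in primers if p.kind in {"anchor_primer", "test_primer"}]
    anchor_primer = next((p for p in primers if p.name == anchor_name), None)
    if anchor_primer is None:
        raise ValidationError(f"anchor primer {anchor_name!r} not found")
    anchor_frag = _fragment_for(anchor_primer, fragments)

    seen: dict[int, str] = {}
    tests: list[RestrictionFragment] = []
    for p in primers:
        if p.name == anchor_name or p.kind != "test_primer":
            continue
        frag = _fragment_for(p, fragments)
        if frag.index in seen:
            logger.warning(
                "primers %r and %r share fragment %s; keeping one axis entry",
                seen[frag.index], p.name, frag.name,
            )
            continue
        seen[frag.index] = p.name
        tests.append(frag)
    tests.sort(key=lambda f: f.interval.start)
    return FragmentAxis(anchor_frag, tuple(tests))


def fragments_to_bed(
    fragments: Iterable[RestrictionFragment], path: str | Path
) -> None:
    """Export a fragment map as BED (chrom, start, end, name, index, enzyme)."""
    with Path(path).open("w") as fh:
        for f in fragments:
            iv = f.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{f.index}\t{f.enzyme}\n"
            )


def fragments_from_bed(path: str | Path) -> list[RestrictionFragment]:
    """Read a fragment map written by :func:`fragments_to_bed`."""
    frags = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path} line {lineno}: expected 6 columns")
            chrom, start, end, name, index, enzyme = fields[:6]
            iv = GenomicInterval(chrom, int(start), int(end), name=name)
            frags.append(RestrictionFragment(int(index), iv, enzyme))
    frags.sort(key=lambda f: f.index)
    return frags
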