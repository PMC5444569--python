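"""Core domain types and coordinate conventions.

Conventions used throughout the package:

* all coordinates are 0-based, half-open ``[start, end)``; 1-based inclusive
  coordinates appear only at the GFF3 / GenBank boundaries;
* a :class:`Locus` stores its sequence already in *gene orientation* — for a
  reverse-strand locus the stored string is the reverse complement of the
  genomic slice, so every downstream operation (part splitting, splicing,
  recoding) is orientation-free.  The :class:`StrandedLocation` in
  ``Locus.origin`` retains the original genomic frame;
* a gene is an ordered assembly of exactly five part slots —
  promoter, 5'UTR, CDS, 3'UTR, terminator — whose genomic spans tile the
  locus; 5'/3'UTR slots may be zero-length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .errors import StructuralError

PART_TYPES: Tuple[str, ...] = ("promoter", "utr5", "cds", "utr3", "terminator")
#: Part slots that may legitimately be empty (zero-length span).
OPTIONAL_PART_TYPES = frozenset({"utr5", "utr3"})
#: Part slots carrying exon structure (transcribed parts).
TRANSCRIBED_PART_TYPES = frozenset({"utr5", "cds", "utr3"})

FORWARD = "+"
REVERSE = "-"
STRANDS = (FORWARD, REVERSE)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` in base pairs.

    Zero-length intervals (``start == end``) are permitted to represent empty
    UTR slots; validation of strictness where required (exons, locus origins)
    happens at the point of use.
    """

    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"interval start must be non-negative, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset)


@dataclass(frozen=True)
class StrandedLocation:
    """A contig-anchored, strand-oriented span in genomic coordinates."""

    contig_id: str
    span: Interval
    strand: str

    def __post_init__(self):
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class ExonChain:
    """Ordered exon intervals in locus-local, gene-oriented coordinates.

    Exons are sorted ascending and pairwise non-overlapping.  An empty chain
    is allowed only for empty (zero-length) UTR parts; :func:`validate_gene`
    flags it elsewhere.
    """

    exons: Tuple[Interval, ...]

    def __init__(self, exons: Iterable[Interval]):
        object.__setattr__(self, "exons", tuple(exons))

    def __iter__(self):
        return iter(self.exons)

    def __len__(self):
        return len(self.exons)

    @property
    def span(self) -> Optional[Interval]:
        if not self.exons:
            return None
        return Interval(
            min(e.start for e in self.exons), max(e.end for e in self.exons)
        )

    @property
    def total_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def violations(self) -> List[str]:
        out = []
        for e in self.exons:
            if len(e) == 0:
                out.append(f"zero-length exon {e.start}-{e.end}")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.start:
                out.append(f"exons out of order: {a} before {b}")
            elif b.start < a.end:
                out.append(f"exons overlap: {a} and {b}")
        return out


@dataclass(frozen=True)
class Part:
    """A typed genetic part anchored on its locus.

    ``sequence`` is the *genomic* (unspliced) subsequence of the locus over
    ``genomic_span``, in gene orientation.  Spliced sequences of transcribed
    parts are recovered from the exon chain (see
    :func:`genoparts.split.spliced_sequence`).
    """

    part_id: str
    part_type: str
    genomic_span: Interval
    exons: ExonChain
    sequence: str

    def __post_init__(self):
        if self.part_type not in PART_TYPES:
            raise StructuralError(f"unknown part type {self.part_type!r}")

    @property
    def is_empty(self) -> bool:
        return len(self.genomic_span) == 0


@dataclass
class Gene:
    """An ordered assembly of the five part slots for one isoform/ORF."""

    gene_id: str
    locus_id: str
    transcript_id: str
    parts: Dict[str, Part]
    is_primary: bool = True
    aliases: Tuple[str, ...] = ()

    def part(self, part_type: str) -> Part:
        return self.parts[part_type]

    @property
    def cds_id(self) -> str:
        return self.parts["cds"].part_id

    @property
    def span(self) -> Interval:
        return Interval(
            self.parts["promoter"].genomic_span.start,
            self.parts["terminator"].genomic_span.end,
        )


@dataclass
class Locus:
    """A flank-padded, strand-oriented genomic window holding ≥1 genes."""

    locus_id: str
    origin: StrandedLocation
    sequence: str
    genes: List[Gene] = field(default_factory=list)

    def __len__(self):
        return len(self.sequence)

    def slice(self, interval: Interval) -> str:
        if interval.end > len(self.sequence):
            raise ValueError(
                f"interval {interval} outside locus {self.locus_id} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[interval.start : interval.end]


@dataclass(frozen=True)
class TranscriptMapping:
    """Exon-level transcript→genome mapping (spliced-aligner output).

    ``exon_pairs`` is ordered by ascending transcript coordinate; the
    transcript intervals partition ``[0, transcript_length)``.  On the reverse
    strand the genomic intervals descend along the contig.
    """

    transcript_id: str
    location: StrandedLocation
    exon_pairs: Tuple[Tuple[Interval, Interval], ...]
    identity: float = 100.0
    coverage: float = 100.0

    def __init__(self, transcript_id, location, exon_pairs, identity=100.0, coverage=100.0):
        object.__setattr__(self, "transcript_id", transcript_id)
        object.__setattr__(self, "location", location)
        object.__setattr__(self, "exon_pairs", tuple((t, g) for t, g in exon_pairs))
        object.__setattr__(self, "identity", float(identity))
        object.__setattr__(self, "coverage", float(coverage))
        self._validate()

    def _validate(self):
        if not self.exon_pairs:
            raise ValueError(f"mapping {self.transcript_id} has no exons")
        pos = 0
        for t, g in self.exon_pairs:
            if len(t) != len(g):
                raise ValueError(
                    f"mapping {self.transcript_id}: transcript exon {t} and "
                    f"genomic exon {g} differ in length"
                )
            if t.start != pos:
                raise ValueError(
                    f"mapping {self.transcript_id}: transcript intervals do not "
                    f"partition the transcript (gap/overlap at {t.start})"
                )
            pos = t.end
        gs = sorted((g for _, g in self.exon_pairs), key=lambda i: i.start)
        for a, b in zip(gs, gs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"mapping {self.transcript_id}: genomic exons overlap ({a}, {b})"
                )

    @property
    def transcript_length(self) -> int:
        return self.exon_pairs[-1][0].end

    @property
    def genomic_span(self) -> Interval:
        gs = [g for _, g in self.exon_pairs]
        return Interval(min(g.start for g in gs), max(g.end for g in gs))


@dataclass(frozen=True)
class OrfPrediction:
    """An open reading frame on the spliced transcript.

    ``orf_span`` covers the coding region *including* the stop codon when one
    is present; ``protein`` never includes the stop.  ORFs reaching the
    transcript end without a stop are flagged ``partial``.
    """

    transcript_id: str
    orf_span: Interval
    protein: str
    partial: bool = False

    def __post_init__(self):
        if len(self.orf_span) % 3:
            raise ValueError(
                f"ORF length {len(self.orf_span)} on {self.transcript_id} "
                "is not divisible by 3"
            )
        expected = len(self.orf_span) // 3 - (0 if self.partial else 1)
        if len(self.protein) != expected:
            raise ValueError(
                f"ORF on {self.transcript_id}: protein length {len(self.protein)} "
                f"does not match span ({expected} expected)"
            )


@dataclass(frozen=True)
class AnnotationHit:
    """BLASTp or Pfam evidence attached to a CDS (coordinates on the protein)."""

    cds_id: str
    source: str  # "blastp" | "pfam"
    accession: str
    keywords: Tuple[str, ...]
    e_value: float
    bitscore: float
    hit_span: Interval
    identity: Optional[float] = None            # blastp only
    coverage_per_subject: Optional[float] = None  # blastp only
    gathering_threshold: Optional[float] = None   # pfam only

    def __post_init__(self):
        if self.source not in ("blastp", "pfam"):
            raise StructuralError(f"unknown hit source {self.source!r}")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if self.source == "blastp" and (
            self.identity is None or self.coverage_per_subject is None
        ):
            raise StructuralError("blastp hit requires identity and coverage_per_subject")


def validate_gene(gene: Gene, locus: Locus) -> List[str]:
    """Check all structural invariants of ``gene`` against its locus.

    Returns a list of human-readable violation descriptions (empty when the
    gene is fully consistent).  Unknown part types raise
    :class:`~genoparts.errors.StructuralError` at :class:`Part` construction,
    so only slot-level problems are reported here.
    """
    violations: List[str] = []
    for pt in gene.parts:
        if pt not in PART_TYPES:
            raise StructuralError(f"unknown part type {pt!r} in gene {gene.gene_id}")
    for pt in PART_TYPES:
        if pt not in gene.parts:
            violations.append(f"missing part slot {pt}")
    if violations:
        return violations

    length = len(locus)
    prev_end = None
    for pt in PART_TYPES:
        part = gene.parts[pt]
        span = part.genomic_span
        if span.end > length:
            violations.append(f"{pt}: span {span} outside locus of length {length}")
        if len(part.sequence) != len(span):
            violations.append(
                f"{pt}: sequence length {len(part.sequence)} != span length {len(span)}"
            )
        if len(span) == 0 and pt not in OPTIONAL_PART_TYPES:
            violations.append(f"{pt}: required part is empty")
        if prev_end is not None and span.start != prev_end:
            violations.append(
                f"{pt}: span start {span.start} does not abut previous part end {prev_end}"
            )
        prev_end = span.end

        chain = part.exons
        for v in chain.violations():
            violations.append(f"{pt}: {v}")
        if len(chain) == 0:
            if len(span) != 0:
                violations.append(f"{pt}: non-empty part with empty exon chain")
        else:
            cspan = chain.span
            if not span.contains(cspan):
                violations.append(f"{pt}: exon union {cspan} outside span {span}")
            if pt in ("promoter", "terminator") and (
                len(chain) != 1 or chain.exons[0] != span
            ):
                violations.append(f"{pt}: must consist of a single exon equal to its span")
    return violations
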