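"""Locus building: cluster transcript mappings, extract flank-padded windows.

Isoforms with overlapping genomic spans (≥1 bp, same contig, same strand by
default) are assigned to the same locus; each locus window is the union of
its transcript spans extended by a flank (default 3000 bp) on each side,
clipped to the contig.  Reverse-strand loci are stored reverse-complemented
so all downstream part logic runs in gene orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from .datamodel import (
    FORWARD,
    REVERSE,
    Interval,
    Locus,
    StrandedLocation,
    TranscriptMapping,
)
from .errors import ConsistencyError, MissingReferenceError
from .sequence import normalize_dna, reverse_complement

DEFAULT_FLANK = 3000
DEFAULT_MIN_MAPPING_IDENTITY = 99.0
DEFAULT_MIN_MAPPING_COVERAGE = 99.0


def filter_mappings(
    mappings: Sequence[TranscriptMapping],
    min_identity: float = DEFAULT_MIN_MAPPING_IDENTITY,
    min_coverage: float = DEFAULT_MIN_MAPPING_COVERAGE,
) -> List[TranscriptMapping]:
    """Drop mappings below the spliced-aligner identity/coverage cutoffs."""
    return [
        m for m in mappings if m.identity >= min_identity and m.coverage >= min_coverage
    ]


def cluster_mappings(
    mappings: Sequence[TranscriptMapping],
    *,
    stranded: bool = True,
) -> List[List[TranscriptMapping]]:
    """Partition mappings into loci by transitive genomic-span overlap.

    Two mappings share a cluster iff they are connected by a chain of pairwise
    span overlaps (≥1 bp) on the same contig (and same strand unless
    ``stranded=False``).  Clusters are ordered by (contig, leftmost start,
    strand); members keep input order.  Deterministic.
    """
    groups: Dict[Tuple, List[TranscriptMapping]] = {}
    for m in mappings:
        key = (m.location.contig_id, m.location.strand if stranded else None)
        groups.setdefault(key, []).append(m)

    clusters: List[List[TranscriptMapping]] = []
    for key in groups:
        members = sorted(
            range(len(groups[key])), key=lambda i: groups[key][i].genomic_span.start
        )
        # sweep: overlap is transitive once sorted by start
        current: List[int] = []
        current_end = None
        for i in members:
            span = groups[key][i].genomic_span
            if current and span.start < current_end:
                current.append(i)
                current_end = max(current_end, span.end)
            else:
                if current:
                    clusters.append([groups[key][i] for i in sorted(current)])
                current = [i]
                current_end = span.end
        if current:
            clusters.append([groups[key][i] for i in sorted(current)])

    clusters.sort(
        key=lambda c: (
            c[0].location.contig_id,
            min(m.genomic_span.start for m in c),
            c[0].location.strand,
        )
    )
    return clusters


def extract_locus(
    genome: Mapping[str, str],
    cluster: Sequence[TranscriptMapping],
    flank: int = DEFAULT_FLANK,
    locus_id: str = "locus",
) -> Locus:
    """Extract the flank-padded, gene-oriented sequence window for a cluster.

    The origin span is the union of the cluster's transcript genomic spans
    extended by ``flank`` bp on each side and clipped to ``[0, contig length)``.
    Reverse-strand clusters yield the reverse complement of the genomic slice.
    """
    if not cluster:
        raise ValueError("cannot extract a locus from an empty cluster")
    if flank < 0:
        raise ValueError("flank must be non-negative")
    contig = cluster[0].location.contig_id
    strand = cluster[0].location.strand
    for m in cluster:
        if m.location.contig_id != contig or m.location.strand != strand:
            raise ConsistencyError(
                f"cluster mixes contigs/strands: {m.transcript_id} not on "
                f"{contig}{strand}"
            )
    if contig not in genome:
        raise MissingReferenceError(f"contig {contig!r} absent from genome")
    contig_seq = normalize_dna(str(genome[contig]), context=f"contig {contig}")

    start = min(m.genomic_span.start for m in cluster)
    end = max(m.genomic_span.end for m in cluster)
    origin = Interval(max(0, start - flank), min(len(contig_seq), end + flank))
    seq = contig_seq[origin.start : origin.end]
    if strand == REVERSE:
        seq = reverse_complement(seq)
    return Locus(
        locus_id=locus_id,
        origin=StrandedLocation(contig, origin, strand),
        sequence=seq,
    )


@dataclass(frozen=True)
class LiftedMapping:
    """A transcript mapping expressed in locus-local, gene-oriented coordinates.

    ``exon_pairs`` ascend in transcript order *and* in locus coordinate (on a
    reverse-strand locus the genomic exon order is therefore reversed relative
    to the contig).
    """

    transcript_id: str
    locus_id: str
    exon_pairs: Tuple[Tuple[Interval, Interval], ...]

    @property
    def tss(self) -> int:
        """Transcription start site in locus coordinates."""
        return self.exon_pairs[0][1].start

    @property
    def tes(self) -> int:
        """Transcription end site in locus coordinates."""
        return self.exon_pairs[-1][1].end

    @property
    def transcript_length(self) -> int:
        return self.exon_pairs[-1][0].end


def genomic_to_local(interval: Interval, locus: Locus) -> Interval:
    """Map a genomic interval into the locus-local gene-oriented frame."""
    origin = locus.origin.span
    if interval.start < origin.start or interval.end > origin.end:
        raise ConsistencyError(f"interval {interval} outside locus origin {origin}")
    if locus.origin.strand == FORWARD:
        return Interval(interval.start - origin.start, interval.end - origin.start)
    return Interval(origin.end - interval.end, origin.end - interval.start)


def local_to_genomic(interval: Interval, locus: Locus) -> Interval:
    """Inverse of :func:`genomic_to_local` (round-trip is the identity)."""
    origin = locus.origin.span
    if interval.end > len(locus):
        raise ConsistencyError(f"interval {interval} outside locus of length {len(locus)}")
    if locus.origin.strand == FORWARD:
        return Interval(interval.start + origin.start, interval.end + origin.start)
    return Interval(origin.end - interval.end, origin.end - interval.start)


def liftover(mapping: TranscriptMapping, locus: Locus) -> LiftedMapping:
    """Lift a mapping's exon chain into the locus frame.

    Exon lengths are preserved and, on reverse-strand loci, exon order is
    flipped so transcript coordinates ascend with locus coordinates.
    """
    if mapping.location.contig_id != locus.origin.contig_id:
        raise ConsistencyError(
            f"mapping {mapping.transcript_id} is on {mapping.location.contig_id}, "
            f"locus on {locus.origin.contig_id}"
        )
    pairs = [(t, genomic_to_local(g, locus)) for t, g in mapping.exon_pairs]
    pairs.sort(key=lambda p: p[0].start)
    for (_, a), (_, b) in zip(pairs, pairs[1:]):
        if b.start < a.end:
            raise ConsistencyError(
                f"lifted exons of {mapping.transcript_id} out of order in locus frame"
            )
    return LiftedMapping(mapping.transcript_id, locus.locus_id, tuple(pairs))
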