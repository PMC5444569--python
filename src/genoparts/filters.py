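"""Evidence filters and the isoform-retention rule.

BLASTp hits are kept at ≥35% identity and ≥20% coverage per subject
(alignment length on the subject over subject length); Pfam hits are kept at
bitscore ≥ the family's curated gathering threshold (GA).  Isoforms are
retained only when they carry at least one predicted CDS and at least one
retained hit from either source.  Both filters are idempotent and monotone
in their thresholds.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Sequence, Set

from .datamodel import AnnotationHit
from .errors import StructuralError

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 35.0
DEFAULT_MIN_COVERAGE_PER_SUBJECT = 20.0


def filter_blast_hits(
    hits: Sequence[AnnotationHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_cov_subject: float = DEFAULT_MIN_COVERAGE_PER_SUBJECT,
) -> List[AnnotationHit]:
    """Keep BLASTp hits with identity and subject coverage at/above the cutoffs.

    Boundaries are inclusive ("minimal identity of 35%" names the smallest
    admissible value).  Order is preserved.
    """
    for h in hits:
        if h.source != "blastp":
            raise StructuralError(f"filter_blast_hits got a {h.source} hit ({h.accession})")
    return [
        h
        for h in hits
        if h.identity >= min_identity and h.coverage_per_subject >= min_cov_subject
    ]


def filter_pfam_hits(hits: Sequence[AnnotationHit]) -> List[AnnotationHit]:
    """Keep Pfam hits whose bitscore meets the family gathering threshold.

    The GA boundary is inclusive (the Pfam convention).  Hits missing a
    gathering threshold are dropped with a logged warning, not an error.
    """
    for h in hits:
        if h.source != "pfam":
            raise StructuralError(f"filter_pfam_hits got a {h.source} hit ({h.accession})")
    kept = []
    for h in hits:
        if h.gathering_threshold is None:
            logger.warning(
                "pfam hit %s on %s has no gathering threshold; dropped",
                h.accession,
                h.cds_id,
            )
            continue
        if h.bitscore >= h.gathering_threshold:
            kept.append(h)
    return kept


def retain_isoforms(
    cds_by_isoform: Mapping[str, Sequence[str]],
    retained_hits: Iterable[AnnotationHit],
) -> List[str]:
    """Apply the isoform-retention rule.

    An isoform is kept iff it has at least one predicted CDS and at least one
    retained hit (either source) on any of its CDSs.  ``retained_hits`` must
    already be filtered.  Input order of isoforms is preserved.
    """
    annotated: Set[str] = {h.cds_id for h in retained_hits}
    kept = []
    for isoform_id, cds_ids in cds_by_isoform.items():
        if cds_ids and any(c in annotated for c in cds_ids):
            kept.append(isoform_id)
    return kept
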