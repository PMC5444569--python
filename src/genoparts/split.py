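"""ORF stand-in prediction and gene splitting into the five-part assembly.

A gene model is decomposed along the locus in strict order
promoter — 5'UTR — CDS — 3'UTR — terminator:

* promoter: locus start to the mapped transcription start site (TSS);
* 5'UTR: TSS to the start of the ORF (spliced region; may be empty);
* CDS: genomic exons covered by the ORF, including its stop codon;
* 3'UTR: ORF end to the transcript end (may be empty);
* terminator: transcription end site (TES) to the locus end.

The five genomic spans tile the locus window.  UTR and CDS parts keep exon
chains so spliced sequences can be recovered; introns falling between two
slots are attributed to the upstream-slot span so tiling is preserved.
"""

from __future__ import annotations

from typing import List, Sequence

from .datamodel import (
    ExonChain,
    Gene,
    Interval,
    Locus,
    OrfPrediction,
    Part,
)
from .errors import ConsistencyError
from .locus import LiftedMapping
from .sequence import normalize_dna, translate  # noqa: F401  (re-exported)

DEFAULT_MIN_ORF_AA = 100
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"


def predict_orfs(
    transcript: str,
    transcript_id: str = "",
    min_len_aa: int = DEFAULT_MIN_ORF_AA,
    *,
    include_partial: bool = True,
) -> List[OrfPrediction]:
    """Stand-in ORF finder on the forward strand of an oriented transcript.

    Reports, per reading frame and stop-delimited region, the maximal ORF:
    first ATG after the previous in-frame stop through the next stop (or the
    transcript end, flagged 3'-partial when ``include_partial``).  ORFs whose
    protein is strictly longer than ``min_len_aa`` amino acids are kept,
    sorted by decreasing protein length, then ascending start.  No coding-
    potential model is applied; external ORF tables may be used instead.
    """
    seq = normalize_dna(transcript, context=f"transcript {transcript_id or '?'}")
    found: List[OrfPrediction] = []
    n = len(seq)
    for frame in range(3):
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    protein_len = (pos - start) // 3
                    if protein_len > min_len_aa:
                        found.append(
                            OrfPrediction(
                                transcript_id,
                                Interval(start, pos + 3),
                                translate(seq[start : pos + 3]),
                                partial=False,
                            )
                        )
                    start = None
            elif codon == START_CODON and start is None:
                start = pos
        if start is not None and include_partial:
            end = start + 3 * ((n - start) // 3)
            protein_len = (end - start) // 3
            if protein_len > min_len_aa:
                found.append(
                    OrfPrediction(
                        transcript_id,
                        Interval(start, end),
                        translate(seq[start:end]),
                        partial=True,
                    )
                )
    found.sort(key=lambda o: (-len(o.protein), o.orf_span.start))
    return found


def map_transcript_interval(
    lifted: LiftedMapping, interval: Interval
) -> List[Interval]:
    """Project a transcript interval through the exon chain into locus frame.

    Exons are split exactly at the interval boundaries; the result is the
    ordered list of locus-local genomic intervals covering the transcript
    region (empty for a zero-length interval).
    """
    if interval.start < 0 or interval.end > lifted.transcript_length:
        raise ConsistencyError(
            f"transcript interval {interval} outside transcript "
            f"{lifted.transcript_id} of length {lifted.transcript_length}"
        )
    out: List[Interval] = []
    for t, g in lifted.exon_pairs:
        lo = max(interval.start, t.start)
        hi = min(interval.end, t.end)
        if lo < hi:
            out.append(Interval(g.start + (lo - t.start), g.start + (hi - t.start)))
    return out


def split_gene(
    locus: Locus,
    lifted: LiftedMapping,
    orf: OrfPrediction,
    gene_id: str,
    *,
    is_primary: bool = True,
    cds_part_id: str = None,
) -> Gene:
    """Split the locus window into the five-part assembly for one ORF."""
    if orf.orf_span.end > lifted.transcript_length:
        raise ConsistencyError(
            f"ORF {orf.orf_span} outside transcript {lifted.transcript_id} "
            f"of length {lifted.transcript_length}"
        )
    tss, tes = lifted.tss, lifted.tes
    tlen = lifted.transcript_length
    length = len(locus)

    utr5_exons = map_transcript_interval(lifted, Interval(0, orf.orf_span.start))
    cds_exons = map_transcript_interval(lifted, orf.orf_span)
    utr3_exons = map_transcript_interval(lifted, Interval(orf.orf_span.end, tlen))
    if not cds_exons:
        raise ConsistencyError(f"ORF {orf.orf_span} maps to no exons")

    cds_start = cds_exons[0].start
    cds_end = cds_exons[-1].end
    spans = {
        "promoter": Interval(0, tss),
        "utr5": Interval(tss, cds_start),
        "cds": Interval(cds_start, cds_end),
        "utr3": Interval(cds_end, tes),
        "terminator": Interval(tes, length),
    }
    chains = {
        "promoter": ExonChain([spans["promoter"]] if len(spans["promoter"]) else []),
        "utr5": ExonChain(utr5_exons),
        "cds": ExonChain(cds_exons),
        "utr3": ExonChain(utr3_exons),
        "terminator": ExonChain(
            [spans["terminator"]] if len(spans["terminator"]) else []
        ),
    }
    part_ids = {pt: f"{gene_id}.{pt}" for pt in spans}
    if cds_part_id is not None:
        part_ids["cds"] = cds_part_id
    parts = {
        pt: Part(
            part_id=part_ids[pt],
            part_type=pt,
            genomic_span=spans[pt],
            exons=chains[pt],
            sequence=locus.slice(spans[pt]),
        )
        for pt in spans
    }
    return Gene(
        gene_id=gene_id,
        locus_id=locus.locus_id,
        transcript_id=lifted.transcript_id,
        parts=parts,
        is_primary=is_primary,
    )


def spliced_sequence(part: Part, locus: Locus) -> str:
    """Concatenate the locus subsequences at the part's exon intervals."""
    chunks = []
    for exon in part.exons:
        if exon.end > len(locus):
            raise ConsistencyError(
                f"exon {exon} of part {part.part_id} outside locus {locus.locus_id}"
            )
        chunks.append(locus.slice(exon))
    return "".join(chunks)
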