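"""Readers and writers for the external file dialects.

FASTA and GenBank go through Biopython; GFF3 exon input through gffutils;
the simple tabular dialects (mapping TSV, ORF table, BLAST 12+2 columns,
Pfam TSV) through pandas.  All coordinates in the TSV dialects are 0-based
half-open; GFF3 is 1-based inclusive at the boundary as usual.
"""

from __future__ import annotations

import os
from typing import Dict, List, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    AnnotationHit,
    Interval,
    OrfPrediction,
    StrandedLocation,
    TranscriptMapping,
)
from .sequence import normalize_dna

MAPPING_TSV_COLUMNS = [
    "transcript_id", "contig", "strand",
    "transcript_start", "transcript_end", "genomic_start", "genomic_end",
]
ORF_TSV_COLUMNS = ["transcript_id", "orf_start", "orf_end", "protein"]
BLAST_TAB_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "slen", "stitle",
]
PFAM_TSV_COLUMNS = [
    "cds_id", "pfam_accession", "description", "start", "end",
    "bitscore", "e_value", "gathering_threshold",
]


def read_fasta(path: str) -> Dict[str, str]:
    return {
        rec.id: normalize_dna(str(rec.seq), context=rec.id)
        for rec in SeqIO.parse(path, "fasta")
    }


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, path, "fasta")


def _mapping_from_exon_rows(rows: pd.DataFrame) -> TranscriptMapping:
    rows = rows.sort_values("transcript_start")
    first = rows.iloc[0]
    gstart = int(rows["genomic_start"].min())
    gend = int(rows["genomic_end"].max())
    return TranscriptMapping(
        transcript_id=str(first["transcript_id"]),
        location=StrandedLocation(
            str(first["contig"]), Interval(gstart, gend), str(first["strand"])
        ),
        exon_pairs=[
            (
                Interval(int(r.transcript_start), int(r.transcript_end)),
                Interval(int(r.genomic_start), int(r.genomic_end)),
            )
            for r in rows.itertuples()
        ],
        identity=float(first.get("identity", 100.0)),
        coverage=float(first.get("coverage", 100.0)),
    )


def read_mappings_tsv(path: str) -> List[TranscriptMapping]:
    """Read the simple exon-level mapping dialect (0-based half-open).

    Required columns: transcript_id, contig, strand, transcript_start,
    transcript_end, genomic_start, genomic_end; optional identity, coverage.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(MAPPING_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"mapping TSV missing columns: {sorted(missing)}")
    return [
        _mapping_from_exon_rows(group)
        for _, group in df.groupby("transcript_id", sort=True)
    ]


def write_mappings_tsv(mappings: Sequence[TranscriptMapping], path: str) -> None:
    rows = []
    for m in mappings:
        for t, g in m.exon_pairs:
            rows.append(
                {
                    "transcript_id": m.transcript_id,
                    "contig": m.location.contig_id,
                    "strand": m.location.strand,
                    "transcript_start": t.start,
                    "transcript_end": t.end,
                    "genomic_start": g.start,
                    "genomic_end": g.end,
                    "identity": m.identity,
                    "coverage": m.coverage,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mappings_gff3(path: str) -> List[TranscriptMapping]:
    """Read exon features (Parent = transcript ID) from a GFF3 file.

    Transcript-side coordinates are reconstructed by accumulating exon
    lengths in transcript order (reverse-genomic order on the minus strand).
    """
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    by_parent: Dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [exon.id])
        for parent in parents:
            by_parent.setdefault(parent, []).append(exon)
    mappings = []
    for transcript_id in sorted(by_parent):
        exons = by_parent[transcript_id]
        strand = exons[0].strand
        contig = exons[0].seqid
        exons.sort(key=lambda e: e.start, reverse=(strand == "-"))
        pairs = []
        pos = 0
        for e in exons:
            g = Interval(e.start - 1, e.end)  # GFF3 is 1-based inclusive
            pairs.append((Interval(pos, pos + len(g)), g))
            pos += len(g)
        gs = [g for _, g in pairs]
        mappings.append(
            TranscriptMapping(
                transcript_id=transcript_id,
                location=StrandedLocation(
                    contig,
                    Interval(min(g.start for g in gs), max(g.end for g in gs)),
                    strand,
                ),
                exon_pairs=pairs,
            )
        )
    return mappings


def write_mappings_gff3(mappings: Sequence[TranscriptMapping], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in mappings:
            loc = m.location
            fh.write(
                "\t".join(
                    [
                        loc.contig_id, "genoparts", "mRNA",
                        str(loc.span.start + 1), str(loc.span.end), ".",
                        loc.strand, ".", f"ID={m.transcript_id}",
                    ]
                )
                + "\n"
            )
            for i, (_, g) in enumerate(m.exon_pairs, 1):
                fh.write(
                    "\t".join(
                        [
                            loc.contig_id, "genoparts", "exon",
                            str(g.start + 1), str(g.end), ".", loc.strand, ".",
                            f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}",
                        ]
                    )
                    + "\n"
                )


def read_orf_table(path: str) -> List[OrfPrediction]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ORF_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ORF table missing columns: {sorted(missing)}")
    orfs = []
    for r in df.itertuples():
        span = Interval(int(r.orf_start), int(r.orf_end))
        partial = bool(getattr(r, "partial", False))
        orfs.append(
            OrfPrediction(str(r.transcript_id), span, str(r.protein), partial=partial)
        )
    return orfs


def write_orf_table(orfs: Sequence[OrfPrediction], path: str) -> None:
    pd.DataFrame(
        [
            {
                "transcript_id": o.transcript_id,
                "orf_start": o.orf_span.start,
                "orf_end": o.orf_span.end,
                "protein": o.protein,
                "partial": o.partial,
            }
            for o in orfs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_blast_tab(path: str) -> List[AnnotationHit]:
    """Read protein BLAST hits in the 12-column tabular dialect + slen, stitle.

    qseqid is the CDS identifier; coverage per subject is computed as
    subject-side alignment length over subject length × 100.  Alignment
    coordinates in the table are 1-based inclusive (BLAST convention).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_TAB_COLUMNS)
    hits = []
    for r in df.itertuples():
        sstart, send = sorted((int(r.sstart), int(r.send)))
        coverage = (send - sstart + 1) / int(r.slen) * 100.0
        title_words = tuple(str(r.stitle).split("|"))
        hits.append(
            AnnotationHit(
                cds_id=str(r.qseqid),
                source="blastp",
                accession=str(r.sseqid),
                keywords=title_words,
                e_value=float(r.evalue),
                bitscore=float(r.bitscore),
                hit_span=Interval(int(r.qstart) - 1, int(r.qend)),
                identity=float(r.pident),
                coverage_per_subject=coverage,
            )
        )
    return hits


def read_pfam_tsv(path: str) -> List[AnnotationHit]:
    """Read Pfam hits: cds_id, accession, description, start, end (0-based
    half-open on the protein), bitscore, e_value, gathering_threshold."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PFAM_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Pfam TSV missing columns: {sorted(missing)}")
    hits = []
    for r in df.itertuples():
        ga = r.gathering_threshold
        hits.append(
            AnnotationHit(
                cds_id=str(r.cds_id),
                source="pfam",
                accession=str(r.pfam_accession),
                keywords=tuple(str(r.description).split("|")),
                e_value=float(r.e_value),
                bitscore=float(r.bitscore),
                hit_span=Interval(int(r.start), int(r.end)),
                gathering_threshold=None if pd.isna(ga) else float(ga),
            )
        )
    return hits
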