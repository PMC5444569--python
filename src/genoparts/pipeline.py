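"""End-to-end compilation: evidence files in, gene-part loci out.

Order of operations mirrors the upstream framework: drop low-quality
transcript mappings (spliced-aligner 99/99 cutoffs), predict or ingest ORFs,
filter BLASTp/Pfam evidence, apply the isoform-retention rule, cluster the
surviving mappings into loci, extract flank-padded windows and split each
isoform/ORF into its five-part gene model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .datamodel import (
    AnnotationHit,
    Gene,
    Locus,
    OrfPrediction,
    TranscriptMapping,
    validate_gene,
)
from .errors import MissingReferenceError
from .filters import filter_blast_hits, filter_pfam_hits, retain_isoforms
from .locus import cluster_mappings, extract_locus, filter_mappings, liftover
from .registry import Registry, build_registry
from .split import predict_orfs, split_gene


@dataclass
class PipelineConfig:
    flank: int = 3000
    min_mapping_identity: float = 99.0
    min_mapping_coverage: float = 99.0
    min_orf_len_aa: int = 100
    include_partial_orfs: bool = True
    min_blast_identity: float = 35.0
    min_blast_coverage_per_subject: float = 20.0
    stranded_clustering: bool = True


@dataclass
class CompileResult:
    loci: List[Locus]
    retained_hits: List[AnnotationHit]
    retained_isoforms: List[str]
    dropped_isoforms: List[str]
    #: gene_id -> list of structural violations (empty lists omitted)
    violations: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def genes(self) -> List[Gene]:
        return [g for locus in self.loci for g in locus.genes]


def cds_identifier(transcript_id: str, rank: int) -> str:
    """CDS/gene identifier for the rank-th ORF (1-based, longest first)."""
    return f"{transcript_id}.orf{rank}"


def compile_dataset(
    genome: Mapping[str, str],
    transcripts: Mapping[str, str],
    mappings: Sequence[TranscriptMapping],
    orfs: Optional[Sequence[OrfPrediction]] = None,
    blast_hits: Sequence[AnnotationHit] = (),
    pfam_hits: Sequence[AnnotationHit] = (),
    config: Optional[PipelineConfig] = None,
) -> CompileResult:
    cfg = config or PipelineConfig()

    kept_mappings = filter_mappings(
        mappings, cfg.min_mapping_identity, cfg.min_mapping_coverage
    )

    orfs_by_tid: Dict[str, List[OrfPrediction]] = {}
    if orfs is None:
        for m in kept_mappings:
            tid = m.transcript_id
            if tid not in transcripts:
                raise MissingReferenceError(f"transcript {tid!r} absent from FASTA")
            orfs_by_tid[tid] = predict_orfs(
                transcripts[tid], tid, cfg.min_orf_len_aa,
                include_partial=cfg.include_partial_orfs,
            )
    else:
        for o in orfs:
            orfs_by_tid.setdefault(o.transcript_id, []).append(o)
        for tid in orfs_by_tid:
            orfs_by_tid[tid].sort(key=lambda o: (-len(o.protein), o.orf_span.start))

    retained = [
        *filter_blast_hits(
            blast_hits, cfg.min_blast_identity, cfg.min_blast_coverage_per_subject
        ),
        *filter_pfam_hits(pfam_hits),
    ]

    cds_by_isoform = {
        m.transcript_id: [
            cds_identifier(m.transcript_id, k)
            for k in range(1, len(orfs_by_tid.get(m.transcript_id, [])) + 1)
        ]
        for m in kept_mappings
    }
    kept_ids = set(retain_isoforms(cds_by_isoform, retained))
    dropped = [tid for tid in cds_by_isoform if tid not in kept_ids]

    final_mappings = [m for m in kept_mappings if m.transcript_id in kept_ids]
    clusters = cluster_mappings(final_mappings, stranded=cfg.stranded_clustering)

    loci: List[Locus] = []
    violations: Dict[str, List[str]] = {}
    for idx, cluster in enumerate(clusters, 1):
        locus = extract_locus(genome, cluster, cfg.flank, locus_id=f"locus{idx:05d}")
        for m in cluster:
            lifted = liftover(m, locus)
            for k, orf in enumerate(orfs_by_tid[m.transcript_id], 1):
                gene_id = cds_identifier(m.transcript_id, k)
                gene = split_gene(
                    locus, lifted, orf, gene_id,
                    is_primary=(k == 1), cds_part_id=gene_id,
                )
                bad = validate_gene(gene, locus)
                if bad:
                    violations[gene_id] = bad
                locus.genes.append(gene)
        loci.append(locus)

    built_cds = {g.cds_id for locus in loci for g in locus.genes}
    final_hits = [h for h in retained if h.cds_id in built_cds]
    return CompileResult(
        loci=loci,
        retained_hits=final_hits,
        retained_isoforms=sorted(kept_ids),
        dropped_isoforms=sorted(dropped),
        violations=violations,
    )


def compile_to_registry(
    result: CompileResult, path: str = ":memory:"
) -> Registry:
    return build_registry(result.loci, result.retained_hits, path)
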