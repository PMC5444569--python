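"""Deterministic synthetic-data generator with full ground truth.

Emulates the upstream evidence the pipeline consumes — genome contigs,
oriented transcript sequences, exon-level transcript→genome mappings, ORF
predictions, and BLASTp/Pfam hit tables — for multi-exon genes on both
strands, multi-isoform loci and genes near contig edges.  Every bundle
carries a truth table (JSON-serializable) so each pipeline stage can be
checked against known part boundaries, spliced sequences and proteins.

Restriction-site footprints and threshold-straddling hit scores are injected
explicitly rather than awaited by chance, so recode and filter code paths
are covered deterministically.  Transcripts are constructed to contain
exactly one qualifying ORF (the truth CDS); candidate draws producing
spurious long ORFs in other frames are redrawn, keeping the truth tables
exact while remaining byte-deterministic for a given seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as gio
from .datamodel import (
    AnnotationHit,
    Interval,
    OrfPrediction,
    StrandedLocation,
    TranscriptMapping,
)
from .errors import GenerationError
from .sequence import reverse_complement, translate
from .split import predict_orfs

DEFAULT_FLANK = 3000

_BASES = "ACGT"
_STOPS = ("TAA", "TAG", "TGA")
_SENSE = tuple(
    sorted(
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS
    )
)


@dataclass
class GeneratorSpec:
    """Tunable parameters of the stated synthetic world.

    Defaults emulate compact plant-like gene models: up to two isoforms per
    locus, 1–4 exons, short introns, UTRs under 300 bp, CDSs comfortably
    above the >100 aa retention rule, and 3 kb of genuine flank on either
    side of most genes so the default promoter/terminator windows are full
    length.
    """

    n_loci: int = 6
    loci_per_contig: int = 2
    second_isoform_fraction: float = 0.5
    exon_range: Tuple[int, int] = (1, 4)
    intron_range: Tuple[int, int] = (80, 400)
    utr5_range: Tuple[int, int] = (40, 280)
    utr3_range: Tuple[int, int] = (40, 280)
    cds_aa_range: Tuple[int, int] = (120, 320)
    edge_pad_range: Tuple[int, int] = (3200, 4000)
    gap_range: Tuple[int, int] = (1500, 2500)
    reverse_fraction: float = 0.5
    gc: float = 0.5
    flank: int = DEFAULT_FLANK

    def validate(self) -> None:
        if self.n_loci < 1 or self.loci_per_contig < 1:
            raise GenerationError("need at least one locus and one locus per contig")
        if self.exon_range[0] < 1:
            raise GenerationError("genes need at least one exon")
        if self.cds_aa_range[0] <= 100:
            raise GenerationError(
                "cds_aa_range must exceed the 100 aa retention threshold"
            )
        if self.utr3_range[1] > 300:
            raise GenerationError(
                "3'UTRs above 300 bp could harbour spurious >100 aa ORFs"
            )


@dataclass
class _GeneSpec:
    """Internal per-gene plan (one locus = one gene + optional isoform)."""

    strand: str = "+"
    n_exons: int = 1
    utr5_len: int = 120
    utr3_len: int = 120
    n_aa: int = 150
    second_isoform: bool = False
    inject_sites: bool = False
    no_hits: bool = False
    left_pad: Optional[int] = None  # override contig-edge pad (truncated promoter)


@dataclass
class Bundle:
    """A generated dataset plus its ground truth."""

    genome: Dict[str, str]
    transcripts: Dict[str, str]
    mappings: List[TranscriptMapping]
    orfs: List[OrfPrediction]
    blast_hits: List[AnnotationHit]
    pfam_hits: List[AnnotationHit]
    truth: Dict

    def write(self, outdir: str) -> None:
        """Emit exactly the dialects the pipeline consumes, plus truth.json."""
        os.makedirs(outdir, exist_ok=True)
        gio.write_fasta(self.genome, os.path.join(outdir, "genome.fasta"))
        gio.write_fasta(self.transcripts, os.path.join(outdir, "transcripts.fasta"))
        gio.write_mappings_tsv(self.mappings, os.path.join(outdir, "mappings.tsv"))
        gio.write_mappings_gff3(self.mappings, os.path.join(outdir, "mappings.gff3"))
        gio.write_orf_table(self.orfs, os.path.join(outdir, "orfs.tsv"))
        self._write_blast_tab(os.path.join(outdir, "blast.tsv"))
        self._write_pfam_tsv(os.path.join(outdir, "pfam.tsv"))
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)

    def _write_blast_tab(self, path: str) -> None:
        lines = []
        for h in self.blast_hits:
            slen = 1000
            send = round(h.coverage_per_subject * 10)  # (send-1+1)/1000*100 = cov
            lines.append(
                "\t".join(
                    str(x)
                    for x in [
                        h.cds_id, h.accession, h.identity,
                        send, 0, 0,
                        h.hit_span.start + 1, h.hit_span.end,
                        1, send, h.e_value, h.bitscore, slen,
                        "|".join(h.keywords),
                    ]
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))

    def _write_pfam_tsv(self, path: str) -> None:
        rows = ["\t".join(gio.PFAM_TSV_COLUMNS)]
        for h in self.pfam_hits:
            rows.append(
                "\t".join(
                    str(x)
                    for x in [
                        h.cds_id, h.accession, "|".join(h.keywords),
                        h.hit_span.start, h.hit_span.end,
                        h.bitscore, h.e_value,
                        "" if h.gathering_threshold is None else h.gathering_threshold,
                    ]
                )
            )
        with open(path, "w") as fh:
            fh.write("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(_BASES[i] for i in idx)


def _atg_free(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random DNA with every ATG broken (so UTRs never seed spurious ORFs)."""
    s = _random_dna(rng, n, gc)
    i = s.find("ATG")
    while i != -1:
        s = s[: i + 2] + "C" + s[i + 3 :]
        i = s.find("ATG")
    return s


def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(_SENSE[i] for i in rng.integers(0, len(_SENSE), size=n_aa - 1))
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _inject_footprints(cds: str) -> str:
    """Plant a forward BsaI and a reverse-strand SapI footprint, codon-aligned.

    GGT+CTC spells GGTCTC (BsaI); GAA+GAG+CAA contains GAAGAGC, the reverse
    complement of the SapI recognition site GCTCTTC.  All injected codons are
    sense codons, so the protein stays stop-free.
    """
    n_codons = len(cds) // 3
    if n_codons < 16:
        raise GenerationError("CDS too short for site injection")
    k1, k2 = 3, n_codons // 2
    codons = [cds[3 * i : 3 * i + 3] for i in range(n_codons)]
    codons[k1 : k1 + 2] = ["GGT", "CTC"]
    codons[k2 : k2 + 3] = ["GAA", "GAG", "CAA"]
    return "".join(codons)


def _cut_exons(
    rng: np.random.Generator, length: int, n_exons: int, min_exon: int = 25
) -> List[int]:
    """Sorted internal cut points splitting [0, length) into n_exons pieces."""
    if n_exons == 1:
        return []
    for _ in range(100):
        cuts = sorted(rng.integers(min_exon, length - min_exon, size=n_exons - 1))
        ok = all(b - a >= min_exon for a, b in zip(cuts, cuts[1:]))
        if ok:
            return [int(c) for c in cuts]
    raise GenerationError(f"cannot split {length} bp into {n_exons} exons")


def _carve_pairs(
    pairs: Sequence[Tuple[Interval, Interval]], lo: int, hi: int
) -> List[Tuple[Interval, Interval]]:
    """Restrict exon pairs to transcript window [lo, hi), rebased to 0."""
    out = []
    for t, r in pairs:
        a, b = max(lo, t.start), min(hi, t.end)
        if a < b:
            out.append(
                (
                    Interval(a - lo, b - lo),
                    Interval(r.start + (a - t.start), r.start + (b - t.start)),
                )
            )
    return out


# ---------------------------------------------------------------------------
# generator core


def _build_gene(
    rng: np.random.Generator, spec: GeneratorSpec, gspec: _GeneSpec
) -> Dict:
    """Draw one gene template in gene-oriented region coordinates.

    Redraws (bounded) until the spliced transcript contains exactly one
    qualifying ORF, which must be the truth CDS.
    """
    for _ in range(60):
        utr5 = _atg_free(rng, gspec.utr5_len, spec.gc)
        cds = _random_cds(rng, gspec.n_aa)
        if gspec.inject_sites:
            cds = _inject_footprints(cds)
        utr3 = _atg_free(rng, gspec.utr3_len, spec.gc)
        transcript = utr5 + cds + utr3
        orf_span = Interval(len(utr5), len(utr5) + len(cds))
        orfs = predict_orfs(transcript, "candidate")
        if len(orfs) == 1 and orfs[0].orf_span == orf_span:
            break
    else:
        raise GenerationError("could not draw a single-ORF transcript in 60 attempts")

    cuts = _cut_exons(rng, len(transcript), gspec.n_exons)
    bounds = [0, *cuts, len(transcript)]
    introns = [
        _random_dna(rng, int(rng.integers(*spec.intron_range)), spec.gc)
        for _ in range(gspec.n_exons - 1)
    ]
    pairs: List[Tuple[Interval, Interval]] = []
    region_chunks: List[str] = []
    rpos = 0
    for i in range(gspec.n_exons):
        t = Interval(bounds[i], bounds[i + 1])
        region_chunks.append(transcript[t.start : t.end])
        pairs.append((t, Interval(rpos, rpos + len(t))))
        rpos += len(t)
        if i < gspec.n_exons - 1:
            region_chunks.append(introns[i])
            rpos += len(introns[i])
    return {
        "transcript": transcript,
        "region": "".join(region_chunks),
        "pairs": pairs,
        "orf_span": orf_span,
        "protein": translate(cds),
        "cds": cds,
        "utr5": utr5,
        "utr3": utr3,
    }


def _second_isoform_window(
    rng: np.random.Generator, gspec: _GeneSpec, orf_span: Interval, tlen: int
) -> Tuple[int, int]:
    d5 = int(rng.integers(10, max(11, gspec.utr5_len - 5))) if gspec.utr5_len >= 20 else 0
    d3 = int(rng.integers(10, max(11, gspec.utr3_len - 5))) if gspec.utr3_len >= 20 else 0
    return d5, tlen - d3


def _hit_grid(cds_id: str, idx: int, protein_len: int, passing_only: bool = False):
    """Threshold-straddling BLASTp/Pfam hits for one CDS.

    BLAST: clear pass, boundary pass (35.0 / 20.0), identity fail (34.9),
    coverage fail (19.9).  Pfam (GA 25.0): clear pass, boundary pass
    (bitscore == GA), fail (24.9).
    """
    span = Interval(0, min(60, protein_len))
    kw_b = (f"GENE{idx}", f"putative protein {idx}", "Synthetica viridis")
    kw_p = (f"Domain family {idx}",)
    grid_b = [
        (80.0, 50.0, 10 ** -(40 + idx % 10), 180.0, True),
        (35.0, 20.0, 1e-20, 90.0, True),
        (34.9, 50.0, 1e-18, 80.0, False),
        (80.0, 19.9, 1e-22, 85.0, False),
    ]
    ga = 25.0
    grid_p = [(ga + 10.0, 1e-30, True), (ga, 1e-10, True), (ga - 0.1, 1.0, False)]
    if passing_only:
        grid_b = grid_b[:1]
        grid_p = grid_p[:1]
    blast = [
        (
            AnnotationHit(
                cds_id=cds_id, source="blastp", accession=f"SP{idx:04d}.{j}",
                keywords=kw_b, e_value=ev, bitscore=bs, hit_span=span,
                identity=ident, coverage_per_subject=cov,
            ),
            ok,
        )
        for j, (ident, cov, ev, bs, ok) in enumerate(grid_b, 1)
    ]
    pfam = [
        (
            AnnotationHit(
                cds_id=cds_id, source="pfam", accession=f"PF{idx:05d}.{j}",
                keywords=kw_p, e_value=ev, bitscore=bs, hit_span=span,
                gathering_threshold=ga,
            ),
            ok,
        )
        for j, (bs, ev, ok) in enumerate(grid_p, 1)
    ]
    return blast, pfam


def _fail_only_hits(cds_id: str, idx: int, protein_len: int):
    """Hits that all fail their filters (isoform-retention negative control)."""
    span = Interval(0, min(60, protein_len))
    blast = [
        (
            AnnotationHit(
                cds_id=cds_id, source="blastp", accession=f"SP{idx:04d}.X",
                keywords=(f"GENE{idx}",), e_value=1e-5, bitscore=40.0,
                hit_span=span, identity=30.0, coverage_per_subject=10.0,
            ),
            False,
        )
    ]
    pfam = [
        (
            AnnotationHit(
                cds_id=cds_id, source="pfam", accession=f"PF{idx:05d}.X",
                keywords=("Unconvincing domain",), e_value=5.0, bitscore=20.0,
                hit_span=span, gathering_threshold=25.0,
            ),
            False,
        )
    ]
    return blast, pfam


def _generate(
    rng: np.random.Generator, spec: GeneratorSpec, gene_specs: List[_GeneSpec]
) -> Bundle:
    spec.validate()
    genome: Dict[str, str] = {}
    transcripts: Dict[str, str] = {}
    mappings: List[TranscriptMapping] = []
    orfs: List[OrfPrediction] = []
    blast_hits: List[AnnotationHit] = []
    pfam_hits: List[AnnotationHit] = []
    truth_loci: List[Dict] = []
    truth_genes: List[Dict] = []
    truth_hits = {"blastp": [], "pfam": []}

    n_contigs = (len(gene_specs) + spec.loci_per_contig - 1) // spec.loci_per_contig
    locus_idx = 0
    for ci in range(n_contigs):
        contig_name = f"contig{ci + 1:02d}"
        chunk: List[str] = []
        cursor = 0
        first = gene_specs[locus_idx] if locus_idx < len(gene_specs) else None
        lead = (
            first.left_pad
            if first is not None and first.left_pad is not None
            else int(rng.integers(*spec.edge_pad_range))
        )
        chunk.append(_random_dna(rng, lead, spec.gc))
        cursor += lead
        contig_loci: List[Dict] = []
        for _ in range(spec.loci_per_contig):
            if locus_idx >= len(gene_specs):
                break
            gspec = gene_specs[locus_idx]
            tpl = _build_gene(rng, spec, gspec)
            place = cursor
            region = tpl["region"]
            embed = region if gspec.strand == "+" else reverse_complement(region)
            chunk.append(embed)
            cursor += len(region)
            gap = int(rng.integers(*spec.gap_range))
            chunk.append(_random_dna(rng, gap, spec.gc))
            cursor += gap
            contig_loci.append(
                {
                    "gspec": gspec, "tpl": tpl, "place": place,
                    "region_len": len(region), "locus_idx": locus_idx,
                }
            )
            locus_idx += 1
        tail = int(rng.integers(*spec.edge_pad_range))
        chunk.append(_random_dna(rng, tail, spec.gc))
        contig_seq = "".join(chunk)
        genome[contig_name] = contig_seq

        for entry in contig_loci:
            gspec, tpl = entry["gspec"], entry["tpl"]
            place, rlen = entry["place"], entry["region_len"]
            li = entry["locus_idx"]
            strand = gspec.strand

            def to_genomic(r: Interval) -> Interval:
                if strand == "+":
                    return Interval(place + r.start, place + r.end)
                return Interval(place + rlen - r.end, place + rlen - r.start)

            iso_windows = [(0, len(tpl["transcript"]))]
            if gspec.second_isoform:
                iso_windows.append(
                    _second_isoform_window(
                        rng, gspec, tpl["orf_span"], len(tpl["transcript"])
                    )
                )
            tids = []
            span_lo = min(to_genomic(r).start for _, r in tpl["pairs"])
            span_hi = max(to_genomic(r).end for _, r in tpl["pairs"])
            origin = Interval(
                max(0, span_lo - spec.flank), min(len(contig_seq), span_hi + spec.flank)
            )
            for iso_no, (lo, hi) in enumerate(iso_windows, 1):
                tid = f"t{li + 1:04d}i{iso_no}"
                tids.append(tid)
                pairs = _carve_pairs(tpl["pairs"], lo, hi)
                tseq = tpl["transcript"][lo:hi]
                gpairs = [(t, to_genomic(r)) for t, r in pairs]
                gs = [g for _, g in gpairs]
                mapping = TranscriptMapping(
                    transcript_id=tid,
                    location=StrandedLocation(
                        contig_name,
                        Interval(min(g.start for g in gs), max(g.end for g in gs)),
                        strand,
                    ),
                    exon_pairs=gpairs,
                )
                transcripts[tid] = tseq
                mappings.append(mapping)
                orf_span = Interval(tpl["orf_span"].start - lo, tpl["orf_span"].end - lo)
                orfs.append(OrfPrediction(tid, orf_span, tpl["protein"]))
                cds_id = f"{tid}.orf1"

                if strand == "+":
                    tss_local = mapping.genomic_span.start - origin.start
                    tes_local = mapping.genomic_span.end - origin.start
                else:
                    tss_local = origin.end - mapping.genomic_span.end
                    tes_local = origin.end - mapping.genomic_span.start
                cds_t = Interval(orf_span.start, orf_span.end)
                n_cds_exons = sum(
                    1 for t, _ in pairs if t.start < cds_t.end and cds_t.start < t.end
                )
                retained = not gspec.no_hits
                truth_genes.append(
                    {
                        "transcript_id": tid,
                        "cds_id": cds_id,
                        "contig": contig_name,
                        "strand": strand,
                        "protein": tpl["protein"],
                        "spliced_cds": tpl["cds"],
                        "spliced_transcript": tseq,
                        "orf_span": [orf_span.start, orf_span.end],
                        "utr5_spliced_length": orf_span.start,
                        "utr3_spliced_length": len(tseq) - orf_span.end,
                        "promoter_length": tss_local,
                        "terminator_length": len(origin) - tes_local,
                        "tss_local": tss_local,
                        "tes_local": tes_local,
                        "locus_length": len(origin),
                        "n_cds_exons": n_cds_exons,
                        "has_sites": bool(gspec.inject_sites),
                        "retained": retained,
                    }
                )
                idx = li * 10 + iso_no
                if gspec.no_hits:
                    bl, pf = _fail_only_hits(cds_id, idx, len(tpl["protein"]))
                else:
                    bl, pf = _hit_grid(cds_id, idx, len(tpl["protein"]))
                for h, ok in bl:
                    blast_hits.append(h)
                    truth_hits["blastp"].append(
                        {"cds_id": cds_id, "accession": h.accession, "passes": ok}
                    )
                for h, ok in pf:
                    pfam_hits.append(h)
                    truth_hits["pfam"].append(
                        {"cds_id": cds_id, "accession": h.accession, "passes": ok}
                    )
            truth_loci.append(
                {
                    "contig": contig_name,
                    "strand": strand,
                    "span": [span_lo, span_hi],
                    "origin": [origin.start, origin.end],
                    "transcripts": tids,
                    "retained": not gspec.no_hits,
                }
            )

    truth = {
        "flank": spec.flank,
        "contigs": {k: len(v) for k, v in genome.items()},
        "loci": truth_loci,
        "genes": truth_genes,
        "hits": truth_hits,
    }
    return Bundle(genome, transcripts, mappings, orfs, blast_hits, pfam_hits, truth)


def make_dataset(
    seed: int, spec: Optional[GeneratorSpec] = None
) -> Bundle:
    """Generate a randomized dataset bundle (same seed + spec → same bundle)."""
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(seed)
    gene_specs = []
    for i in range(spec.n_loci):
        gene_specs.append(
            _GeneSpec(
                strand="-" if rng.random() < spec.reverse_fraction else "+",
                n_exons=int(rng.integers(spec.exon_range[0], spec.exon_range[1] + 1)),
                utr5_len=int(rng.integers(*spec.utr5_range)),
                utr3_len=int(rng.integers(*spec.utr3_range)),
                n_aa=int(rng.integers(*spec.cds_aa_range)),
                second_isoform=bool(rng.random() < spec.second_isoform_fraction),
            )
        )
    return _generate(rng, spec, gene_specs)


def make_edge_cases(seed: int, spec: Optional[GeneratorSpec] = None) -> Bundle:
    """Generate the fixed edge-case bundle.

    Contains: a gene within 3 kb of its contig start (truncated promoter), a
    reverse-strand multi-exon gene, a two-isoform locus, a transcript whose
    ORF starts at position 0 (empty 5'UTR), a CDS carrying forward BsaI and
    reverse SapI footprints, an unannotated isoform (all hits fail, so it is
    dropped by the retention rule), and a plain forward single-exon baseline.
    """
    spec = spec or GeneratorSpec(loci_per_contig=2)
    rng = np.random.default_rng(seed)
    # specs with a left_pad override must come first on their contig
    gene_specs = [
        _GeneSpec(strand="+", n_exons=2, left_pad=1000),  # truncated promoter
        _GeneSpec(strand="+", n_exons=1),  # baseline
        _GeneSpec(strand="-", n_exons=3),  # reverse multi-exon
        _GeneSpec(strand="+", n_exons=2, second_isoform=True),  # one locus, 2 isoforms
        _GeneSpec(strand="+", n_exons=1, utr5_len=0),  # ORF at transcript position 0
        _GeneSpec(strand="-", n_exons=2, inject_sites=True, n_aa=160),  # BsaI+SapI CDS
        _GeneSpec(strand="+", n_exons=1, no_hits=True),  # dropped by retention
    ]
    bundle = _generate(rng, spec, gene_specs)
    bundle.truth["edge_cases"] = {
        "truncated_promoter": "t0001i1",
        "baseline": "t0002i1",
        "reverse_multiexon": "t0003i1",
        "multi_isoform_locus": ["t0004i1", "t0004i2"],
        "orf_at_start": "t0005i1",
        "sites_cds": "t0006i1",
        "dropped_isoform": "t0007i1",
    }
    return bundle
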