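"""Embedded gene-part registry: persistence, querying, export, batch retrieval.

The store mirrors the part-centric schema of the source framework: five
tables holding the sequences of each genetic part type (promoter, 5'UTR,
CDS, 3'UTR, terminator), a gene table referencing one part of each type,
and two hit tables (BLASTp, Pfam) attached to CDSs, plus a locus table
recording original genomic coordinates.  Backing store is sqlite3 —
``:memory:`` for tests, a file for the CLI — with referential integrity
enforced.
"""

from __future__ import annotations

import io as _io
import json
import re
import sqlite3
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .datamodel import (
    PART_TYPES,
    AnnotationHit,
    ExonChain,
    Gene,
    Interval,
    Locus,
    Part,
    StrandedLocation,
)
from .errors import IntegrityError, UndefinedStatisticError
from .recode import OverhangConfig, RecodeResult, recode
from .split import spliced_sequence

_PART_TABLES = {pt: f"{pt}_parts" for pt in PART_TYPES}

_SCHEMA = """
CREATE TABLE loci (
    id TEXT PRIMARY KEY, contig TEXT NOT NULL, start INTEGER NOT NULL,
    end INTEGER NOT NULL, strand TEXT NOT NULL, sequence TEXT NOT NULL
);
{part_tables}
CREATE TABLE genes (
    id TEXT PRIMARY KEY,
    locus_id TEXT NOT NULL REFERENCES loci(id),
    transcript_id TEXT NOT NULL,
    is_primary INTEGER NOT NULL DEFAULT 1,
    promoter_id TEXT NOT NULL REFERENCES promoter_parts(id),
    utr5_id TEXT NOT NULL REFERENCES utr5_parts(id),
    cds_id TEXT NOT NULL REFERENCES cds_parts(id),
    utr3_id TEXT NOT NULL REFERENCES utr3_parts(id),
    terminator_id TEXT NOT NULL REFERENCES terminator_parts(id),
    aliases TEXT NOT NULL DEFAULT '[]'
);
CREATE TABLE blast_hits (
    id INTEGER PRIMARY KEY,
    cds_id TEXT NOT NULL REFERENCES cds_parts(id),
    accession TEXT NOT NULL, keywords TEXT NOT NULL,
    e_value REAL NOT NULL, bitscore REAL NOT NULL,
    identity REAL NOT NULL, coverage_per_subject REAL NOT NULL,
    span_start INTEGER NOT NULL, span_end INTEGER NOT NULL
);
CREATE TABLE pfam_hits (
    id INTEGER PRIMARY KEY,
    cds_id TEXT NOT NULL REFERENCES cds_parts(id),
    accession TEXT NOT NULL, keywords TEXT NOT NULL,
    e_value REAL NOT NULL, bitscore REAL NOT NULL,
    gathering_threshold REAL,
    span_start INTEGER NOT NULL, span_end INTEGER NOT NULL
);
""".format(
    part_tables="\n".join(
        f"""CREATE TABLE {table} (
    id TEXT PRIMARY KEY,
    span_start INTEGER NOT NULL, span_end INTEGER NOT NULL,
    exons TEXT NOT NULL, sequence TEXT NOT NULL
);"""
        for table in _PART_TABLES.values()
    )
)


@dataclass
class QueryRow:
    """One (locus, hit) row of a keyword query, E-value ascending."""

    locus_id: str
    gene_id: str
    cds_id: str
    source: str  # "blastp" | "pfam" | "id"
    accession: str
    e_value: Optional[float]
    keywords: Tuple[str, ...]


@dataclass
class PromoterRecord:
    cds_id: str
    sequence: str
    truncated: bool
    recoded: Optional[RecodeResult] = None


@dataclass
class PromoterLibrary:
    records: List[PromoterRecord] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    rejects: List[str] = field(default_factory=list)


@dataclass(frozen=True)
class AssemblyStats:
    count: int
    total_bp: int
    n50: int


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """Count, total length, and N50 of a set of sequence lengths.

    N50 is the length of the shortest sequence in the minimal set of longest
    sequences whose cumulative length reaches half the total.
    """
    if not lengths:
        raise UndefinedStatisticError("N50 is undefined for an empty length set")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if 2 * acc >= total:
            return AssemblyStats(len(lengths), total, l)
    raise AssertionError("unreachable")


def regex_search(sequence: str, pattern: str) -> List[Interval]:
    """All non-overlapping, leftmost-first regex matches on the forward strand."""
    try:
        compiled = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid pattern {pattern!r}: {exc}") from exc
    return [
        Interval(m.start(), m.end())
        for m in compiled.finditer(sequence)
        if m.end() > m.start()
    ]


class Registry:
    """Handle over the embedded part store."""

    def __init__(self, path: str = ":memory:"):
        self._conn = sqlite3.connect(path)
        self._conn.execute("PRAGMA foreign_keys = ON")
        if not self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='genes'"
        ).fetchone():
            self._conn.executescript(_SCHEMA)

    # -- construction --------------------------------------------------

    def add_locus(self, locus: Locus) -> None:
        o = locus.origin
        try:
            self._conn.execute(
                "INSERT INTO loci VALUES (?,?,?,?,?,?)",
                (locus.locus_id, o.contig_id, o.span.start, o.span.end, o.strand,
                 locus.sequence),
            )
        except sqlite3.IntegrityError as exc:
            raise IntegrityError(f"locus {locus.locus_id}: {exc}") from exc
        for gene in locus.genes:
            self.add_gene(gene)

    def add_gene(self, gene: Gene) -> None:
        try:
            for pt in PART_TYPES:
                part = gene.parts[pt]
                self._conn.execute(
                    f"INSERT INTO {_PART_TABLES[pt]} VALUES (?,?,?,?,?)",
                    (
                        part.part_id,
                        part.genomic_span.start,
                        part.genomic_span.end,
                        json.dumps([[e.start, e.end] for e in part.exons]),
                        part.sequence,
                    ),
                )
            self._conn.execute(
                "INSERT INTO genes VALUES (?,?,?,?,?,?,?,?,?,?)",
                (
                    gene.gene_id,
                    gene.locus_id,
                    gene.transcript_id,
                    int(gene.is_primary),
                    *(gene.parts[pt].part_id for pt in PART_TYPES),
                    json.dumps(list(gene.aliases)),
                ),
            )
        except (sqlite3.IntegrityError, KeyError) as exc:
            raise IntegrityError(f"gene {gene.gene_id}: {exc}") from exc

    def add_hit(self, hit: AnnotationHit) -> None:
        if not self._conn.execute(
            "SELECT 1 FROM cds_parts WHERE id=?", (hit.cds_id,)
        ).fetchone():
            raise IntegrityError(f"hit {hit.accession}: unknown CDS {hit.cds_id}")
        if hit.source == "blastp":
            self._conn.execute(
                "INSERT INTO blast_hits VALUES (NULL,?,?,?,?,?,?,?,?,?)",
                (hit.cds_id, hit.accession, json.dumps(list(hit.keywords)),
                 hit.e_value, hit.bitscore, hit.identity, hit.coverage_per_subject,
                 hit.hit_span.start, hit.hit_span.end),
            )
        else:
            self._conn.execute(
                "INSERT INTO pfam_hits VALUES (NULL,?,?,?,?,?,?,?,?)",
                (hit.cds_id, hit.accession, json.dumps(list(hit.keywords)),
                 hit.e_value, hit.bitscore, hit.gathering_threshold,
                 hit.hit_span.start, hit.hit_span.end),
            )

    def commit(self) -> None:
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- introspection -------------------------------------------------

    @property
    def part_types(self) -> Tuple[str, ...]:
        """The five part collections of the schema."""
        return PART_TYPES

    def counts(self) -> Dict[str, int]:
        out = {}
        for name in ["loci", "genes", "blast_hits", "pfam_hits", *_PART_TABLES.values()]:
            out[name] = self._conn.execute(f"SELECT COUNT(*) FROM {name}").fetchone()[0]
        return out

    def gene_ids(self) -> List[str]:
        return [r[0] for r in self._conn.execute("SELECT id FROM genes ORDER BY id")]

    # -- object reconstruction -----------------------------------------

    def _load_part(self, part_type: str, part_id: str) -> Part:
        row = self._conn.execute(
            f"SELECT id, span_start, span_end, exons, sequence FROM "
            f"{_PART_TABLES[part_type]} WHERE id=?",
            (part_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"{part_type} part {part_id!r} not found")
        return Part(
            part_id=row[0],
            part_type=part_type,
            genomic_span=Interval(row[1], row[2]),
            exons=ExonChain([Interval(a, b) for a, b in json.loads(row[3])]),
            sequence=row[4],
        )

    def get_gene(self, gene_id: str) -> Gene:
        row = self._conn.execute(
            "SELECT id, locus_id, transcript_id, is_primary, promoter_id, utr5_id,"
            " cds_id, utr3_id, terminator_id, aliases FROM genes WHERE id=?",
            (gene_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"gene {gene_id!r} not found")
        parts = {
            pt: self._load_part(pt, row[4 + i]) for i, pt in enumerate(PART_TYPES)
        }
        return Gene(
            gene_id=row[0], locus_id=row[1], transcript_id=row[2],
            parts=parts, is_primary=bool(row[3]), aliases=tuple(json.loads(row[9])),
        )

    def get_locus(self, locus_id: str, with_genes: bool = True) -> Locus:
        row = self._conn.execute(
            "SELECT id, contig, start, end, strand, sequence FROM loci WHERE id=?",
            (locus_id,),
        ).fetchone()
        if row is None:
            raise KeyError(f"locus {locus_id!r} not found")
        locus = Locus(
            locus_id=row[0],
            origin=StrandedLocation(row[1], Interval(row[2], row[3]), row[4]),
            sequence=row[5],
        )
        if with_genes:
            for (gid,) in self._conn.execute(
                "SELECT id FROM genes WHERE locus_id=? ORDER BY id", (locus_id,)
            ):
                locus.genes.append(self.get_gene(gid))
        return locus

    def hits_for_cds(self, cds_id: str) -> List[AnnotationHit]:
        hits = []
        for row in self._conn.execute(
            "SELECT accession, keywords, e_value, bitscore, identity,"
            " coverage_per_subject, span_start, span_end FROM blast_hits"
            " WHERE cds_id=? ORDER BY id",
            (cds_id,),
        ):
            hits.append(
                AnnotationHit(
                    cds_id=cds_id, source="blastp", accession=row[0],
                    keywords=tuple(json.loads(row[1])), e_value=row[2],
                    bitscore=row[3], hit_span=Interval(row[6], row[7]),
                    identity=row[4], coverage_per_subject=row[5],
                )
            )
        for row in self._conn.execute(
            "SELECT accession, keywords, e_value, bitscore, gathering_threshold,"
            " span_start, span_end FROM pfam_hits WHERE cds_id=? ORDER BY id",
            (cds_id,),
        ):
            hits.append(
                AnnotationHit(
                    cds_id=cds_id, source="pfam", accession=row[0],
                    keywords=tuple(json.loads(row[1])), e_value=row[2],
                    bitscore=row[3], hit_span=Interval(row[5], row[6]),
                    gathering_threshold=row[4],
                )
            )
        return hits

    # -- querying ------------------------------------------------------

    def query(self, keyword: str) -> List[QueryRow]:
        """Case-insensitive keyword search over hit text and gene/locus IDs.

        One row per matching (locus, hit), sorted ascending by E-value with a
        deterministic (locus_id, accession) tie-break; ID matches (gene,
        locus, or alias equal to the keyword) rank after scored hits.
        """
        kw = keyword.lower()
        rows: List[QueryRow] = []
        gene_index = {
            gid: (locus_id, cds_id, aliases)
            for gid, locus_id, cds_id, aliases in self._conn.execute(
                "SELECT id, locus_id, cds_id, aliases FROM genes"
            )
        }
        cds_to_gene = {v[1]: (gid, v[0]) for gid, v in gene_index.items()}

        for table, source in (("blast_hits", "blastp"), ("pfam_hits", "pfam")):
            for cds_id, accession, keywords, e_value in self._conn.execute(
                f"SELECT cds_id, accession, keywords, e_value FROM {table}"
            ):
                words = json.loads(keywords)
                text = " ".join([accession, *words]).lower()
                if kw in text:
                    gid, locus_id = cds_to_gene[cds_id]
                    rows.append(
                        QueryRow(locus_id, gid, cds_id, source, accession,
                                 e_value, tuple(words))
                    )
        matched_loci = {r.locus_id for r in rows}
        for gid, (locus_id, cds_id, aliases) in gene_index.items():
            idents = {gid.lower(), locus_id.lower()}
            idents.update(a.lower() for a in json.loads(aliases))
            if kw in idents and locus_id not in matched_loci:
                rows.append(QueryRow(locus_id, gid, cds_id, "id", gid, None, ()))
        rows.sort(
            key=lambda r: (
                r.e_value if r.e_value is not None else float("inf"),
                r.locus_id,
                r.accession,
            )
        )
        return rows

    # -- GenBank export ------------------------------------------------

    def export_genbank(self, gene_id: str) -> str:
        """Render a gene as an annotated GenBank flat file (round-trippable)."""
        gene = self.get_gene(gene_id)
        locus = self.get_locus(gene.locus_id, with_genes=False)
        span = gene.span
        seq = locus.sequence[span.start : span.end]
        record = SeqRecord(
            Seq(seq),
            id=gene_id[:20],
            name=re.sub(r"[^A-Za-z0-9_.-]", "_", gene_id)[:16],
            description=f"{gene_id} from {gene.locus_id}",
            annotations={"molecule_type": "DNA", "topology": "linear"},
        )
        feature_keys = {
            "promoter": "promoter", "utr5": "5'UTR", "cds": "CDS",
            "utr3": "3'UTR", "terminator": "terminator",
        }
        for pt in PART_TYPES:
            part = gene.parts[pt]
            if part.is_empty:
                continue
            if pt in ("utr5", "cds", "utr3") and len(part.exons) > 1:
                locs = [
                    SimpleLocation(e.start - span.start, e.end - span.start, strand=1)
                    for e in part.exons
                ]
                location = CompoundLocation(locs, operator="join")
            else:
                location = SimpleLocation(
                    part.genomic_span.start - span.start,
                    part.genomic_span.end - span.start,
                    strand=1,
                )
            qualifiers = {"label": [part.part_id]}
            if pt == "cds":
                qualifiers["translation"] = [
                    str(Seq(self.spliced_part_sequence(part, locus)).translate()).rstrip("*")
                ]
            record.features.append(
                SeqFeature(location, type=feature_keys[pt], qualifiers=qualifiers)
            )
        cds_span = gene.parts["cds"].genomic_span
        for hit in self.hits_for_cds(gene.cds_id):
            record.features.append(
                SeqFeature(
                    SimpleLocation(
                        cds_span.start - span.start, cds_span.end - span.start, strand=1
                    ),
                    type="misc_feature",
                    qualifiers={
                        "label": [hit.accession],
                        "note": [f"{hit.source} hit; " + "; ".join(hit.keywords)],
                        "accession": [hit.accession],
                        "e_value": [repr(hit.e_value)],
                    },
                )
            )
        out = _io.StringIO()
        SeqIO.write(record, out, "genbank")
        return out.getvalue()

    @staticmethod
    def spliced_part_sequence(part: Part, locus: Locus) -> str:
        return spliced_sequence(part, locus)

    # -- batch promoter retrieval --------------------------------------

    def batch_promoters(
        self,
        cds_ids: Sequence[str],
        promoter_len: int = 2000,
        include_utr5: bool = True,
        recode_parts: bool = False,
        config: Optional[OverhangConfig] = None,
    ) -> PromoterLibrary:
        """Retrieve promoter elements for a list of CDS IDs.

        For each CDS the TSS-proximal ``promoter_len`` bp of the stored
        promoter part (truncated with a warning when the stored flank is
        shorter), optionally concatenated with the spliced 5'UTR, optionally
        recoded with promoter-position overhangs.  Output order follows input
        order; unresolvable IDs go to the rejects list.
        """
        lib = PromoterLibrary()
        for cds_id in cds_ids:
            row = self._conn.execute(
                "SELECT id, locus_id FROM genes WHERE cds_id=?", (cds_id,)
            ).fetchone()
            if row is None:
                lib.rejects.append(cds_id)
                continue
            gene = self.get_gene(row[0])
            locus = self.get_locus(gene.locus_id, with_genes=False)
            promoter = gene.parts["promoter"].sequence
            truncated = len(promoter) < promoter_len
            if truncated:
                lib.warnings.append(
                    f"{cds_id}: stored promoter is {len(promoter)} bp, "
                    f"shorter than requested {promoter_len} bp"
                )
            seq = promoter[-promoter_len:] if promoter_len else ""
            if include_utr5:
                seq += spliced_sequence(gene.parts["utr5"], locus)
            rec = recode(seq, "promoter", config=config) if recode_parts else None
            lib.records.append(PromoterRecord(cds_id, seq, truncated, rec))
        return lib


def build_registry(
    loci: Iterable[Locus],
    hits: Iterable[AnnotationHit] = (),
    path: str = ":memory:",
) -> Registry:
    """Create a registry from loci (carrying their genes) and retained hits.

    Hits referencing CDSs absent from the store raise
    :class:`~genoparts.errors.IntegrityError`, as do duplicate gene IDs.
    """
    reg = Registry(path)
    for locus in loci:
        reg.add_locus(locus)
    for hit in hits:
        reg.add_hit(hit)
    reg.commit()
    return reg
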