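"""Registry store, querying, GenBank export, batch promoters, N50."""

import io as _io
from dataclasses import replace

import numpy as np
import pytest
from Bio import SeqIO
from hypothesis import given, settings, strategies as st

from conftest import locus_of
from oracles import n50_oracle

from genoparts import (
    assembly_stats,
    build_registry,
    compile_to_registry,
    regex_search,
    scan_sites,
    spliced_sequence,
)
from genoparts.errors import IntegrityError, UndefinedStatisticError


@pytest.fixture(scope="module")
def reg(edge_result):
    return compile_to_registry(edge_result)


class TestBuild:
    def test_schema_has_exactly_five_part_collections(self, reg):
        assert reg.part_types == ("promoter", "utr5", "cds", "utr3", "terminator")
        counts = reg.counts()
        part_tables = [k for k in counts if k.endswith("_parts")]
        assert len(part_tables) == 5

    def test_cardinalities_match_truth(self, reg, edge_bundle, edge_result):
        counts = reg.counts()
        n_genes = sum(1 for g in edge_bundle.truth["genes"] if g["retained"])
        assert counts["genes"] == n_genes
        for t in ["promoter_parts", "utr5_parts", "cds_parts", "utr3_parts",
                  "terminator_parts"]:
            assert counts[t] == n_genes
        n_loci = sum(1 for l in edge_bundle.truth["loci"] if l["retained"])
        assert counts["loci"] == n_loci
        # retained hits only
        want_blast = sum(
            1 for h in edge_bundle.truth["hits"]["blastp"]
            if h["passes"] and any(
                g["cds_id"] == h["cds_id"] and g["retained"]
                for g in edge_bundle.truth["genes"]
            )
        )
        assert counts["blast_hits"] == want_blast

    def test_empty_registry_is_valid(self):
        r = build_registry([], [])
        assert sum(r.counts().values()) == 0
        assert r.query("anything") == []

    def test_duplicate_gene_rejected(self, edge_result):
        r = build_registry(edge_result.loci, [])
        with pytest.raises(IntegrityError):
            r.add_gene(edge_result.genes[0])

    def test_dangling_hit_rejected(self, edge_result):
        r = build_registry(edge_result.loci, [])
        bad = replace(edge_result.retained_hits[0], cds_id="nope.orf9")
        with pytest.raises(IntegrityError):
            r.add_hit(bad)

    def test_roundtrip_gene_reconstruction(self, reg, edge_result):
        for gene in edge_result.genes:
            loaded = reg.get_gene(gene.gene_id)
            for pt in reg.part_types:
                assert loaded.parts[pt].sequence == gene.parts[pt].sequence
                assert loaded.parts[pt].genomic_span == gene.parts[pt].genomic_span
                assert list(loaded.parts[pt].exons) == list(gene.parts[pt].exons)


class TestQuery:
    def test_sorted_by_evalue(self, reg):
        rows = reg.query("GENE")  # matches every blast keyword
        evs = [r.e_value for r in rows if r.e_value is not None]
        assert evs == sorted(evs)
        assert rows  # non-empty
        # naive rescan: every returned row's hit text really contains the kw
        for r in rows:
            if r.source != "id":
                text = " ".join([r.accession, *r.keywords]).lower()
                assert "gene" in text

    def test_best_evalue_locus_first(self, reg):
        rows = reg.query("GENE")
        best = min(r.e_value for r in rows if r.e_value is not None)
        assert rows[0].e_value == best

    def test_unmatched_keyword_empty(self, reg):
        assert reg.query("zzz-not-there") == []

    def test_gene_id_match_without_hit_text(self, reg, edge_result):
        gid = edge_result.genes[0].gene_id
        rows = reg.query(gid)
        assert any(r.gene_id == gid for r in rows)

    def test_case_insensitive(self, reg):
        assert reg.query("gene") == reg.query("GENE")


class TestRegexSearch:
    def test_agrees_with_site_scan(self, edge_result):
        locus = edge_result.loci[0]
        matches = regex_search(locus.sequence, "GGTCTC|GAGACC")
        want = sorted(
            o.footprint for o in scan_sites(locus.sequence) if o.pattern == "BsaI"
        )
        assert sorted(matches) == want

    def test_no_match(self):
        assert regex_search("AAAA", "GGTCTC") == []

    def test_non_overlapping_leftmost(self):
        from genoparts import Interval

        assert regex_search("ATGATG", "ATG") == [Interval(0, 3), Interval(3, 6)]

    def test_invalid_pattern(self):
        with pytest.raises(ValueError):
            regex_search("AAAA", "(")


class TestGenBankExport:
    def test_multi_exon_cds_join_location(self, reg, edge_result, edge_bundle):
        tid = edge_bundle.truth["edge_cases"]["reverse_multiexon"]
        gene = next(g for g in edge_result.genes if g.transcript_id == tid)
        text = reg.export_genbank(gene.gene_id)
        assert "join(" in text
        rec = SeqIO.read(_io.StringIO(text), "genbank")
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        assert len(cds_feats) == 1
        assert len(cds_feats[0].location.parts) == len(gene.parts["cds"].exons)

    def test_roundtrip_sequence_and_coordinates(self, reg, edge_result):
        for gene in edge_result.genes:
            locus = locus_of(edge_result, gene)
            text = reg.export_genbank(gene.gene_id)
            rec = SeqIO.read(_io.StringIO(text), "genbank")
            assert str(rec.seq) == locus.sequence  # gene tiles the whole locus
            cds = next(f for f in rec.features if f.type == "CDS")
            got = [(int(p.start), int(p.end)) for p in cds.location.parts]
            want = [(e.start, e.end) for e in gene.parts["cds"].exons]
            assert got == want

    def test_feature_count_is_parts_plus_hits(self, reg, edge_result):
        for gene in edge_result.genes:
            n_nonempty = sum(
                0 if gene.parts[pt].is_empty else 1 for pt in reg.part_types
            )
            n_hits = len(reg.hits_for_cds(gene.cds_id))
            rec = SeqIO.read(_io.StringIO(reg.export_genbank(gene.gene_id)), "genbank")
            assert len(rec.features) == n_nonempty + n_hits

    def test_unknown_gene(self, reg):
        with pytest.raises(KeyError):
            reg.export_genbank("nope")


class TestBatchPromoters:
    def test_default_slice_is_tss_proximal_2kb(self, reg, edge_result):
        gene = next(
            g for g in edge_result.genes
            if len(g.parts["promoter"].sequence) >= 3000
        )
        lib = reg.batch_promoters([gene.cds_id], include_utr5=False)
        (r,) = lib.records
        assert len(r.sequence) == 2000
        assert gene.parts["promoter"].sequence.endswith(r.sequence)

    def test_utr5_appended_spliced(self, reg, edge_result):
        gene = next(
            g for g in edge_result.genes if len(g.parts["utr5"].exons) >= 1
        )
        locus = locus_of(edge_result, gene)
        lib = reg.batch_promoters([gene.cds_id], include_utr5=True)
        (r,) = lib.records
        utr5 = spliced_sequence(gene.parts["utr5"], locus)
        assert r.sequence.endswith(utr5)
        prom = gene.parts["promoter"].sequence
        assert r.sequence[: len(r.sequence) - len(utr5)] == prom[-2000:]

    def test_truncation_warning(self, reg, edge_result, edge_bundle):
        tid = edge_bundle.truth["edge_cases"]["truncated_promoter"]
        gene = next(g for g in edge_result.genes if g.transcript_id == tid)
        assert len(gene.parts["promoter"].sequence) < 2000
        lib = reg.batch_promoters([gene.cds_id], include_utr5=False)
        assert lib.warnings and lib.records[0].truncated

    def test_empty_and_rejects(self, reg):
        assert reg.batch_promoters([]).records == []
        lib = reg.batch_promoters(["missing.orf1"])
        assert lib.rejects == ["missing.orf1"] and lib.records == []

    def test_recoded_output_site_free(self, reg, edge_result):
        gene = edge_result.genes[0]
        lib = reg.batch_promoters([gene.cds_id], recode_parts=True)
        rec = lib.records[0].recoded
        assert rec is not None
        assert scan_sites(rec.interior_sequence) == []


class TestAssemblyStats:
    def test_cumulative_example(self):
        s = assembly_stats([6, 5, 4, 3, 2])
        assert (s.count, s.total_bp, s.n50) == (5, 20, 5)

    def test_single_length(self):
        assert assembly_stats([42]).n50 == 42

    def test_empty_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            assembly_stats([])

    @given(
        st.lists(st.integers(min_value=1, max_value=10**6), min_size=1, max_size=50)
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_bruteforce_oracle(self, lengths):
        assert assembly_stats(lengths).n50 == n50_oracle(lengths)
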