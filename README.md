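# genoparts

**genoparts** compiles genome and transcriptome evidence into a gene-centric
registry of reusable genetic parts, and recodes any part into a type IIS
common-syntax DNA part ready for Golden Gate assembly.

It is aimed at plant synthetic biologists (and anyone with a draft genome, a
transcriptome and standard annotation output) who want to mine endogenous
promoters, UTRs, CDSs and terminators as standalone, assembly-ready modules
rather than browse a conventional genome browser.

## What it does

Starting from contigs (FASTA), oriented transcript sequences (FASTA) and
exon-level transcript→genome mappings (GFF3 exon features or a simple TSV),
the pipeline:

1. drops mappings below the spliced-aligner quality cutoffs (identity and
   coverage ≥ 99% by default);
2. predicts ORFs on each transcript (stand-in for a full ORF caller: maximal
   ATG→stop ORFs per frame, kept only when the protein is **strictly longer
   than 100 aa**; an external ORF table can be supplied instead);
3. filters protein evidence — BLASTp hits at **identity ≥ 35%** and
   **coverage per subject ≥ 20%**, Pfam hits at **bitscore ≥ the family
   gathering threshold** — and retains only isoforms with at least one
   predicted CDS *and* one retained hit;
4. clusters overlapping same-strand mappings into loci and extracts each
   locus window with **3 kb flanks** (reverse-strand loci are stored
   reverse-complemented, so all downstream logic is orientation-free);
5. splits every isoform/ORF into the strict five-part assembly
   **promoter — 5′UTR — CDS — 3′UTR — terminator**, keeping exon
   coordinates so spliced sequences are always recoverable;
6. stores everything in an embedded registry (five part tables, a gene
   table, two hit tables) supporting keyword queries sorted by E-value,
   regex sequence search, annotated GenBank export, and batch retrieval of
   2 kb promoter elements (+5′UTRs);
7. **recodes** any part for type IIS assembly: BsaI/SapI sites are removed —
   synonymously within CDSs, by minimal single-base substitution elsewhere —
   and common-syntax adapters are appended so digestion releases the part
   flanked by its standard 4-nt fusion sites (12-site table shipped as
   replaceable JSON; CDSs support N-terminal / C-terminal / no-fusion
   modes).

A deterministic fixtures module generates complete synthetic datasets
(multi-exon genes on both strands, multi-isoform loci, contig-edge genes,
planted restriction sites) with ground-truth tables, so the entire pipeline
is testable without any external data.

## Worked example

```python
import genoparts as gp

bundle = gp.make_edge_cases(11)                      # synthetic dataset + truth
result = gp.compile_dataset(bundle.genome, bundle.transcripts, bundle.mappings,
                            blast_hits=bundle.blast_hits,
                            pfam_hits=bundle.pfam_hits)
print(len(result.loci), len(result.genes), result.dropped_isoforms)
# 6 7 ['t0007i1']        <- 6 loci, 7 genes; one isoform had no retained hit

reg = gp.compile_to_registry(result)
for r in reg.query("GENE31")[:2]:                    # rows sorted by E-value
    print(r.locus_id, r.gene_id, r.source, r.accession, r.e_value)
# locus00004 t0004i1.orf1 blastp SP0031.1 1e-41
# locus00004 t0004i1.orf1 blastp SP0031.2 1e-20

locus, gene = result.loci[0], result.genes[0]
cds = gp.spliced_sequence(gene.parts["cds"], locus)  # intron-free CDS
out = gp.recode(cds, "cds", "no_fusion")             # domesticate + adapters
print(len(out.edits), out.adapters.five_prime_fusion_site,
      out.adapters.three_prime_fusion_site)
# 0 AATG GCTT            <- clean CDS: no edits needed; standard CDS overhangs
```

The query rows say: the keyword matched two BLASTp hits on gene
`t0004i1.orf1` in locus `locus00004`, best E-value first.  The recode result
is the CDS flanked by BsaI adapters such that digestion releases it with
`AATG`/`GCTT` overhangs (the common-syntax CDS position); `0 edits` means no
internal BsaI/SapI site had to be recoded away.

The same flows are available from the shell:

```bash
genoparts fixtures --seed 11 --edge-cases --out bundle/
genoparts build --genome bundle/genome.fasta --transcripts bundle/transcripts.fasta \
    --mappings bundle/mappings.tsv --blast bundle/blast.tsv --pfam bundle/pfam.tsv \
    --out registry.db
genoparts query --registry registry.db GENE31
genoparts export-genbank --registry registry.db --gene t0004i1.orf1 --out gene.gb
genoparts batch-promoters --registry registry.db --ids ids.txt --out promoters.fasta
genoparts stats bundle/genome.fasta          # count / total bp / N50
genoparts recode --part-type cds --fusion none --in cds.fasta --out part.gb
```

## Acceptance script

`scripts/acceptance.py` regenerates the seeded edge-case bundle, runs the
complete pipeline (build → query → GenBank export → recode), verifies the
run against the bundle's ground truth, and writes the results manifest:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
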