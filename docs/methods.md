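# Methods

## The gene-part model

A **locus** is a contig-anchored, strand-oriented window: the union of the
genomic spans of a set of overlapping transcript mappings, extended by a
flank (default 3000 bp, configurable) on each side and clipped to the
contig. Reverse-strand loci are stored already reverse-complemented; the
`origin` field keeps the genomic frame. This buys a single orientation-free
code path for splitting, splicing and recoding at the cost of one inversion
at extraction time and one at export time.

A **gene** is one (isoform, ORF) pair decomposed into five slots that tile
the locus in strict order:

| part | genomic span | exon structure |
|---|---|---|
| promoter | `[0, TSS)` | single exon = span |
| 5′UTR | `[TSS, CDS start)` | spliced; may be empty |
| CDS | ORF-covered exons (stop codon included) | spliced |
| 3′UTR | `[CDS end, TES)` | spliced; may be empty |
| terminator | `[TES, locus end)` | single exon = span |

All coordinates are 0-based half-open; GFF3/GenBank conversion happens only
at the I/O boundary. Exons are split exactly at ORF boundaries, so UTR and
CDS chains never share bases. An intron that falls between two slots is
attributed to the upstream slot's genomic span, which is what makes the
five spans a partition of the locus. Part sequences are stored unspliced
(genomic); spliced sequences are recovered from the exon chains on demand.

Multiple ORFs on one transcript each yield a gene candidate sharing the
transcript boundaries; the longest is marked primary. Genes whose transcript
maps within a flank's reach of a contig edge get a shorter (possibly empty)
promoter or terminator; this is reported by validation, not rejected, since
the data is real even when the window is truncated.

## Clustering

Two mappings share a locus iff connected by a chain of pairwise genomic-span
overlaps (≥ 1 bp) on the same contig **and strand**. Strandedness is a
deliberate tightening: merging antisense overlaps would fuse distinct
genes; `stranded=False` restores the looser behavior. Overlap is evaluated
on transcript spans, not exon intersections, and flank-extended windows of
neighboring loci may overlap without being merged. The implementation is a
sort-and-sweep; tests compare it against an all-pairs connected-components
oracle.

## ORF stand-in

The built-in finder reports, per reading frame and stop-delimited region,
the maximal ORF (first ATG after the previous in-frame stop, through the
stop). It applies no coding-potential model — transcripts are assumed
oriented, and downstream logic needs only coordinates. The retention rule
is strict: protein length must *exceed* 100 aa, so a 100-aa ORF is dropped
and a 101-aa ORF kept. ORFs reaching the transcript end without a stop are
kept and flagged 3′-partial (configurable). External ORF tables bypass the
stand-in entirely.

## Evidence filters

* BLASTp: identity ≥ 35% and coverage-per-subject ≥ 20%, both inclusive
  ("minimal" values are admissible). Coverage per subject is the
  subject-side alignment length over the subject length; the tabular input
  dialect therefore adds `slen` and `stitle` to the standard 12 columns.
* Pfam: bitscore ≥ the family's sequence-level gathering threshold
  (inclusive, the Pfam convention). Hits without a GA are dropped with a
  warning rather than an error.
* Isoform retention: at least one predicted CDS and at least one retained
  hit from either source. Filters are applied per hit, are idempotent, and
  are monotone in their thresholds (property-tested).

## Recoding (type IIS domestication)

Sites scanned: BsaI `GGTCTC` and SapI `GCTCTTC`, both strands, overlapping
occurrences included, `N` never matches.

* **CDS**: per site, all synonymous single-codon substitutions in codons
  overlapping the footprint are enumerated; a candidate must destroy the
  site and create no new one. Ranking is (fewest base changes, highest
  codon-usage frequency, lexicographic) — the usage table is a bundled
  generic plant-like table used purely as a deterministic tie-break. Stop
  codons are a synonymous family, so a site overlapping the terminal stop
  is still resolvable. The protein is asserted unchanged.
* **Non-coding**: minimal single-base substitutions inside footprints;
  candidates destroying more sites rank first, so one edit in the overlap
  of two sites resolves both. Edit counts are verified against a
  brute-force minimal-edit search on small inputs.
* Unresolvable sites raise a domestication error naming the site; nothing
  is silently left in place.

Adapters follow conventional Golden Gate primer layout:
`GGTCTC + A + fusion site … part … fusion site + T + GAGACC`, so BsaI
(cutting one base 3′ of its recognition site, leaving 4-nt overhangs)
releases the part flanked by its configured fusion sites. Tests verify this
with an independently implemented digestion simulator.

The shipped syntax table (`data/common_syntax.json`) enumerates the 12
standard plant common-syntax fusion sites (GGAG, TGAC, TCCC, TACT, CCAT,
AATG, AGCC, TTCG, GCTT, GGTA, CGCT, GTTT). The source framework prints only
the count (12) and the three CDS fusion modes, so the position assignments
here — promoter GGAG→AATG, CDS no-fusion AATG→GCTT, C-terminal AATG→TTCG,
N-terminal AGCC→GCTT, terminator GGTA→CGCT — are this package's defaults,
shipped as data so any syntax can be substituted wholesale.

## Registry

sqlite3-backed (in-memory for tests): five part tables, a gene table
referencing one part of each type, two hit tables, plus a locus table for
original genomic coordinates. Referential integrity (dangling CDS
references, duplicate gene IDs) raises. Keyword queries match hit keywords
and accessions by case-insensitive substring, and gene/locus IDs and
aliases exactly; one row per (locus, hit), ascending E-value, ties broken
by (locus, accession); pure ID matches carry no E-value and sort last.
GenBank export renders multi-exon CDSs as `join(...)` locations and retained
hits as `misc_feature`s with accession and E-value qualifiers; zero-length
UTR slots are omitted (an empty location is not representable). Batch
promoter retrieval returns the TSS-proximal 2000 bp of the stored promoter
(truncated with a warning when the flank is shorter), optionally
concatenated with the spliced 5′UTR and recoded with promoter-position
overhangs.

N50 is the length of the shortest sequence in the minimal set of longest
sequences whose cumulative length reaches half the total.

## Synthetic data

The generator states a fixed world: by default 6 loci (2 per contig), up to
2 isoforms per locus, 1–4 exons, introns 80–400 bp, UTRs 40–280 bp, CDSs
120–320 aa (comfortably above the >100 aa rule), 3.2–4 kb contig-edge pads
so default flanks are full length, ~50% reverse-strand genes, uniform base
composition. Hit tables straddle every threshold deterministically (35.0 /
34.9 identity, 20.0 / 19.9 coverage, GA / GA−0.1 bitscore); restriction
sites are planted codon-aligned rather than awaited by chance.

Transcripts are constructed to contain exactly one qualifying ORF: UTRs are
generated ATG-free and candidate draws that happen to contain a second
qualifying ORF in another frame are redrawn (bounded, seed-deterministic).
This keeps truth tables exact; it also means the fixtures do not exercise
genuinely multi-ORF transcripts — those paths are covered by directly
constructed sequences in the unit tests. Other realism limits: no
sequencing error, no misassembly, no alternative splicing beyond
end-trimmed isoforms, uniform background composition, and synthesized (not
BLAST-derived) hit scores. A green end-to-end test therefore establishes
coordinate/sequence correctness of the pipeline, not robustness to noisy
alignments.

## Numerical and degenerate-input choices

* Zero-length 5′/3′UTRs are real empty parts (span of length 0); the
  `Interval` type permits `start == end` for exactly this reason, while
  exons and locus origins are validated strictly positive.
* The stop codon is stored in the CDS part sequence but excluded from the
  protein.
* Translation is backed by Biopython's standard table; internal stops raise
  an error naming the codon index, terminal stops are dropped silently.
* `regex` sequence search uses stdlib `re` semantics: non-overlapping,
  leftmost-first, forward strand only.
* Empty inputs: empty registries are valid; N50 of an empty length set is
  an error, not 0.

## Known limitations

* The ORF stand-in has no coding-potential model and will differ from a
  full ORF caller on low-complexity or chimeric transcripts.
* Non-coding domestication edits regulatory sequence; the greedy
  most-sites-destroyed rule is minimal per footprint but is not a global
  minimum-edit proof for pathological dense site arrangements (tested
  against brute force only for ≤ 2-edit neighborhoods).
* GenBank `LOCUS` names are truncated to 16 characters; long IDs remain
  intact in the record description.
* The registry is single-writer; it is an embedded store, not a server.
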