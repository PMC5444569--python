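"""Independent oracles used by the test suite.

Deliberately written without reusing package internals: reverse complement
via Biopython, translation via a hand-rolled codon dictionary, clustering via
networkx connected components, N50 by cumulative brute force, and a type IIS
digestion simulator derived from the enzyme cut geometry.
"""

from itertools import combinations, product

import networkx as nx
from Bio.Seq import Seq

# hand-coded standard genetic code (DNA codons)
CODON_TABLE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(product(_bases, repeat=3)):
    CODON_TABLE[_a + _b + _c] = _aas[_i]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_oracle(cds: str) -> str:
    aas = [CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    assert "*" not in aas
    return "".join(aas)


def cluster_oracle(mappings):
    """Connected components of the all-pairs overlap graph (frozenset of IDs)."""
    g = nx.Graph()
    for m in mappings:
        g.add_node(m.transcript_id)
    for a, b in combinations(mappings, 2):
        if (
            a.location.contig_id == b.location.contig_id
            and a.location.strand == b.location.strand
            and a.genomic_span.start < b.genomic_span.end
            and b.genomic_span.start < a.genomic_span.end
        ):
            g.add_edge(a.transcript_id, b.transcript_id)
    return {frozenset(c) for c in nx.connected_components(g)}


def n50_oracle(lengths):
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= total / 2:
            return l


def orf_scan_oracle(seq: str, min_len_aa: int = 100):
    """Maximal ATG→stop ORFs per frame/region, as (start, end, partial)."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for frame in range(3):
        codons = [
            (i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)
        ]
        start = None
        for i, codon in codons:
            if codon in stops:
                if start is not None and (i - start) // 3 > min_len_aa:
                    out.append((start, i + 3, False))
                start = None
            elif codon == "ATG" and start is None:
                start = i
        if start is not None:
            end = start + 3 * ((len(seq) - start) // 3)
            if (end - start) // 3 > min_len_aa:
                out.append((start, end, True))
    return sorted(out, key=lambda t: (-(t[1] - t[0]), t[0]))


def find_sites_oracle(seq: str):
    """Substring + revcomp search for BsaI/SapI footprints: (pos, name, strand)."""
    out = []
    for name, rec in (("BsaI", "GGTCTC"), ("SapI", "GCTCTTC")):
        for pat, strand in ((rec, "+"), (revcomp(rec), "-")):
            for i in range(len(seq) - len(pat) + 1):
                if seq[i : i + len(pat)] == pat:
                    out.append((i, name, strand))
    return sorted(out)


def digest_type_iis(seq: str, recognition: str = "GGTCTC", overhang_len: int = 4):
    """Simulate digestion of a construct carrying one inward-facing site pair.

    The enzyme cuts the top strand one spacer base 3' of the forward
    recognition site, and symmetrically for the reverse-oriented site;
    returns the released fragment, whose first/last ``overhang_len`` bases
    are the 5'/3' fusion-site overhangs.
    """
    rc = revcomp(recognition)
    fwd = [i for i in range(len(seq)) if seq.startswith(recognition, i)]
    rev = [i for i in range(len(seq)) if seq.startswith(rc, i)]
    assert len(fwd) == 1 and len(rev) == 1, "expected exactly one site per strand"
    top_cut_left = fwd[0] + len(recognition) + 1
    top_cut_right = rev[0] - 1
    assert top_cut_left + overhang_len <= top_cut_right
    fragment = seq[top_cut_left:top_cut_right]
    return fragment, fragment[:overhang_len], fragment[-overhang_len:]


def minimal_edits_to_clean(seq: str, scan, max_edits: int = 2):
    """Brute-force smallest number of base substitutions removing all sites."""
    if not scan(seq):
        return 0
    for k in range(1, max_edits + 1):
        for positions in combinations(range(len(seq)), k):
            for bases in product("ACGT", repeat=k):
                if any(seq[p] == b for p, b in zip(positions, bases)):
                    continue
                trial = list(seq)
                for p, b in zip(positions, bases):
                    trial[p] = b
                if not scan("".join(trial)):
                    return k
    return None
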