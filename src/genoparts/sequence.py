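"""DNA string helpers: alphabet normalization, reverse complement, translation.

All sequences in the package are plain upper-case Python strings over
{A, C, G, T, N}. Translation is backed by Biopython's standard table with
package-level error semantics (frame check, loud internal stops, silent
terminal-stop removal).
"""

from __future__ import annotations

from Bio.Seq import Seq

from .errors import AlphabetError, FrameError, PrematureStopError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_dna(seq: str, *, context: str = "sequence") -> str:
    """Upper-case ``seq`` and reject characters outside {A, C, G, T, N}."""
    up = seq.upper().replace("U", "T")
    bad = set(up) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"{context} contains invalid characters: {sorted(bad)}")
    return up


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate ``cds`` with the standard genetic code.

    The terminal stop codon (if present) is dropped from the protein. An
    internal stop raises :class:`PrematureStopError` naming the codon index;
    a length not divisible by three raises :class:`FrameError`.
    """
    if len(cds) % 3:
        raise FrameError(f"CDS length {len(cds)} is not divisible by 3")
    if not cds:
        return ""
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    star = protein.find("*")
    if star != -1:
        raise PrematureStopError(star, cds[3 * star : 3 * star + 3])
    return protein
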