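"""Type IIS domestication and common-syntax overhang appending.

Domestication removes internal BsaI/SapI recognition sites: synonymously
(codon-preserving) for CDS parts, by minimal single-base substitution for
non-coding parts.  ``apply_common_syntax`` then flanks the clean interior
with Golden Gate adapters (enzyme recognition + spacer + 4-nt fusion site)
so that digestion with the assembly enzyme releases the part carrying the
configured standard overhangs.

The shipped default syntax table (``data/common_syntax.json``) enumerates
the 12 standard plant fusion sites and the per-part-position junctions; it
is data, not code, and can be replaced wholesale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .datamodel import Interval
from .errors import DomesticationError, UsageError
from .sequence import normalize_dna, reverse_complement, translate

# ---------------------------------------------------------------------------
# site scanning


@dataclass(frozen=True)
class SitePattern:
    name: str
    recognition: str

    def __post_init__(self):
        if not self.recognition:
            raise ValueError("recognition sequence must be non-empty")


BSAI = SitePattern("BsaI", "GGTCTC")
SAPI = SitePattern("SapI", "GCTCTTC")
DEFAULT_PATTERNS: Tuple[SitePattern, ...] = (BSAI, SAPI)


@dataclass(frozen=True, order=True)
class SiteOccurrence:
    """A recognition-site match, in forward-strand coordinates."""

    position: int
    pattern: str
    strand: str  # "+" when the recognition sequence reads on the given strand
    length: int

    @property
    def footprint(self) -> Interval:
        return Interval(self.position, self.position + self.length)


def _find_all(seq: str, sub: str) -> List[int]:
    out, i = [], seq.find(sub)
    while i != -1:
        out.append(i)
        i = seq.find(sub, i + 1)  # step 1: overlapping matches all reported
    return out


def scan_sites(
    seq: str, patterns: Sequence[SitePattern] = DEFAULT_PATTERNS
) -> List[SiteOccurrence]:
    """Find all recognition-site occurrences on both strands.

    Positions are 0-based offsets of the footprint start on the forward
    strand; overlapping occurrences are all reported; N never matches.
    """
    seq = normalize_dna(seq)
    occs: List[SiteOccurrence] = []
    for p in patterns:
        rc = reverse_complement(p.recognition)
        for i in _find_all(seq, p.recognition):
            occs.append(SiteOccurrence(i, p.name, "+", len(p.recognition)))
        if rc != p.recognition:
            for i in _find_all(seq, rc):
                occs.append(SiteOccurrence(i, p.name, "-", len(p.recognition)))
    occs.sort()
    return occs


# ---------------------------------------------------------------------------
# codon machinery


@lru_cache(maxsize=1)
def _codon_usage() -> Dict[str, float]:
    with resources.files("genoparts.data").joinpath("codon_usage.json").open() as fh:
        return json.load(fh)["frequencies"]


@lru_cache(maxsize=1)
def _synonyms() -> Dict[str, Tuple[str, ...]]:
    by_aa: Dict[str, List[str]] = {}
    bases = "ACGT"
    for a in bases:
        for b in bases:
            for c in bases:
                codon = a + b + c
                aa = str(Seq(codon).translate())
                by_aa.setdefault(aa, []).append(codon)
    return {
        codon: tuple(sorted(set(fam) - {codon}))
        for fam in by_aa.values()
        for codon in fam
    }


@dataclass
class Edit:
    position: int
    old: str
    new: str


@dataclass
class Adapters:
    """Description of the appended 5'/3' adapter blocks."""

    enzyme: str
    five_prime: str
    three_prime: str
    five_prime_fusion_site: str
    three_prime_fusion_site: str


@dataclass
class RecodeResult:
    sequence: str
    edits: List[Edit] = field(default_factory=list)
    old_sites: List[SiteOccurrence] = field(default_factory=list)
    adapters: Optional[Adapters] = None
    #: interval of the original (domesticated) part within ``sequence``
    interior: Optional[Interval] = None
    #: exportable annotations: (feature type, interval on sequence, label)
    features: List[Tuple[str, Interval, str]] = field(default_factory=list)

    @property
    def interior_sequence(self) -> str:
        if self.interior is None:
            return self.sequence
        return self.sequence[self.interior.start : self.interior.end]


def _created_sites(
    old: Sequence[SiteOccurrence], new: Sequence[SiteOccurrence]
) -> List[SiteOccurrence]:
    return [o for o in new if o not in set(old)]


# ---------------------------------------------------------------------------
# domestication


def domesticate_cds(
    cds: str,
    patterns: Sequence[SitePattern] = DEFAULT_PATTERNS,
) -> RecodeResult:
    """Remove restriction sites from a CDS by synonymous codon substitution.

    The output translates to the identical protein.  Per site, candidate
    single-codon substitutions are ranked by fewest base changes, then by
    descending codon-usage frequency, then lexicographically; a candidate is
    admissible only if it destroys the site without creating a new one.
    """
    seq = normalize_dna(cds, context="CDS")
    if len(seq) % 3:
        raise DomesticationError(f"CDS length {len(seq)} not divisible by 3")
    translate(seq)  # raises on internal stop
    usage = _codon_usage()
    synonyms = _synonyms()

    original_sites = scan_sites(seq, patterns)
    edits: List[Edit] = []
    current = seq
    for _ in range(len(original_sites) + 4):
        sites = scan_sites(current, patterns)
        if not sites:
            break
        site = sites[0]
        first_codon = site.position // 3
        last_codon = (site.position + site.length - 1) // 3
        candidates = []
        for ci in range(first_codon, last_codon + 1):
            codon = current[3 * ci : 3 * ci + 3]
            for alt in synonyms.get(codon, ()):
                if "N" in alt:
                    continue
                trial = current[: 3 * ci] + alt + current[3 * ci + 3 :]
                new_sites = scan_sites(trial, patterns)
                if site in new_sites or _created_sites(sites, new_sites):
                    continue
                ndiff = sum(a != b for a, b in zip(codon, alt))
                candidates.append((ndiff, -usage.get(alt, 0.0), alt, ci, codon, trial))
        if not candidates:
            raise DomesticationError(
                f"no synonymous substitution removes {site.pattern} site at "
                f"{site.position} ({site.strand})"
            )
        _, _, alt, ci, codon, trial = min(candidates)
        for k, (a, b) in enumerate(zip(codon, alt)):
            if a != b:
                edits.append(Edit(3 * ci + k, a, b))
        current = trial
    else:
        raise DomesticationError("domestication did not converge")

    assert translate(current) == translate(seq)
    return RecodeResult(sequence=current, edits=edits, old_sites=original_sites)


def domesticate_noncoding(
    seq: str,
    patterns: Sequence[SitePattern] = DEFAULT_PATTERNS,
) -> RecodeResult:
    """Remove restriction sites by minimal single-base substitution.

    Each edit lies inside a site footprint; candidates are ranked by most
    sites destroyed (so one edit in the overlap of two sites resolves both),
    then by position, then base, for determinism.
    """
    current = normalize_dna(seq)
    original_sites = scan_sites(current, patterns)
    edits: List[Edit] = []
    for _ in range(len(original_sites) + 4):
        sites = scan_sites(current, patterns)
        if not sites:
            break
        site = sites[0]
        candidates = []
        for pos in range(site.position, site.position + site.length):
            old = current[pos]
            for base in "ACGT":
                if base == old:
                    continue
                trial = current[:pos] + base + current[pos + 1 :]
                new_sites = scan_sites(trial, patterns)
                if site in new_sites or _created_sites(sites, new_sites):
                    continue
                destroyed = len(sites) - len(new_sites)
                candidates.append((-destroyed, pos, base, old, trial))
        if not candidates:
            raise DomesticationError(
                f"no single-base substitution removes {site.pattern} site at "
                f"{site.position} ({site.strand})"
            )
        _, pos, base, old, trial = min(candidates)
        edits.append(Edit(pos, old, base))
        current = trial
    else:
        raise DomesticationError("domestication did not converge")
    return RecodeResult(sequence=current, edits=edits, old_sites=original_sites)


# ---------------------------------------------------------------------------
# common-syntax adapters


@dataclass(frozen=True)
class OverhangConfig:
    """Fusion-site table for a type IIS assembly syntax.

    ``positions`` maps ``part_type`` (non-CDS) or ``"cds:<fusion_mode>"`` to
    the pair (5' fusion site, 3' fusion site); every site is a 4-mer drawn
    from ``fusion_sites``, the syntax's full set of 12 distinct overhangs.
    """

    enzyme: SitePattern
    spacer: str
    fusion_sites: Tuple[str, ...]
    positions: Dict[str, Tuple[str, str]]

    def junctions(self, part_type: str, fusion_mode: Optional[str]) -> Tuple[str, str]:
        if part_type == "cds":
            key = f"cds:{fusion_mode or 'no_fusion'}"
        else:
            if fusion_mode not in (None, "no_fusion"):
                raise UsageError(
                    f"fusion mode {fusion_mode!r} applies only to CDS parts"
                )
            key = part_type
        if key not in self.positions:
            raise UsageError(f"no overhang configuration for {key!r}")
        return self.positions[key]


FUSION_MODES = ("n_terminal", "c_terminal", "no_fusion")


@lru_cache(maxsize=1)
def default_overhang_config() -> OverhangConfig:
    with resources.files("genoparts.data").joinpath("common_syntax.json").open() as fh:
        raw = json.load(fh)
    sites = tuple(raw["fusion_sites"].values())
    if len(set(sites)) != len(sites):
        raise ValueError("fusion sites in syntax config must be distinct")
    for s in sites:
        if len(s) != 4:
            raise ValueError(f"fusion site {s!r} is not a 4-mer")
    return OverhangConfig(
        enzyme=SitePattern(raw["enzyme"]["name"], raw["enzyme"]["recognition"]),
        spacer=raw["spacer"],
        fusion_sites=sites,
        positions={k: (v[0], v[1]) for k, v in raw["positions"].items()},
    )


def apply_common_syntax(
    seq: str,
    part_type: str,
    fusion_mode: Optional[str] = None,
    config: Optional[OverhangConfig] = None,
) -> RecodeResult:
    """Flank a domesticated part with common-syntax Golden Gate adapters.

    Output layout: ``recognition + spacer + F5 | seq | F3 + rc(spacer) +
    rc(recognition)``; digestion with the assembly enzyme releases
    ``F5 + seq + F3``, i.e. the part carrying its configured 4-nt overhangs.
    """
    config = config or default_overhang_config()
    seq = normalize_dna(seq)
    f5, f3 = config.junctions(part_type, fusion_mode)
    rec = config.enzyme.recognition
    five = rec + config.spacer + f5
    three = f3 + reverse_complement(config.spacer) + reverse_complement(rec)
    out = five + seq + three
    interior = Interval(len(five), len(five) + len(seq))
    features = [
        ("enzyme_site", Interval(0, len(rec)), f"{config.enzyme.name} (forward)"),
        (
            "enzyme_site",
            Interval(len(out) - len(rec), len(out)),
            f"{config.enzyme.name} (reverse)",
        ),
        ("overhang", Interval(len(five) - 4, len(five)), f"5' fusion site {f5}"),
        ("overhang", Interval(interior.end, interior.end + 4), f"3' fusion site {f3}"),
        ("part", interior, part_type),
    ]
    return RecodeResult(
        sequence=out,
        adapters=Adapters(config.enzyme.name, five, three, f5, f3),
        interior=interior,
        features=features,
    )


def recode(
    seq: str,
    part_type: str,
    fusion_mode: Optional[str] = None,
    config: Optional[OverhangConfig] = None,
    patterns: Sequence[SitePattern] = DEFAULT_PATTERNS,
) -> RecodeResult:
    """Domesticate a part (CDS-aware) and append common-syntax adapters."""
    if part_type == "cds":
        dom = domesticate_cds(seq, patterns)
    else:
        dom = domesticate_noncoding(seq, patterns)
    syn = apply_common_syntax(dom.sequence, part_type, fusion_mode, config)
    offset = syn.interior.start
    features = list(syn.features)
    for occ in dom.old_sites:
        features.append(
            (
                "old_site",
                occ.footprint.shift(offset),
                f"removed {occ.pattern} site ({occ.strand})",
            )
        )
    for e in dom.edits:
        features.append(
            ("edit", Interval(e.position + offset, e.position + offset + 1),
             f"{e.old}->{e.new}")
        )
    return RecodeResult(
        sequence=syn.sequence,
        edits=dom.edits,
        old_sites=dom.old_sites,
        adapters=syn.adapters,
        interior=syn.interior,
        features=features,
    )
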